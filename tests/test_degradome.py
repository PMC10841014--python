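"""Degradome profiles, cleavage scoring, categories, region calls, T-plots."""

from __future__ import annotations

import numpy as np
import pytest

import oracles
from liverpare import simdata
from liverpare.degradome import (
    DegradomeProfile,
    annotate_region,
    assign_category,
    call_targets,
    cutting_power,
    degradome_score,
    map_tags,
    profiles_from_counts,
    score_candidate,
)
from liverpare.duplex import align_site, find_candidate_sites
from liverpare.models import MiRNARecord, TranscriptModel, reverse_complement


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_profile(counts, library_total=None):
    total = library_total if library_total is not None else sum(counts.values())
    return DegradomeProfile(
        "t", "lib",
        counts=dict(counts),
        norm={p: c * 1e7 / total for p, c in counts.items()},
    )


class TestMapTags:
    def test_exact_placement(self, rng):
        transcript = random_seq(rng, 200)
        tag = transcript[49:69]  # 1-based positions 50..69
        profiles = map_tags([tag], {"t1": transcript})
        assert profiles["t1"].counts == {50: 1.0}

    def test_multi_transcript_fractional(self, rng):
        shared = random_seq(rng, 20)
        t1 = shared + random_seq(rng, 100)
        t2 = random_seq(rng, 50) + shared + random_seq(rng, 50)
        profiles = map_tags([shared], {"t1": t1, "t2": t2})
        assert profiles["t1"].counts == {1: 0.5}
        assert profiles["t2"].counts == {51: 0.5}

    def test_short_and_unmapped_tags_discarded(self, rng):
        transcript = random_seq(rng, 100)
        profiles = map_tags(
            [transcript[:10], "A" * 20], {"t1": transcript.replace("A" * 20, "")[:90]}
        )
        assert profiles["t1"].total == 0

    def test_empty_transcript_set_rejected(self):
        with pytest.raises(ValueError):
            map_tags(["A" * 20], {})

    def test_norm_is_tp10m(self, rng):
        transcript = random_seq(rng, 100)
        profiles = map_tags([transcript[0:20], transcript[30:50]], {"t": transcript})
        assert profiles["t"].norm[1] == pytest.approx(1e7 / 2)

    def test_matches_bruteforce_substring_scan(self, rng):
        """Profile totals equal a leftmost-occurrence scan on 300 tags."""
        transcripts = {f"t{i}": random_seq(rng, 300) for i in range(4)}
        tags = []
        for _ in range(300):
            tid = f"t{rng.integers(4)}"
            start = int(rng.integers(0, 281))
            tags.append(transcripts[tid][start : start + 20])
        profiles = map_tags(tags, transcripts)
        brute = {tid: {} for tid in transcripts}
        for tag in tags:
            hits = [
                (tid, seq.find(tag) + 1)
                for tid, seq in transcripts.items()
                if tag in seq
            ]
            for tid, pos in hits:
                brute[tid][pos] = brute[tid].get(pos, 0.0) + 1.0 / len(hits)
        for tid in transcripts:
            assert profiles[tid].counts == pytest.approx(brute[tid])


class TestCuttingPower:
    def test_unique_maximum_scores_ten(self):
        p = make_profile({100: 90, 200: 2})
        assert cutting_power(p, 100) == 10

    def test_one_percent_site_scores_zero(self):
        p = make_profile({100: 100, 200: 1})
        assert cutting_power(p, 200) == 0

    def test_all_zero_profile_rejected_not_crashed(self):
        p = DegradomeProfile("t", "lib")
        assert cutting_power(p, 50) is None

    def test_matches_formula_oracle(self, rng):
        for _ in range(200):
            counts = {
                int(p): float(c)
                for p, c in zip(
                    rng.choice(500, size=30, replace=False), rng.integers(1, 200, 30)
                )
            }
            p = make_profile(counts)
            pos = int(rng.choice(list(counts)))
            assert cutting_power(p, pos) == oracles.cutting_power_brute(p.norm, pos)


class TestCategory:
    def test_unique_max_is_zero(self):
        assert assign_category(make_profile({100: 9, 200: 2}), 100) == 0

    def test_tied_max_is_one(self):
        assert assign_category(make_profile({100: 5, 200: 5}), 100) == 1

    def test_single_read_is_four(self):
        assert assign_category(make_profile({100: 9, 200: 1}), 200) == 4

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            assign_category(make_profile({100: 9}), 55)

    def test_matches_rank_and_median_oracle(self, rng):
        """1000 random profiles against an independent rank/median rule."""
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            counts = {
                int(p): float(c)
                for p, c in zip(
                    rng.choice(300, size=n, replace=False), rng.integers(1, 20, n)
                )
            }
            p = make_profile(counts)
            pos = int(rng.choice(list(counts)))
            assert assign_category(p, pos) == oracles.category_brute(counts, pos)


class TestScore:
    def test_perfect_duplex_at_unique_max_is_18(self):
        assert degradome_score(10, 0.0) == 18.0

    def test_floors_at_zero(self):
        assert degradome_score(0, 8.0) == 0.0
        assert degradome_score(0, 12.0) == 0.0

    def test_arithmetic(self):
        assert degradome_score(7, 2.5) == 12.5

    def test_bounds_hold_under_fuzz(self, rng):
        for _ in range(500):
            cp = int(rng.integers(0, 11))
            penalty = float(rng.uniform(0, 25))
            s = degradome_score(cp, penalty)
            assert 0.0 <= s <= 18.0


class TestRegion:
    MODEL = TranscriptModel("t", 100, utr5=(1, 20), cds=(21, 80), utr3=(81, 100))

    def test_inclusive_boundaries(self):
        assert annotate_region(21, self.MODEL) == "cds"
        assert annotate_region(80, self.MODEL) == "cds"
        assert annotate_region(81, self.MODEL) == "utr3"
        assert annotate_region(20, self.MODEL) == "utr5"

    def test_outside_model_rejected(self):
        with pytest.raises(ValueError):
            annotate_region(101, self.MODEL)

    def test_matches_interval_oracle(self, rng):
        intervals = {"utr5": (1, 20), "cds": (21, 80), "utr3": (81, 100)}
        for pos in rng.integers(1, 101, size=500):
            assert annotate_region(int(pos), self.MODEL) == oracles.region_brute(
                intervals, int(pos)
            )


class TestCallTargets:
    def test_planted_modules_recovered(self, small_dataset, small_profiles):
        ds = small_dataset
        models = {m.transcript_id: m for m in ds.models}
        candidates, tplots = call_targets(
            ds.mirnas, ds.sequences, models, small_profiles
        )
        found = {
            (c.alignment.mirna_name, c.alignment.transcript_id,
             c.alignment.cleavage_position, c.region, c.library_id)
            for c in candidates
        }
        for site in ds.truth.planted_sites:
            for organ in ds.degradome_libraries:
                assert (
                    site.mirna_name, site.transcript_id,
                    site.cleavage_position, site.region, organ,
                ) in found

    def test_decoy_mirnas_make_no_calls(self, small_dataset, small_profiles):
        ds = small_dataset
        models = {m.transcript_id: m for m in ds.models}
        decoys = simdata.make_decoy_mirnas(ds.config, 3)
        candidates, _ = call_targets(decoys, ds.sequences, models, small_profiles)
        assert candidates == []

    def test_min_score_above_max_empties_output(self, small_dataset, small_profiles):
        ds = small_dataset
        models = {m.transcript_id: m for m in ds.models}
        candidates, tplots = call_targets(
            ds.mirnas, ds.sequences, models, small_profiles, min_score=19.0
        )
        assert candidates == [] and tplots == {}

    def test_no_profiles_rejected(self, small_dataset):
        models = {m.transcript_id: m for m in small_dataset.models}
        with pytest.raises(ValueError):
            call_targets(
                small_dataset.mirnas, small_dataset.sequences, models, {}
            )

    def test_register_tolerance_one_base(self, rng):
        """A pileup one base 3' of the canonical slice position still calls."""
        mirna = MiRNARecord("m", random_seq(rng, 21))
        transcript = random_seq(rng, 80) + reverse_complement(mirna.sequence) + random_seq(rng, 80)
        model = TranscriptModel("t", len(transcript), cds=(1, len(transcript)))
        aln = align_site(mirna, "t", transcript, site_end=101)
        profiles = profiles_from_counts(
            {"t": {aln.cleavage_position + 1: 50.0, 10: 3.0}}
        )
        cand = score_candidate(aln, profiles["t"], model)
        assert cand is not None
        assert cand.register_offset == 1
        assert cand.degradome_score == 18.0

    def test_matches_exhaustive_bruteforce(self, rng):
        """Every (site, register) pair re-scored independently on a small
        instance reproduces call_targets exactly."""
        mirnas = [MiRNARecord("m1", random_seq(rng, 21)),
                  MiRNARecord("m2", random_seq(rng, 21))]
        transcripts = {}
        models = {}
        for tid in ("t1", "t2"):
            seq = random_seq(rng, 400)
            # embed a perfect site for m1 in t1
            if tid == "t1":
                seq = seq[:200] + reverse_complement(mirnas[0].sequence) + seq[221:]
            transcripts[tid] = seq
            models[tid] = TranscriptModel(
                tid, len(seq), utr5=(1, 60), cds=(61, 300), utr3=(301, len(seq))
            )
        counts = {
            tid: {
                int(p): float(c)
                for p, c in zip(
                    rng.choice(380, size=40, replace=False) + 1,
                    rng.integers(1, 30, 40),
                )
            }
            for tid in transcripts
        }
        counts["t1"][212] = 400.0  # cleavage position of the embedded site
        profiles = {"lib": profiles_from_counts(counts)}
        max_penalty, min_score, min_cat = 6.0, 5.0, 3
        got, _ = call_targets(
            mirnas, transcripts, models, profiles,
            max_penalty=max_penalty, min_score=min_score, min_category=min_cat,
        )
        got_set = {
            (c.alignment.mirna_name, c.alignment.transcript_id,
             c.alignment.cleavage_position, c.register_offset,
             c.degradome_score, c.category)
            for c in got
        }
        # independent re-derivation
        expected = set()
        lib_total = sum(sum(c.values()) for c in counts.values())
        for m in mirnas:
            for tid, seq in transcripts.items():
                for site_start, pen in oracles.scan_sites_brute(
                    m.sequence, seq, max_penalty
                ):
                    cleav = site_start + len(m.sequence) - 1 - 9
                    best = None
                    for off in (0, 1):
                        c = counts[tid].get(cleav + off, 0.0)
                        if c <= 0:
                            continue
                        norm = {p: v * 1e7 / lib_total for p, v in counts[tid].items()}
                        cp = oracles.cutting_power_brute(norm, cleav + off)
                        score = max(0.0, cp + 8.0 - pen)
                        cat = oracles.category_brute(counts[tid], cleav + off)
                        if best is None or (-score, cat) < (-best[2], best[3]):
                            best = (m.name, tid, cleav, off, score, cat)
                    if best and best[4] >= min_score and best[5] <= min_cat:
                        expected.add((best[0], best[1], cleav, best[3], best[4], best[5]))
        assert got_set == expected

    def test_category_zero_implies_full_cutting_power(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 10))
            counts = {
                int(p): float(c)
                for p, c in zip(
                    rng.choice(300, size=n, replace=False), rng.integers(1, 40, n)
                )
            }
            p = make_profile(counts)
            for pos in counts:
                if assign_category(p, pos) == 0:
                    assert cutting_power(p, pos) == 10

    def test_spike_fraction_monotonicity(self):
        """Raising the planted spike never lowers the site's score."""
        scores = []
        for spike in (0.1, 0.5, 0.9):
            cfg = simdata.SimulationConfig(seed=5, spike_fraction=spike)
            sequences, models_list = simdata.generate_transcriptome(cfg)
            mirnas = simdata.generate_mirnas(cfg)
            truth = simdata.plant_target_sites(cfg, sequences, models_list, mirnas)
            tags = simdata.simulate_degradome_library(cfg, sequences, truth, "Mv")
            profiles = {"Mv": map_tags([s for _, s in tags], sequences, "Mv")}
            models = {m.transcript_id: m for m in models_list}
            cands, _ = call_targets(
                mirnas, sequences, models, profiles, min_score=0.0, min_category=4
            )
            site = truth.planted_sites[0]
            score = max(
                (c.degradome_score for c in cands
                 if c.alignment.mirna_name == site.mirna_name
                 and c.alignment.cleavage_position == site.cleavage_position),
                default=0.0,
            )
            scores.append(score)
        assert scores == sorted(scores)

    def test_tplot_rows_cover_signal_and_flag_candidates(
        self, small_dataset, small_profiles
    ):
        ds = small_dataset
        models = {m.transcript_id: m for m in ds.models}
        candidates, tplots = call_targets(
            ds.mirnas, ds.sequences, models, small_profiles
        )
        assert tplots
        for (lib, tid), tp in tplots.items():
            profile = small_profiles[lib][tid]
            assert set(tp.rows["position"]) == set(profile.norm)
            flagged = set(tp.rows.loc[tp.rows["is_candidate"], "position"])
            expected = {
                c.alignment.cleavage_position + c.register_offset
                for c in candidates
                if c.library_id == lib and c.alignment.transcript_id == tid
            }
            assert flagged == expected
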