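"""Degradome (PARE) profiles, cleavage scoring and T-plot data.

A degradome library is a set of 5'-end tags from uncapped mRNA fragments.
Tags are placed on transcripts by exact substring search; the 5'-end start
coordinate of each placement increments that transcript's positional count
(tags hitting k transcripts contribute 1/k to each).  Profiles are
normalized to tags-per-ten-million (TP10M) within each library.

A candidate slice site combines two components into the composite
degradome score reported on a 0-18 scale:

* cutting power CP in {0..10}: how dominant the site's 5'-end peak is
  within its transcript, CP = round(10 * norm[pos] / max(norm));
* compliance, 8 - duplex penalty (1 point per mismatch, 0.5 per G:U
  wobble), so a perfect duplex contributes 8;

score = max(0, CP + 8 - penalty_total), hence the 0-18 range: 18 is a
perfect duplex at a unique transcript-wide maximum, and heavily mismatched
sites floor at 0.  Each candidate also carries a five-level category (the
rank class of its cleavage position among the transcript's degradome
positions: 0 unique maximum, 1 tied maximum, 2 above the median of
occupied positions, 3 at/below it, 4 single-read evidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .duplex import DuplexAlignment, compliance_score, find_candidate_sites
from .models import MiRNARecord, TranscriptModel, canonical_dna

MIN_TAG_LEN = 15
CUTTING_POWER_MAX = 10
SCORE_MAX = 18.0
DEFAULT_MIN_SCORE = 10.0
DEFAULT_MAX_CATEGORY = 2
#: extra downstream registers examined per candidate (tag starts one base
#: 3' of the canonical slice position are tolerated)
REGISTER_TOLERANCE = 1


@dataclass
class DegradomeProfile:
    """Per-transcript degradome 5'-end counts by 1-based position."""

    transcript_id: str
    library_id: str
    counts: Dict[int, float] = field(default_factory=dict)
    norm: Dict[int, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def max_norm(self) -> float:
        return max(self.norm.values(), default=0.0)


@dataclass
class CleavageCandidate:
    alignment: DuplexAlignment
    library_id: str
    cutting_power: int
    category: int
    degradome_score: float
    region: str
    site_raw_reads: float
    site_norm_reads: float
    register_offset: int = 0  # 0 = canonical slice position, 1 = one base 3'

    @property
    def cleavage_position(self) -> int:
        return self.alignment.cleavage_position


@dataclass
class TPlotData:
    """Rows of (position, norm_reads, is_candidate) for one transcript."""

    transcript_id: str
    library_id: str
    rows: pd.DataFrame
    annotations: List[Tuple[str, int]] = field(default_factory=list)


def map_tags(
    tags: Iterable[str],
    transcripts: Mapping[str, str],
    library_id: str = "lib",
) -> Dict[str, DegradomeProfile]:
    """Assign tags to transcripts by exact substring search.

    Each tag's leftmost occurrence per transcript is used; a tag matching k
    transcripts adds 1/k at each start position.  Tags below 15 nt or
    matching nowhere are discarded.  Norm is TP10M over the library's
    mapped-tag total.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    seqs = {tid: canonical_dna(s) for tid, s in transcripts.items()}
    profiles = {
        tid: DegradomeProfile(transcript_id=tid, library_id=library_id)
        for tid in seqs
    }
    # exact-lookup index, built lazily per tag length
    index_by_len: Dict[int, Dict[str, List[Tuple[str, int]]]] = {}

    def index_for(length: int) -> Dict[str, List[Tuple[str, int]]]:
        idx = index_by_len.get(length)
        if idx is None:
            idx = {}
            for tid, seq in seqs.items():
                seen = set()
                for start0 in range(len(seq) - length + 1):
                    sub = seq[start0 : start0 + length]
                    if (sub, tid) in seen:
                        continue
                    # leftmost occurrence per transcript only
                    hits = idx.setdefault(sub, [])
                    if not any(h[0] == tid for h in hits):
                        hits.append((tid, start0 + 1))
                    seen.add((sub, tid))
            index_by_len[length] = idx
        return idx

    for tag in tags:
        tag = canonical_dna(tag)
        if len(tag) < MIN_TAG_LEN:
            continue
        hits = index_for(len(tag)).get(tag)
        if not hits:
            continue
        weight = 1.0 / len(hits)
        for tid, pos in hits:
            counts = profiles[tid].counts
            counts[pos] = counts.get(pos, 0.0) + weight
    mapped_total = sum(p.total for p in profiles.values())
    if mapped_total > 0:
        for p in profiles.values():
            p.norm = {pos: c * 1e7 / mapped_total for pos, c in p.counts.items()}
    return profiles


def profiles_from_counts(
    counts: Mapping[str, Mapping[int, float]], library_id: str = "lib"
) -> Dict[str, DegradomeProfile]:
    """Build profiles from pre-computed per-position counts (aligner import)."""
    profiles = {
        tid: DegradomeProfile(tid, library_id, counts=dict(c))
        for tid, c in counts.items()
    }
    total = sum(p.total for p in profiles.values())
    if total > 0:
        for p in profiles.values():
            p.norm = {pos: c * 1e7 / total for pos, c in p.counts.items()}
    return profiles


def read_count_table(path: str, library_id: str = "lib") -> Dict[str, DegradomeProfile]:
    """TSV (transcript_id, position, count) -> profiles."""
    df = pd.read_csv(path, sep="\t")
    grouped: Dict[str, Dict[int, float]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault(row.transcript_id, {})[int(row.position)] = float(row.count)
    return profiles_from_counts(grouped, library_id)


def cutting_power(profile: DegradomeProfile, position: int) -> Optional[int]:
    """CP = round(10 * norm[position] / max(norm)), half-up.

    Returns None for an all-zero profile (no cleavage evidence at all):
    the candidate is rejected rather than scored.
    """
    peak = profile.max_norm()
    if peak <= 0:
        return None
    value = profile.norm.get(position, 0.0)
    return int(math.floor(CUTTING_POWER_MAX * value / peak + 0.5))


def assign_category(profile: DegradomeProfile, position: int) -> int:
    """Five-level rank class of a cleavage position within its transcript."""
    count = profile.counts.get(position, 0.0)
    if count <= 0:
        raise ValueError(
            f"no degradome evidence at {profile.transcript_id}:{position}"
        )
    if count <= 1:
        return 4
    values = np.array([c for c in profile.counts.values() if c > 0], dtype=float)
    peak = values.max()
    if count == peak:
        return 0 if (values == peak).sum() == 1 else 1
    median = float(np.median(values))
    return 2 if count > median else 3


def degradome_score(cp: int, penalty_total: float) -> float:
    """Composite score, clamped to the reported [0, 18] range."""
    return max(0.0, cp + 8.0 - penalty_total)


def annotate_region(position: int, model: TranscriptModel) -> str:
    """Region (utr5/cds/utr3) containing the cleavage position."""
    return model.region_of(position)


def score_candidate(
    alignment: DuplexAlignment,
    profile: DegradomeProfile,
    model: TranscriptModel,
    register_tolerance: int = REGISTER_TOLERANCE,
) -> Optional[CleavageCandidate]:
    """Evaluate one duplex site against a degradome profile.

    Registers 0..register_tolerance downstream of the canonical slice
    position are tried and the best-scoring kept (score desc, category
    asc).  Returns None when no register carries any tag.
    """
    best: Optional[CleavageCandidate] = None
    for offset in range(register_tolerance + 1):
        pos = alignment.cleavage_position + offset
        if profile.counts.get(pos, 0.0) <= 0:
            continue
        cp = cutting_power(profile, pos)
        if cp is None:
            continue
        cand = CleavageCandidate(
            alignment=alignment,
            library_id=profile.library_id,
            cutting_power=cp,
            category=assign_category(profile, pos),
            degradome_score=degradome_score(cp, alignment.penalty_total),
            region=annotate_region(alignment.cleavage_position, model),
            site_raw_reads=profile.counts[pos],
            site_norm_reads=profile.norm[pos],
            register_offset=offset,
        )
        if best is None or (-cand.degradome_score, cand.category) < (
            -best.degradome_score,
            best.category,
        ):
            best = cand
    return best


def call_targets(
    mirnas: Sequence[MiRNARecord],
    transcripts: Mapping[str, str],
    models: Mapping[str, TranscriptModel],
    profiles_by_library: Mapping[str, Mapping[str, DegradomeProfile]],
    max_penalty: float = 4.0,
    min_score: float = DEFAULT_MIN_SCORE,
    min_category: int = DEFAULT_MAX_CATEGORY,
    register_tolerance: int = REGISTER_TOLERANCE,
) -> Tuple[List[CleavageCandidate], Dict[Tuple[str, str], TPlotData]]:
    """Join duplex candidate sites with degradome evidence, per library.

    Retains candidates with degradome_score >= min_score and category <=
    min_category, sorted by (score desc, category asc, penalty asc); emits
    T-plot data for every (library, transcript) with a reported candidate.
    """
    if not profiles_by_library:
        raise ValueError("no degradome profiles supplied")
    # duplex scan once per (miRNA, transcript); reused across libraries
    sites: Dict[str, List[DuplexAlignment]] = {}
    for mirna in mirnas:
        for tid, seq in transcripts.items():
            if len(seq) < len(mirna.sequence):
                continue
            sites.setdefault(tid, []).extend(
                find_candidate_sites(mirna, tid, seq, max_penalty=max_penalty)
            )
    results: List[CleavageCandidate] = []
    for library_id, profiles in profiles_by_library.items():
        for tid, alignments in sites.items():
            profile = profiles.get(tid)
            if profile is None or profile.total <= 0:
                continue
            for aln in alignments:
                cand = score_candidate(
                    aln, profile, models[tid], register_tolerance=register_tolerance
                )
                if cand is None:
                    continue
                if cand.degradome_score >= min_score and cand.category <= min_category:
                    results.append(cand)
    results.sort(
        key=lambda c: (
            -c.degradome_score,
            c.category,
            c.alignment.penalty_total,
            c.library_id,
            c.alignment.transcript_id,
            c.alignment.cleavage_position,
        )
    )
    tplots: Dict[Tuple[str, str], TPlotData] = {}
    for cand in results:
        key = (cand.library_id, cand.alignment.transcript_id)
        if key not in tplots:
            profile = profiles_by_library[cand.library_id][cand.alignment.transcript_id]
            rows = pd.DataFrame(
                sorted(profile.norm.items()), columns=["position", "norm_reads"]
            )
            rows["is_candidate"] = False
            tplots[key] = TPlotData(
                transcript_id=cand.alignment.transcript_id,
                library_id=cand.library_id,
                rows=rows,
            )
        tp = tplots[key]
        flagged = cand.alignment.cleavage_position + cand.register_offset
        tp.rows.loc[tp.rows["position"] == flagged, "is_candidate"] = True
        tp.annotations.append(
            (cand.alignment.mirna_name, cand.alignment.cleavage_position)
        )
    return results, tplots


def candidates_table(candidates: Sequence[CleavageCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        a = c.alignment
        rows.append(
            {
                "mirna": a.mirna_name,
                "transcript_id": a.transcript_id,
                "library": c.library_id,
                "site_start": a.site_start,
                "site_end": a.site_end,
                "cleavage_position": a.cleavage_position,
                "register_offset": c.register_offset,
                "pair_string": a.pair_string,
                "penalty_total": a.penalty_total,
                "compliance": compliance_score(a),
                "cutting_power": c.cutting_power,
                "category": c.category,
                "degradome_score": c.degradome_score,
                "region": c.region,
                "site_raw_reads": c.site_raw_reads,
                "site_norm_reads": c.site_norm_reads,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "transcript_id", "library", "site_start", "site_end",
            "cleavage_position", "register_offset", "pair_string",
            "penalty_total", "compliance", "cutting_power", "category",
            "degradome_score", "region", "site_raw_reads", "site_norm_reads",
        ],
    )


def plot_tplot(tplot: TPlotData, path: str) -> None:
    """Write a T-plot figure: normalized 5'-end reads vs position, with the
    candidate slice positions arrowed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.vlines(
        tplot.rows["position"], 0, tplot.rows["norm_reads"],
        color="0.6", linewidth=1,
    )
    peak = tplot.rows["norm_reads"].max() if len(tplot.rows) else 1.0
    for name, pos in tplot.annotations:
        y = float(
            tplot.rows.loc[tplot.rows["position"] == pos, "norm_reads"].max()
        ) if (tplot.rows["position"] == pos).any() else 0.0
        ax.annotate(
            name,
            xy=(pos, y),
            xytext=(pos, y + 0.15 * peak),
            arrowprops=dict(arrowstyle="->", color="red"),
            color="red", ha="center", fontsize=8,
        )
    ax.set_xlabel(f"{tplot.transcript_id} position (nt)")
    ax.set_ylabel("degradome 5' ends (TP10M)")
    ax.set_title(f"T-plot: {tplot.transcript_id} [{tplot.library_id}]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
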