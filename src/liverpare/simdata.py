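"""Synthetic datasets with planted miRNA-target modules.

The generator emulates the study design the pipeline is built for: four
*Marchantia* organ conditions (male/female vegetative thallus Mv/Fv,
antheridiophore Ma, archegoniophore Fa) x 3 replicates of sRNA-seq,
one degradome (PARE) library per organ, and an RT-qPCR Ct table.  Each
configured miRNA gets an organ-specific abundance, a target transcript
with its exact reverse complement planted in a chosen region
(predominantly the 3'UTR), a degradome tag pileup spiked at the planted
slice position, and a target whose relative expression falls as the
miRNA's abundance rises (RQ = 1 / (1 + a * RPM / 1000), normalized to the
calibrator organ).

Every random draw flows from ``SimulationConfig.seed`` through named
sub-streams, so an identical config reproduces byte-identical files.

miRNA abundances are interpreted in RPM of *retained* (18-28 nt) reads —
the unit the quantifier reports — so per-read sampling probabilities are
calibrated for the fraction of background inserts (random 15-35 nt) that
survive the length filter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .models import (
    ORGANS,
    REGIONS,
    MiRNARecord,
    TranscriptModel,
    canonical_dna,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: slice site opposite miRNA position 10: cleavage = site_end - 9
CLEAVAGE_OFFSET_FROM_SITE_END = 9

REFERENCE_GENE = "MpACT7"
CALIBRATOR_ORGAN = "Mv"
#: constant Illumina read length emulated for sRNA libraries
SRNA_READ_LENGTH = 50
BACKGROUND_INSERT_RANGE = (15, 35)
MIN_DEGRADOME_TAG_LEN = 15


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MiRNASpec:
    """One planted miRNA-target module."""

    name: str
    length: int
    target_transcript: str
    target_region: str  # utr5 | cds | utr3
    abundance: Mapping[str, float]  # organ -> RPM (of retained reads)
    sequence: Optional[str] = None  # drawn from the seeded stream if None


# Default cast: three organ-enriched miRNAs, two with 3'UTR slice sites and
# one with a CDS site.  Organ profiles are well separated (rank-adjacent
# values differ by >= ~1.5x, and every value is either >= 600 RPM or below
# 100) so that sampling noise at the default library size cannot blur the
# organ ranking the inverse-correlation readout depends on.
DEFAULT_MIRNA_SPECS: Tuple[MiRNASpec, ...] = (
    MiRNASpec("MpmiR11737a", 21, "T0001", "utr3",
              {"Mv": 600.0, "Ma": 3300.0, "Fv": 1200.0, "Fa": 2000.0}),
    MiRNASpec("MpmiR11865", 21, "T0002", "utr3",
              {"Mv": 2000.0, "Ma": 600.0, "Fv": 1200.0, "Fa": 50.0}),
    MiRNASpec("MpmiR160", 20, "T0003", "cds",
              {"Mv": 1200.0, "Ma": 3300.0, "Fv": 90.0, "Fa": 600.0}),
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 20
    transcript_length_range: Tuple[int, int] = (500, 1500)
    utr5_frac: float = 0.15
    cds_frac: float = 0.60
    utr3_frac: float = 0.25
    mirna_specs: Tuple[MiRNASpec, ...] = DEFAULT_MIRNA_SPECS
    n_replicates: int = 3
    library_size: int = 1_000_000
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"  # Illumina TruSeq small-RNA 3'
    degradome_tag_length: int = 20
    spike_fraction: float = 0.4
    background_decay: float = 2.0  # mean background tags per position
    ct_noise_sd: float = 0.15
    inverse_gain: float = 2.0

    def validate(self) -> None:
        fracs = (self.utr5_frac, self.cds_frac, self.utr3_frac)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"region fractions must be non-negative and sum to 1, got {fracs}"
            )
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be >= 1")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError(
                f"invalid transcript_length_range {self.transcript_length_range}"
            )
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ConfigurationError("spike_fraction must lie in [0, 1]")
        if self.background_decay < 0 or self.ct_noise_sd < 0:
            raise ConfigurationError("rates and noise sds must be non-negative")
        if self.inverse_gain <= 0:
            raise ConfigurationError("inverse_gain must be positive")
        if self.degradome_tag_length < MIN_DEGRADOME_TAG_LEN:
            raise ConfigurationError(
                f"degradome_tag_length must be >= {MIN_DEGRADOME_TAG_LEN}"
            )
        names = [s.name for s in self.mirna_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate miRNA names")
        targets = [s.target_transcript for s in self.mirna_specs]
        if len(set(targets)) != len(targets):
            raise ConfigurationError(
                "each miRNA needs its own target transcript (shared targets "
                "would make the qPCR ground truth ambiguous)"
            )
        for s in self.mirna_specs:
            if not 18 <= s.length <= 28:
                raise ConfigurationError(
                    f"{s.name}: mature length {s.length} outside [18, 28]"
                )
            if s.target_region not in REGIONS:
                raise ConfigurationError(
                    f"{s.name}: unknown target region {s.target_region!r}"
                )
            if any(a < 0 for a in s.abundance.values()):
                raise ConfigurationError(f"{s.name}: negative abundance")
            missing = set(ORGANS) - set(s.abundance)
            if missing:
                raise ConfigurationError(
                    f"{s.name}: abundance missing organs {sorted(missing)}"
                )
            if s.sequence is not None and len(canonical_dna(s.sequence)) != s.length:
                raise ConfigurationError(f"{s.name}: sequence/length mismatch")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        specs = raw.pop("mirna_specs", None)
        if specs is not None:
            raw["mirna_specs"] = tuple(MiRNASpec(**s) for s in specs)
        if "transcript_length_range" in raw:
            raw["transcript_length_range"] = tuple(raw["transcript_length_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class PlantedSite:
    mirna_name: str
    transcript_id: str
    cleavage_position: int  # 1-based
    region: str
    site_start: int
    site_end: int


@dataclass
class GroundTruth:
    planted_sites: List[PlantedSite]
    true_abundance: pd.DataFrame  # organs x miRNAs, RPM
    true_rq: pd.DataFrame  # organs x target transcripts, calibrator-normalized


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _transcript_id(i: int) -> str:
    return f"T{i:04d}"


def generate_mirnas(cfg: SimulationConfig) -> List[MiRNARecord]:
    """Mature miRNA records; unspecified sequences come from the seeded
    stream (re-drawn if they collide or contain the adapter seed)."""
    rng = _rng(cfg, 1)
    seed8 = cfg.adapter[:8].upper()
    seen = set()
    out = []
    for spec in cfg.mirna_specs:
        if spec.sequence is not None:
            seq = canonical_dna(spec.sequence)
        else:
            while True:
                seq = _random_seq(rng, spec.length)
                if seq not in seen and seed8 not in seq:
                    break
        if seq in seen:
            raise ConfigurationError(f"duplicate mature sequence for {spec.name}")
        seen.add(seq)
        out.append(MiRNARecord(spec.name, seq))
    return out


def generate_transcriptome(
    cfg: SimulationConfig,
) -> Tuple[Dict[str, str], List[TranscriptModel]]:
    """Random transcripts with contiguous utr5/cds/utr3 tiling [1, length]."""
    cfg.validate()
    rng = _rng(cfg, 0)
    lo, hi = cfg.transcript_length_range
    sequences: Dict[str, str] = {}
    models: List[TranscriptModel] = []
    for i in range(1, cfg.n_transcripts + 1):
        length = int(rng.integers(lo, hi + 1))
        tid = _transcript_id(i)
        sequences[tid] = _random_seq(rng, length)
        utr5_len = int(round(cfg.utr5_frac * length))
        cds_len = int(round(cfg.cds_frac * length))
        if utr5_len + cds_len > length:
            cds_len = length - utr5_len
        utr3_len = length - utr5_len - cds_len
        model = TranscriptModel(tid, length)
        pos = 1
        for region, rlen in (("utr5", utr5_len), ("cds", cds_len), ("utr3", utr3_len)):
            if rlen > 0:
                setattr(model, region, (pos, pos + rlen - 1))
                pos += rlen
        model.validate_tiling()
        models.append(model)
    by_id = {m.transcript_id: m for m in models}
    for spec in cfg.mirna_specs:
        model = by_id.get(spec.target_transcript)
        if model is None:
            raise ConfigurationError(
                f"{spec.name}: target transcript {spec.target_transcript} "
                f"not generated (n_transcripts={cfg.n_transcripts})"
            )
        iv = model.interval(spec.target_region)
        if iv is None or iv[1] - iv[0] + 1 < spec.length:
            raise ConfigurationError(
                f"{spec.name}: region {spec.target_region} of "
                f"{spec.target_transcript} absent or shorter than the "
                f"{spec.length}-nt miRNA"
            )
    return sequences, models


def plant_target_sites(
    cfg: SimulationConfig,
    sequences: Dict[str, str],
    models: Sequence[TranscriptModel],
    mirnas: Sequence[MiRNARecord],
    n_mismatches: int = 0,
) -> GroundTruth:
    """Edit target transcripts to contain each miRNA's complementary site.

    The planted site is the miRNA's exact reverse complement (with
    ``n_mismatches`` positions mutated if requested); the recorded
    cleavage position is the transcript base paired to miRNA position 10,
    i.e. site_end - 9.
    """
    rng = _rng(cfg, 2)
    by_id = {m.transcript_id: m for m in models}
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    planted: List[PlantedSite] = []
    for spec, mirna in zip(cfg.mirna_specs, mirnas):
        model = by_id[spec.target_transcript]
        iv = model.interval(spec.target_region)
        L = spec.length
        if iv is None or iv[1] - iv[0] + 1 < L:
            raise ConfigurationError(
                f"{spec.name}: region {spec.target_region} of "
                f"{spec.target_transcript} shorter than the miRNA"
            )
        # the cleaved 3' fragment must support a mappable (>= 15 nt) tag,
        # so the slice position may not sit in the transcript's last 14 nt
        site_end_max = min(
            iv[1],
            model.length - MIN_DEGRADOME_TAG_LEN + 1 + CLEAVAGE_OFFSET_FROM_SITE_END,
        )
        if site_end_max - L + 1 < iv[0]:
            raise ConfigurationError(
                f"{spec.name}: region {spec.target_region} of "
                f"{spec.target_transcript} too close to the 3' end to plant a "
                "site with a mappable cleavage fragment"
            )
        taken = occupied.setdefault(spec.target_transcript, [])
        for _ in range(200):
            site_start = int(rng.integers(iv[0], site_end_max - L + 2))
            site_end = site_start + L - 1
            if all(site_end < a or site_start > b for a, b in taken):
                break
        else:
            raise ConfigurationError(
                f"could not place {spec.name} without overlapping another site"
            )
        taken.append((site_start, site_end))
        site_seq = list(reverse_complement(mirna.sequence))
        if n_mismatches:
            for idx in rng.choice(L, size=min(n_mismatches, L), replace=False):
                alternatives = [b for b in "ACGT" if b != site_seq[int(idx)]]
                site_seq[int(idx)] = alternatives[int(rng.integers(len(alternatives)))]
        seq = sequences[spec.target_transcript]
        sequences[spec.target_transcript] = (
            seq[: site_start - 1] + "".join(site_seq) + seq[site_end:]
        )
        cleavage = site_end - CLEAVAGE_OFFSET_FROM_SITE_END
        planted.append(
            PlantedSite(
                mirna_name=spec.name,
                transcript_id=spec.target_transcript,
                cleavage_position=cleavage,
                region=model.region_of(cleavage),
                site_start=site_start,
                site_end=site_end,
            )
        )
    abundance = pd.DataFrame(
        {spec.name: [spec.abundance[o] for o in ORGANS] for spec in cfg.mirna_specs},
        index=list(ORGANS),
    )
    raw_rq = pd.DataFrame(
        {
            spec.target_transcript: 1.0
            / (1.0 + cfg.inverse_gain * abundance[spec.name] / 1000.0)
            for spec in cfg.mirna_specs
        },
        index=list(ORGANS),
    )
    true_rq = raw_rq / raw_rq.loc[CALIBRATOR_ORGAN]
    return GroundTruth(planted_sites=planted, true_abundance=abundance, true_rq=true_rq)


def _background_retention() -> float:
    lo, hi = BACKGROUND_INSERT_RANGE
    lengths = np.arange(lo, hi + 1)
    kept = ((lengths >= 18) & (lengths <= 28)).sum()
    return kept / len(lengths)


def mirna_read_probability(cfg: SimulationConfig, truth: GroundTruth, organ: str) -> pd.Series:
    """Per-read sampling probability of each miRNA in one organ's library.

    Calibrated so the expected RPM *among retained 18-28 nt reads* equals
    the configured abundance: with s = sum(RPM)/1e6 and rho the background
    length-filter retention, overall retention R solves R = s*R + (1-s*R)*rho,
    and q_m = RPM_m/1e6 * R.
    """
    rpm = truth.true_abundance.loc[organ]
    s = rpm.sum() / 1e6
    rho = _background_retention()
    R = rho / (1.0 - s * (1.0 - rho))
    q = rpm / 1e6 * R
    if q.sum() >= 1.0:
        raise ConfigurationError("configured abundances exceed the library")
    return q


def simulate_srna_library(
    cfg: SimulationConfig,
    truth: GroundTruth,
    mirnas: Sequence[MiRNARecord],
    organ: str,
    replicate: int,
) -> List[Tuple[str, str]]:
    """One organ x replicate sRNA library as (read_id, sequence) pairs.

    Each read is a miRNA copy (multinomial in its organ abundance) or a
    random background insert of 15-35 nt, 3'-ligated to the adapter and
    truncated/padded to the constant read length.
    """
    if organ not in ORGANS:
        raise ConfigurationError(f"unknown organ {organ!r}")
    rng = _rng(cfg, 10, ORGANS.index(organ), replicate)
    q = mirna_read_probability(cfg, truth, organ)
    probs = np.append(q.to_numpy(), 1.0 - q.sum())
    counts = rng.multinomial(cfg.library_size, probs)
    inserts: List[str] = []
    for mirna, k in zip(mirnas, counts[:-1]):
        inserts.extend([mirna.sequence] * int(k))
    n_bg = int(counts[-1])
    if n_bg:
        lo, hi = BACKGROUND_INSERT_RANGE
        lengths = rng.integers(lo, hi + 1, size=n_bg)
        mat = _BASES[rng.integers(0, 4, size=(n_bg, hi))]
        raw = mat.tobytes().decode()
        inserts.extend(
            raw[i * hi : i * hi + int(lengths[i])] for i in range(n_bg)
        )
    order = rng.permutation(len(inserts))
    adapter = cfg.adapter.upper()
    reads = []
    for out_i, idx in enumerate(order):
        full = inserts[idx] + adapter
        if len(full) < SRNA_READ_LENGTH:
            full += "A" * (SRNA_READ_LENGTH - len(full))
        reads.append((f"{organ}_r{replicate}_{out_i + 1}", full[:SRNA_READ_LENGTH]))
    return reads


def simulate_degradome_library(
    cfg: SimulationConfig,
    sequences: Mapping[str, str],
    truth: GroundTruth,
    organ: str,
) -> List[Tuple[str, str]]:
    """One organ's PARE tag library as (tag_id, sequence) pairs.

    Per transcript, tag count is Poisson(background_decay * n_positions);
    target transcripts route spike_fraction of tags to the planted
    cleavage position, the rest uniformly over valid 5'-end starts.
    """
    if organ not in ORGANS:
        raise ConfigurationError(f"unknown organ {organ!r}")
    rng = _rng(cfg, 20, ORGANS.index(organ))
    spikes = {
        s.transcript_id: s.cleavage_position for s in truth.planted_sites
    }
    tags: List[Tuple[str, str]] = []
    i = 0
    for tid in sorted(sequences):
        seq = sequences[tid]
        n_pos = len(seq) - MIN_DEGRADOME_TAG_LEN + 1
        if n_pos < 1:
            continue
        n_tags = int(rng.poisson(cfg.background_decay * n_pos))
        if n_tags == 0:
            continue
        probs = np.full(n_pos, 1.0 / n_pos)
        spike_pos = spikes.get(tid)
        if spike_pos is not None and spike_pos <= n_pos:
            probs *= 1.0 - cfg.spike_fraction
            probs[spike_pos - 1] += cfg.spike_fraction
        counts = rng.multinomial(n_tags, probs)
        for pos0 in np.nonzero(counts)[0]:
            tag_seq = seq[pos0 : pos0 + cfg.degradome_tag_length]
            for _ in range(int(counts[pos0])):
                i += 1
                tags.append((f"{organ}_tag{i}", tag_seq))
    return tags


def simulate_ct_table(cfg: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Ct table (organ, replicate, gene, ct) for targets + reference gene.

    Ct of a target falls by one cycle per doubling of its true RQ
    (perfect amplification efficiency): Ct = base - log2(RQ) + noise.
    The reference gene is constant across organs and replicates; the
    Gaussian Ct noise applies to the target measurements.
    """
    rng = _rng(cfg, 30)
    rows = []
    targets = list(truth.true_rq.columns)
    for organ in ORGANS:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append(
                {
                    "organ": organ, "replicate": rep, "gene": REFERENCE_GENE,
                    "ct": 20.0,
                }
            )
            for gene in targets:
                rq = truth.true_rq.loc[organ, gene]
                rows.append(
                    {
                        "organ": organ, "replicate": rep, "gene": gene,
                        "ct": 25.0 - np.log2(rq) + rng.normal(0.0, cfg.ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows, columns=["organ", "replicate", "gene", "ct"])


def make_decoy_mirnas(cfg: SimulationConfig, n: int, length: int = 21) -> List[MiRNARecord]:
    """Random mature sequences with no planted site (negative controls)."""
    rng = _rng(cfg, 40)
    return [MiRNARecord(f"decoy{i + 1}", _random_seq(rng, length)) for i in range(n)]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sequences: Dict[str, str]
    models: List[TranscriptModel]
    mirnas: List[MiRNARecord]
    truth: GroundTruth
    srna_libraries: Dict[Tuple[str, int], List[Tuple[str, str]]] = field(default_factory=dict)
    degradome_libraries: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)
    ct_table: Optional[pd.DataFrame] = None


def simulate_dataset(
    cfg: SimulationConfig,
    with_srna: bool = True,
    with_degradome: bool = True,
    with_ct: bool = True,
) -> SimulatedDataset:
    """Run the whole generator; heavy stages can be switched off."""
    cfg.validate()
    sequences, models = generate_transcriptome(cfg)
    mirnas = generate_mirnas(cfg)
    truth = plant_target_sites(cfg, sequences, models, mirnas)
    ds = SimulatedDataset(cfg, sequences, models, mirnas, truth)
    if with_srna:
        for organ in ORGANS:
            for rep in range(1, cfg.n_replicates + 1):
                ds.srna_libraries[(organ, rep)] = simulate_srna_library(
                    cfg, truth, mirnas, organ, rep
                )
    if with_degradome:
        for organ in ORGANS:
            ds.degradome_libraries[organ] = simulate_degradome_library(
                cfg, sequences, truth, organ
            )
    if with_ct:
        ds.ct_table = simulate_ct_table(cfg, truth)
    return ds


def write_dataset(ds: SimulatedDataset, outdir: str) -> None:
    from . import io as lio

    os.makedirs(outdir, exist_ok=True)
    lio.write_fasta(
        os.path.join(outdir, "transcripts.fa"), sorted(ds.sequences.items())
    )
    lio.write_transcript_models(
        os.path.join(outdir, "transcript_models.gff3"), ds.models
    )
    lio.write_fasta(
        os.path.join(outdir, "mirnas.fa"), [(m.name, m.sequence) for m in ds.mirnas]
    )
    if ds.srna_libraries:
        srna_dir = os.path.join(outdir, "srna")
        os.makedirs(srna_dir, exist_ok=True)
        for (organ, rep), reads in sorted(ds.srna_libraries.items()):
            lio.write_fastq(os.path.join(srna_dir, f"{organ}_rep{rep}.fastq"), reads)
    if ds.degradome_libraries:
        deg_dir = os.path.join(outdir, "degradome")
        os.makedirs(deg_dir, exist_ok=True)
        for organ, tags in sorted(ds.degradome_libraries.items()):
            lio.write_fasta(os.path.join(deg_dir, f"{organ}.fa"), tags)
    if ds.ct_table is not None:
        ds.ct_table.to_csv(os.path.join(outdir, "ct_table.tsv"), sep="\t", index=False)
    pd.DataFrame([s.__dict__ for s in ds.truth.planted_sites]).to_csv(
        os.path.join(outdir, "planted_sites.tsv"), sep="\t", index=False
    )
    ds.truth.true_abundance.to_csv(
        os.path.join(outdir, "true_abundance.tsv"), sep="\t", index_label="organ"
    )
    ds.truth.true_rq.to_csv(
        os.path.join(outdir, "true_rq.tsv"), sep="\t", index_label="organ"
    )
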