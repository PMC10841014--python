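"""Gapless antiparallel miRNA:mRNA duplex alignment and compliance scoring.

Pairing follows the de-facto plant target-prediction conventions: each
position is Watson-Crick (W), G:U wobble (G, penalty 0.5) or mismatch
(M, penalty 1.0); no bulges, no positional weighting.  The miRNA is read
5'->3'; its position i pairs transcript position site_end - i + 1, and the
slice site sits opposite miRNA position 10 (the canonical AGO register),
i.e. at transcript coordinate site_end - 9.

``compliance_score`` is the complementarity half of the composite degradome
score: 8 minus the penalty total (clamping to the reported 0-18 range
happens only when the full score is assembled in :mod:`liverpare.degradome`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .models import MiRNARecord, canonical_dna

#: penalty per pair class
PENALTY_MISMATCH = 1.0
PENALTY_WOBBLE = 0.5
#: maximum compliance (perfect duplex)
COMPLIANCE_MAX = 8.0

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
# G:U in RNA space: miRNA G opposite target T(U), or miRNA T(U) opposite target G
_WOBBLE = {("G", "T"), ("T", "G")}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class DuplexAlignment:
    mirna_name: str
    transcript_id: str
    site_start: int  # 1-based inclusive
    site_end: int
    pair_string: str  # from miRNA 5' end; symbols W / G / M
    penalty_total: float
    cleavage_position: int  # transcript base paired to miRNA position 10

    @property
    def n_mismatches(self) -> int:
        return self.pair_string.count("M")

    @property
    def n_wobbles(self) -> int:
        return self.pair_string.count("G")

    def diagram(self, transcript_seq: str, mirna_seq: str) -> str:
        """Plain-text duplex in the figure style (| W, o wobble, x mismatch).

        Target is drawn 5'->3', the miRNA antiparallel beneath it.
        """
        site = transcript_seq[self.site_start - 1 : self.site_end]
        mid = "".join(
            {"W": "|", "G": "o", "M": "x"}[c] for c in reversed(self.pair_string)
        )
        return (
            f"5' {site} 3'  {self.transcript_id}:{self.site_start}-{self.site_end}\n"
            f"   {mid}\n"
            f"3' {mirna_seq[::-1]} 5'  {self.mirna_name}"
        )


def classify_pair(mirna_base: str, target_base: str) -> str:
    """Classify one duplex position as W (Watson-Crick), G (wobble) or M."""
    pair = (mirna_base, target_base)
    for b in pair:
        if b not in _BASE_CODE:
            raise ValueError(f"non-ACGT base {b!r}")
    if pair in _WC:
        return "W"
    if pair in _WOBBLE:
        return "G"
    return "M"


def pair_penalty(symbol: str) -> float:
    return {"W": 0.0, "G": PENALTY_WOBBLE, "M": PENALTY_MISMATCH}[symbol]


def align_site(
    mirna: MiRNARecord, transcript_id: str, transcript_seq: str, site_end: int
) -> DuplexAlignment:
    """Align a miRNA against the site whose 3'-most transcript base is
    ``site_end`` (paired with miRNA position 1)."""
    L = len(mirna.sequence)
    site_start = site_end - L + 1
    if site_start < 1 or site_end > len(transcript_seq):
        raise ValueError(
            f"site [{site_start}, {site_end}] out of bounds for "
            f"{transcript_id} (length {len(transcript_seq)})"
        )
    symbols = []
    for i in range(1, L + 1):  # miRNA position, 1-based from 5'
        tbase = transcript_seq[site_end - i]  # site_end - i + 1, 0-based
        symbols.append(classify_pair(mirna.sequence[i - 1], tbase))
    pair_string = "".join(symbols)
    penalty = sum(pair_penalty(s) for s in symbols)
    return DuplexAlignment(
        mirna_name=mirna.name,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_end,
        pair_string=pair_string,
        penalty_total=penalty,
        cleavage_position=site_end - 9,
    )


def _penalty_profile(mirna_seq: str) -> np.ndarray:
    """(L, 4) penalty of target base code at each site offset.

    Row j corresponds to the site position site_start + j, which pairs
    miRNA position L - j (1-based).
    """
    L = len(mirna_seq)
    prof = np.empty((L, 4))
    for j in range(L):
        mbase = mirna_seq[L - j - 1]
        for tbase, code in _BASE_CODE.items():
            prof[j, code] = pair_penalty(classify_pair(mbase, tbase))
    return prof


def find_candidate_sites(
    mirna: MiRNARecord,
    transcript_id: str,
    transcript_seq: str,
    max_penalty: float = 4.0,
) -> List[DuplexAlignment]:
    """Scan every window of the transcript; return alignments with
    penalty_total <= max_penalty, sorted by (penalty asc, site_start asc).
    """
    seq = canonical_dna(transcript_seq)
    L = len(mirna.sequence)
    n = len(seq)
    if n < L:
        raise ValueError(
            f"transcript {transcript_id} shorter ({n}) than miRNA ({L})"
        )
    codes = np.frombuffer(seq.translate(str.maketrans("ACGT", "\0\1\2\3")).encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    prof = _penalty_profile(mirna.sequence)
    penalties = prof[np.arange(L)[None, :], windows].sum(axis=1)
    hits = np.nonzero(penalties <= max_penalty + 1e-9)[0]
    out = [align_site(mirna, transcript_id, seq, int(start) + L) for start in hits]
    out.sort(key=lambda a: (a.penalty_total, a.site_start))
    return out


def compliance_score(dup: DuplexAlignment) -> float:
    """Complementarity component: 8 - penalty_total (may be negative)."""
    return COMPLIANCE_MAX - dup.penalty_total
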