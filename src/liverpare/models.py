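"""Core domain records shared across the pipeline.

All sequences are canonicalized to the uppercase DNA alphabet on input
(U -> T); coordinates are 1-based inclusive throughout, matching GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

ORGANS = ("Mv", "Ma", "Fv", "Fa")
REGIONS = ("utr5", "cds", "utr3")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def canonical_dna(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T.

    Raises ValueError on characters outside {A, C, G, T, U, a, c, g, t, u}.
    """
    s = seq.upper().replace("U", "T")
    if not set(s) <= set("ACGT"):
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(f"non-ACGTU characters in sequence: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA: the query of both quantification and targeting."""

    name: str
    sequence: str  # DNA alphabet, uppercase

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonical_dna(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """Transcript with contiguous 1-based 5'UTR / CDS / 3'UTR intervals.

    Intervals are inclusive and must tile [1, length]; an absent region is
    None (zero length).
    """

    transcript_id: str
    length: int
    utr5: Optional[Tuple[int, int]] = None
    cds: Optional[Tuple[int, int]] = None
    utr3: Optional[Tuple[int, int]] = None

    def interval(self, region: str) -> Optional[Tuple[int, int]]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return getattr(self, region)

    def region_of(self, position: int) -> str:
        """Region containing a 1-based position (boundaries inclusive)."""
        for region in REGIONS:
            iv = self.interval(region)
            if iv is not None and iv[0] <= position <= iv[1]:
                return region
        raise ValueError(
            f"position {position} outside all annotated intervals of "
            f"{self.transcript_id} (length {self.length})"
        )

    def validate_tiling(self) -> None:
        ivs = [self.interval(r) for r in REGIONS]
        ivs = [iv for iv in ivs if iv is not None]
        if not ivs:
            raise ValueError(f"{self.transcript_id}: no annotated intervals")
        expected_start = 1
        for start, end in ivs:
            if start != expected_start or end < start:
                raise ValueError(
                    f"{self.transcript_id}: intervals do not tile [1, {self.length}]"
                )
            expected_start = end + 1
        if expected_start != self.length + 1:
            raise ValueError(
                f"{self.transcript_id}: intervals do not tile [1, {self.length}]"
            )
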