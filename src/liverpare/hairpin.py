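"""Stem-loop plausibility check by base-pair maximization.

A precursor is folded with a Nussinov-style dynamic program: maximize the
number of nested Watson-Crick + G:U pairs with a minimum hairpin loop of
3 nt (j - i > 3).  This tests structural plausibility — whether the mature
miRNA and its star can sit base-paired on opposite arms of a stem — and
deliberately says nothing about folding free energies: it is a
combinatorial model, not a thermodynamic one.

Ties in the dynamic program are broken toward pairing the 5'-most base
with its 5'-most admissible partner, making the traceback deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .models import canonical_dna

MIN_LOOP = 3  # unpaired bases enclosed by any pair: j - i > MIN_LOOP

_PAIRABLE = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}


@dataclass
class HairpinFold:
    sequence: str
    pairs: List[Tuple[int, int]]  # 1-based, i < j
    n_pairs: int
    mirna_span: Optional[Tuple[int, int]] = None
    star_span: Optional[Tuple[int, int]] = None
    duplex_paired_fraction: Optional[float] = None

    def partner(self) -> Dict[int, int]:
        d: Dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def fold_maxpairs(sequence: str) -> HairpinFold:
    """Maximum nested Watson-Crick/G:U pairing with loop >= 3."""
    seq = canonical_dna(sequence)
    n = len(seq)
    if n < 10:
        raise ValueError(f"sequence too short to fold ({n} < 10 nt)")
    # N[i, j]: max pairs in seq[i..j], 0-based inclusive
    N = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    cand = 1 + N[i + 1, k - 1] + (N[k + 1, j] if k + 1 <= j else 0)
                    if cand > best:
                        best = cand
            N[i, j] = best
    pairs: List[Tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        target = N[i, j]
        if target == 0:
            continue
        paired = False
        # prefer pairing the 5'-most base, with its 5'-most partner
        for k in range(i + MIN_LOOP + 1, j + 1):
            if _can_pair(seq[i], seq[k]):
                inner = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                outer = N[k + 1, j] if k + 1 <= j else 0
                if 1 + inner + outer == target:
                    pairs.append((i + 1, k + 1))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    pairs.sort()
    return HairpinFold(sequence=seq, pairs=pairs, n_pairs=len(pairs))


def duplex_paired_fraction(
    fold: HairpinFold, mirna_span: Tuple[int, int], star_span: Tuple[int, int]
) -> float:
    """Fraction of miRNA-span positions paired to a position inside the
    star span."""
    partner = fold.partner()
    lo, hi = mirna_span
    s_lo, s_hi = star_span
    total = hi - lo + 1
    hit = sum(
        1 for p in range(lo, hi + 1) if p in partner and s_lo <= partner[p] <= s_hi
    )
    return hit / total


def validate_hairpin(
    fold: HairpinFold,
    mirna_span: Tuple[int, int],
    star_span: Tuple[int, int],
    min_fraction: float = 0.6,
) -> Tuple[bool, Dict[str, object]]:
    """Does the fold place miRNA and miRNA* as a duplex on opposite arms?

    True iff the spans are disjoint and at least ``min_fraction`` of miRNA
    positions pair into the star span.  Returns (verdict, report).
    """
    n = len(fold.sequence)
    for name, (lo, hi) in (("mirna", mirna_span), ("star", star_span)):
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"{name} span {lo}-{hi} outside sequence of length {n}")
    if not (mirna_span[1] < star_span[0] or star_span[1] < mirna_span[0]):
        raise ValueError(
            f"miRNA span {mirna_span} overlaps star span {star_span}"
        )
    frac = duplex_paired_fraction(fold, mirna_span, star_span)
    fold.mirna_span = mirna_span
    fold.star_span = star_span
    fold.duplex_paired_fraction = frac
    verdict = frac >= min_fraction
    report = {
        "duplex_paired_fraction": frac,
        "min_fraction": min_fraction,
        "n_pairs": fold.n_pairs,
        "dot_bracket": fold.dot_bracket(),
        "verdict": verdict,
    }
    return verdict, report
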