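"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (explicit tables, exhaustive
enumeration, textbook formulas) and deliberately shares no code with the
package under test.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

# explicit pair-class table: key (mirna_base, target_base)
PAIR_TABLE: Dict[Tuple[str, str], str] = {}
for _m in "ACGT":
    for _t in "ACGT":
        if _COMP[_m] == _t:
            PAIR_TABLE[(_m, _t)] = "W"
        elif (_m, _t) in (("G", "T"), ("T", "G")):
            PAIR_TABLE[(_m, _t)] = "G"
        else:
            PAIR_TABLE[(_m, _t)] = "M"

PENALTIES = {"W": 0.0, "G": 0.5, "M": 1.0}


def duplex_penalty_brute(mirna_seq: str, site_seq: str) -> float:
    """Penalty of a gapless antiparallel duplex: miRNA 5'->3' against the
    site read 3'->5' (miRNA position i pairs the site's i-th base from its
    3' end)."""
    assert len(mirna_seq) == len(site_seq)
    total = 0.0
    for i, mbase in enumerate(mirna_seq):
        tbase = site_seq[len(site_seq) - 1 - i]
        total += PENALTIES[PAIR_TABLE[(mbase, tbase)]]
    return total


def scan_sites_brute(
    mirna_seq: str, transcript: str, max_penalty: float
) -> List[Tuple[int, float]]:
    """All (site_start 1-based, penalty) with penalty <= max_penalty."""
    L = len(mirna_seq)
    out = []
    for start0 in range(len(transcript) - L + 1):
        pen = duplex_penalty_brute(mirna_seq, transcript[start0 : start0 + L])
        if pen <= max_penalty + 1e-9:
            out.append((start0 + 1, pen))
    return out


def cutting_power_brute(norm: Mapping[int, float], position: int) -> Optional[int]:
    peak = max(norm.values(), default=0.0)
    if peak <= 0:
        return None
    x = 10.0 * norm.get(position, 0.0) / peak
    # half-up rounding
    return int(x + 0.5)


def category_brute(counts: Mapping[int, float], position: int) -> int:
    c = counts[position]
    assert c > 0
    if c <= 1:
        return 4
    values = sorted(v for v in counts.values() if v > 0)
    peak = values[-1]
    if c == peak:
        return 0 if values.count(peak) == 1 else 1
    n = len(values)
    median = (
        values[n // 2] if n % 2 == 1 else 0.5 * (values[n // 2 - 1] + values[n // 2])
    )
    return 2 if c > median else 3


def region_brute(
    intervals: Mapping[str, Optional[Tuple[int, int]]], position: int
) -> Optional[str]:
    for region in ("utr5", "cds", "utr3"):
        iv = intervals.get(region)
        if iv and iv[0] <= position <= iv[1]:
            return region
    return None


def _average_ranks(values: Sequence[float]) -> List[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of average ranks, from raw sums."""
    rx, ry = _average_ranks(x), _average_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def max_nested_pairs_brute(seq: str, min_loop: int = 3) -> int:
    """Exhaustive maximum over all nested structures (small sequences)."""
    pairable = {
        ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")
    }

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        result = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in pairable:
                result = max(result, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return result

    return best(0, len(seq) - 1)
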