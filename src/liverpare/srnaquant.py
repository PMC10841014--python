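"""Small-RNA read processing and miRNA quantification.

The stages mirror a standard plant sRNA-seq workflow: 3'-adapter trimming,
18-28 nt length selection, read collapsing to (sequence, count) pairs, raw
exact-match miRNA counting, and RPM normalization (reads per million
retained reads).  Differential accumulation between organ pairs uses a
Welch t-test on replicate RPM with the three-star significance convention.

Quantification is exact-match on the mature sequence: each miRNA is counted
as the number of retained reads identical to it (no isomiR tolerance).
Adapter trimming cuts at the leftmost exact occurrence of the adapter's
first 8 nt; reads without the seed are kept untrimmed and empty inserts are
dropped.  Real data with sequencing errors should be pre-trimmed with a
dedicated trimmer upstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import welch_stars
from .models import MiRNARecord, ORGANS

ADAPTER_SEED_LEN = 8
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 28
#: pseudocount, in RPM, added to organ means before fold change
FOLD_CHANGE_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int


@dataclass
class LibraryCounts:
    library_id: Tuple[str, int]  # (organ, replicate)
    total_retained: int
    collapsed: List[CollapsedRead] = field(default_factory=list)

    def as_dict(self) -> Dict[str, int]:
        return {c.sequence: c.count for c in self.collapsed}


def trim_adapter(reads: Iterable[str], adapter: str) -> List[str]:
    """Cut each read at the leftmost exact match of the adapter's 8-nt seed.

    Reads lacking the seed pass through untrimmed; reads whose insert is
    empty (seed at position 1) are dropped.
    """
    if len(adapter) < ADAPTER_SEED_LEN:
        raise ValueError(
            f"adapter must be at least {ADAPTER_SEED_LEN} nt, got {len(adapter)}"
        )
    seed = adapter[:ADAPTER_SEED_LEN].upper()
    out: List[str] = []
    for read in reads:
        read = read.upper()
        cut = read.find(seed)
        if cut == 0:
            continue  # empty insert
        out.append(read if cut < 0 else read[:cut])
    return out


def filter_by_length(
    reads: Iterable[str], min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> List[str]:
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse_reads(
    reads: Sequence[str], library_id: Tuple[str, int] = ("NA", 0)
) -> LibraryCounts:
    """Collapse identical sequences; sort by count desc then lexicographic."""
    counter = Counter(reads)
    collapsed = [
        CollapsedRead(seq, n)
        for seq, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return LibraryCounts(
        library_id=library_id, total_retained=len(reads), collapsed=collapsed
    )


def quantify_mirnas(
    lib: LibraryCounts, mirnas: Sequence[MiRNARecord]
) -> Dict[str, int]:
    """Raw count of reads exactly equal to each mature sequence."""
    by_seq: Dict[str, str] = {}
    for m in mirnas:
        if m.sequence in by_seq:
            raise ValueError(
                f"duplicate mature sequence for {by_seq[m.sequence]} and {m.name}: "
                "attribution would be ambiguous"
            )
        by_seq[m.sequence] = m.name
    counts = lib.as_dict()
    return {m.name: counts.get(m.sequence, 0) for m in mirnas}


def normalize_rpm(raw_counts: Dict[str, float], total_retained: int) -> Dict[str, float]:
    """RPM = 1e6 * count / total retained reads."""
    if total_retained <= 0:
        raise ValueError("total_retained must be positive for RPM normalization")
    return {name: 1e6 * c / total_retained for name, c in raw_counts.items()}


def quantify_libraries(
    libraries: Sequence[LibraryCounts], mirnas: Sequence[MiRNARecord]
) -> pd.DataFrame:
    """RPM expression matrix: rows = miRNAs, columns = (organ, replicate)."""
    cols = {}
    for lib in libraries:
        rpm = normalize_rpm(
            {k: float(v) for k, v in quantify_mirnas(lib, mirnas).items()},
            lib.total_retained,
        )
        cols[lib.library_id] = rpm
    mat = pd.DataFrame(cols, index=[m.name for m in mirnas])
    mat.columns = pd.MultiIndex.from_tuples(mat.columns, names=["organ", "replicate"])
    return mat


def organ_means(mat: pd.DataFrame) -> pd.DataFrame:
    """Average the replicate columns of an (organ, replicate) RPM matrix."""
    means = mat.T.groupby(level="organ").mean().T
    order = [o for o in ORGANS if o in means.columns] + [
        o for o in means.columns if o not in ORGANS
    ]
    return means[order]


def differential_accumulation(
    mat: pd.DataFrame, pair: Tuple[str, str], pseudocount: float = FOLD_CHANGE_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-miRNA log2 fold change and Welch t-test between two organs.

    Returns a table with columns mean_<A>, mean_<B>, log2fc, p, stars where
    log2fc = log2((mean_A + pc) / (mean_B + pc)).
    """
    organ_a, organ_b = pair
    for organ in pair:
        if organ not in mat.columns.get_level_values("organ"):
            raise ValueError(f"organ {organ!r} missing from expression matrix")
    a = mat.xs(organ_a, axis=1, level="organ")
    b = mat.xs(organ_b, axis=1, level="organ")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per organ")
    rows = []
    for name in mat.index:
        va, vb = a.loc[name].to_numpy(float), b.loc[name].to_numpy(float)
        log2fc = float(
            np.log2((va.mean() + pseudocount) / (vb.mean() + pseudocount))
        )
        p, stars = welch_stars(va, vb)
        rows.append(
            {
                "mirna": name,
                f"mean_{organ_a}": va.mean(),
                f"mean_{organ_b}": vb.mean(),
                "log2fc": log2fc,
                "p": p,
                "stars": stars,
            }
        )
    return pd.DataFrame(rows).set_index("mirna")


def process_library(
    reads: Iterable[str],
    adapter: str,
    library_id: Tuple[str, int] = ("NA", 0),
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> LibraryCounts:
    """Trim, length-select and collapse one raw FASTQ library."""
    trimmed = trim_adapter(reads, adapter)
    kept = filter_by_length(trimmed, min_len, max_len)
    return collapse_reads(kept, library_id)
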