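"""RT-qPCR relative expression (2^-ddCt) and miRNA-target correlation.

Relative quantities are computed against a reference gene and a calibrator
organ: dCt = Ct_gene - Ct_ref per (organ, replicate), ddCt = dCt - mean
dCt(calibrator), RQ = 2^-ddCt.  Perfect doubling efficiency is assumed (no
standard-curve correction).  Replicate comparisons use a Welch t-test with
the three-star convention (* p<0.05, ** p<0.01, *** p<0.001).

The inverse-correlation report pairs a miRNA's organ RPM profile with its
target's organ RQ profile via Spearman rank correlation over the organ
means; with four organs rho is coarse, so the report carries both rho and
the raw profiles and flags direction only (rho < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import welch_stars
from .models import ORGANS

DEFAULT_REFERENCE_GENE = "MpACT7"
DEFAULT_CALIBRATOR = "Mv"


@dataclass
class RelativeExpression:
    gene: str
    calibrator: str
    rq: pd.DataFrame  # rows: replicate, columns: organ
    mean: pd.Series = field(default_factory=pd.Series)
    sd: pd.Series = field(default_factory=pd.Series)
    stars: Dict[str, str] = field(default_factory=dict)  # vs calibrator


@dataclass
class CorrelationReport:
    mirna: str
    target: str
    mirna_profile: pd.Series  # organ means, RPM
    target_profile: pd.Series  # organ means, RQ
    spearman_rho: Optional[float]
    inverse: Optional[bool]
    evaluable: bool


def delta_delta_ct(
    tbl: pd.DataFrame,
    gene: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    calibrator_organ: str = DEFAULT_CALIBRATOR,
) -> RelativeExpression:
    """2^-ddCt relative expression of one gene across organs.

    ``tbl`` has columns (organ, replicate, gene, ct).  The reference gene
    must be measured in every (organ, replicate) where the gene is.
    """
    sub = tbl[tbl["gene"] == gene]
    ref = tbl[tbl["gene"] == reference_gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from Ct table")
    if calibrator_organ not in set(sub["organ"]):
        raise ValueError(f"calibrator organ {calibrator_organ!r} not measured for {gene}")
    ref_map = {(r.organ, r.replicate): r.ct for r in ref.itertuples(index=False)}
    dct: Dict[Tuple[str, int], float] = {}
    for r in sub.itertuples(index=False):
        key = (r.organ, r.replicate)
        if key not in ref_map:
            raise ValueError(
                f"reference gene {reference_gene!r} missing for organ "
                f"{key[0]!r} replicate {key[1]}"
            )
        dct[key] = r.ct - ref_map[key]
    calib_mean = float(
        np.mean([v for (organ, _), v in dct.items() if organ == calibrator_organ])
    )
    rq_rows: Dict[str, Dict[int, float]] = {}
    for (organ, rep), v in dct.items():
        rq_rows.setdefault(organ, {})[rep] = 2.0 ** (-(v - calib_mean))
    organs = [o for o in ORGANS if o in rq_rows] + [
        o for o in rq_rows if o not in ORGANS
    ]
    rq = pd.DataFrame({o: pd.Series(rq_rows[o]) for o in organs}).sort_index()
    result = RelativeExpression(
        gene=gene, calibrator=calibrator_organ, rq=rq,
        mean=rq.mean(), sd=rq.std(ddof=1),
    )
    calib_vals = rq[calibrator_organ].dropna().to_numpy()
    for organ in organs:
        if organ == calibrator_organ:
            result.stars[organ] = ""
            continue
        vals = rq[organ].dropna().to_numpy()
        if len(vals) >= 2 and len(calib_vals) >= 2:
            _, result.stars[organ] = welch_stars(vals, calib_vals)
        else:
            result.stars[organ] = ""
    return result


def star_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, str]:
    """Two-sided Welch t-test with significance stars."""
    return welch_stars(group_a, group_b)


def inverse_correlation(
    mirna: str,
    target: str,
    mirna_profile: pd.Series,
    target_profile: pd.Series,
) -> CorrelationReport:
    """Spearman rank correlation of organ-mean miRNA RPM vs target RQ.

    A constant profile on either side makes rho undefined; the report is
    then flagged not evaluable.
    """
    organs = list(mirna_profile.index)
    if set(organs) != set(target_profile.index):
        raise ValueError("miRNA and target profiles cover different organs")
    x = mirna_profile.to_numpy(float)
    y = target_profile.reindex(organs).to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport(
            mirna, target, mirna_profile, target_profile,
            spearman_rho=None, inverse=None, evaluable=False,
        )
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationReport(
        mirna, target, mirna_profile, target_profile,
        spearman_rho=rho, inverse=rho < 0, evaluable=True,
    )


def relative_expression_table(results: Sequence[RelativeExpression]) -> pd.DataFrame:
    rows = []
    for res in results:
        for organ in res.rq.columns:
            for rep, value in res.rq[organ].dropna().items():
                rows.append(
                    {
                        "gene": res.gene, "organ": organ, "replicate": rep,
                        "rq": value, "organ_mean": res.mean[organ],
                        "organ_sd": res.sd[organ], "stars_vs_calibrator": res.stars[organ],
                    }
                )
    return pd.DataFrame(rows)


def correlation_table(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        row = {"mirna": rep.mirna, "target": rep.target}
        for organ in rep.mirna_profile.index:
            row[f"rpm_{organ}"] = rep.mirna_profile[organ]
        for organ in rep.target_profile.index:
            row[f"rq_{organ}"] = rep.target_profile[organ]
        row["spearman_rho"] = rep.spearman_rho if rep.evaluable else float("nan")
        row["inverse"] = rep.inverse if rep.evaluable else "not_evaluable"
        rows.append(row)
    return pd.DataFrame(rows)
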