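"""Quantity-quality trade-off synthesis across scales and individuals.

The C x N interaction coefficient summarizes an individual's trade-off
tactic: positive values mean forage quantity (carbon biomass) is preferred
over quality (% nitrogen), negative values the reverse. This module turns
per-unit fits into tidy records, classifies tactics, and runs the
cross-individual synthesis tests (interaction-vs-correlation weighted
regression, collar-year ANOVA, scale comparison).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "TradeoffRecord",
    "classify_tradeoff",
    "records_to_frame",
    "weighted_interaction_regression",
    "year_effect_test",
    "scale_comparison",
]

LABELS = ("quality_over_quantity", "neutral", "quantity_over_quality")


@dataclass
class TradeoffRecord:
    """One unit x scale row of selection coefficients and context."""

    unit_id: str
    scale: str
    beta_c: float
    beta_n: float
    beta_cxn: float
    se_c: float
    se_n: float
    se_cxn: float
    pseudo_r2: float
    cn_pearson_r: float | None = None
    sex: str | None = None
    year: int | None = None


def records_to_frame(records) -> pd.DataFrame:
    rows = [asdict(r) if isinstance(r, TradeoffRecord) else dict(r) for r in records]
    return pd.DataFrame(rows)


def classify_tradeoff(beta_cxn: float, se: float | None = None, band_se: float = 1.0) -> str:
    """Label a trade-off tactic from the C x N interaction coefficient.

    ``|beta| < band_se * SE`` is called neutral (default band one standard
    error); otherwise the sign decides: positive = quantity over quality.
    """
    band = band_se * se if se is not None else 0.0
    if abs(beta_cxn) <= band or beta_cxn == 0:
        return "neutral"
    return "quantity_over_quality" if beta_cxn > 0 else "quality_over_quantity"


def weighted_interaction_regression(
    records,
    predictor: str = "cn_pearson_r",
    response: str = "beta_cxn",
    se_col: str = "se_cxn",
    weighting: str = "inv_var",
):
    """Weighted linear model of interaction coefficients on a predictor.

    Tests whether within-polygon C-N correlation explains individual
    trade-off strength. Weights are ``1/SE^2`` (``weighting='inv_var'``,
    standard WLS) or ``1/SE`` (``'inv_se'``). Returns
    ``(slope, t_statistic, two_sided_p)``.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.dropna(subset=[predictor, response, se_col])
    if len(df) < 3:
        raise ValidationError("need >= 3 records with finite predictor and response")
    if weighting == "inv_var":
        w = 1.0 / np.asarray(df[se_col], dtype=float) ** 2
    elif weighting == "inv_se":
        w = 1.0 / np.asarray(df[se_col], dtype=float)
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    if not np.all(np.isfinite(w)) or np.all(w == 0):
        raise ValidationError("degenerate weights")
    X = sm.add_constant(np.asarray(df[predictor], dtype=float))
    fit = sm.WLS(np.asarray(df[response], dtype=float), X, weights=w).fit()
    return float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1])


def year_effect_test(records, metric: str = "pseudo_r2", group_col: str = "year"):
    """One-way ANOVA of a fit metric across collar years.

    Textbook between/within mean-square ratio; identical group data yield
    ``F = 0, p = 1`` by convention. Returns ``(F, p)``.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.dropna(subset=[metric, group_col])
    groups = [g[metric].to_numpy(dtype=float) for _, g in df.groupby(group_col)]
    if len(groups) < 2:
        raise ValidationError("need >= 2 year groups")
    if sum(len(g) for g in groups) < 3:
        raise ValidationError("need >= 3 records")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = sum(len(g) for g in groups) - len(groups)
    if ssb == 0:
        return 0.0, 1.0
    if ssw == 0 or dfw == 0:
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    return float(F), float(stats.f.sf(F, dfb, dfw))


def scale_comparison(
    records,
    scale_a: str = "home_range",
    scale_b: str = "patch",
    band_se: float = 1.0,
) -> pd.DataFrame:
    """Compare each unit's trade-off tactic between two scales.

    Returns one row per unit present at both scales: the interaction
    coefficients, tactic labels, whether the tactic switched sign (both
    scales non-neutral with opposite labels), and the change in magnitude
    (negative = converging toward zero at the finer scale).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    a = df[df["scale"] == scale_a].set_index("unit_id")
    b = df[df["scale"] == scale_b].set_index("unit_id")
    units = sorted(set(a.index) & set(b.index))
    if not units:
        raise ValidationError(f"no units present at both {scale_a!r} and {scale_b!r}")
    rows = []
    for u in units:
        ba, sa = float(a.loc[u, "beta_cxn"]), float(a.loc[u, "se_cxn"])
        bb, sb = float(b.loc[u, "beta_cxn"]), float(b.loc[u, "se_cxn"])
        la = classify_tradeoff(ba, sa, band_se)
        lb = classify_tradeoff(bb, sb, band_se)
        switched = la != lb and "neutral" not in (la, lb)
        rows.append(
            {
                "unit_id": u,
                f"beta_cxn_{scale_a}": ba,
                f"beta_cxn_{scale_b}": bb,
                f"label_{scale_a}": la,
                f"label_{scale_b}": lb,
                "switched": switched,
                "abs_change": abs(bb) - abs(ba),
            }
        )
    return pd.DataFrame(rows)
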