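"""Resource selection models at three foraging scales.

* Landscape and home-range scales: used/available resource selection
  functions (RSFs), ``w(x) = exp(b0 + b1*x1 + ... + bk*xk)``, fit by
  logistic regression (IRLS/Newton, implemented here).
* Patch scale: integrated step selection analysis (iSSA) — observed 2-h
  steps, a gamma x von Mises movement kernel fit by maximum likelihood,
  matched available steps drawn from that kernel, and a stratified
  conditional logistic regression maximizing the partial likelihood
  ``sum_strata [ b'x_used - log sum_j exp(b'x_j) ]`` (no intercept).

Model strength is summarized by McFadden's pseudo-R^2, ``1 - ll/ll0``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from .movement import MovementModel, _wrap_angle
from .rasters import ElementalRaster

log = logging.getLogger(__name__)

RSF_TERMS = ("C", "N", "C:N")
#: patch-scale covariates: habitat terms plus movement-kernel adjustment
#: terms and their habitat interactions
ISSA_TERMS = (
    "C",
    "N",
    "C:N",
    "step_length",
    "cos_ta",
    "step_length:C",
    "step_length:N",
    "cos_ta:C",
    "cos_ta:N",
)

__all__ = [
    "SelectionFit",
    "steps_from_track",
    "fit_movement_kernel",
    "generate_available_steps",
    "fit_rsf",
    "fit_conditional_logit",
    "conditional_loglik_grad",
    "pseudo_r2",
    "RSF_TERMS",
    "ISSA_TERMS",
]


@dataclass
class SelectionFit:
    """Coefficients and fit summaries for one model / scale / unit."""

    unit_id: str
    scale: str  # landscape | home_range | patch
    terms: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray
    loglik: float
    null_loglik: float
    pseudo_r2: float
    n_used: int
    n_available: int
    converged: bool
    pseudo_r2_flavor: str = "mcfadden"
    meta: dict = field(default_factory=dict)

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for one coefficient."""
        z = stats.norm.ppf(0.5 + level / 2)
        b, s = self.beta[term], self.se[term]
        return (b - z * s, b + z * s)

    def summary_row(self) -> dict:
        row = {
            "scale": self.scale,
            "unit": self.unit_id,
            "n_used": self.n_used,
            "n_available": self.n_available,
            "pseudo_r2": self.pseudo_r2,
            "converged": self.converged,
        }
        for t in self.terms:
            key = t.replace(":", "x")
            row[f"beta_{key}"] = self.beta[t]
            row[f"se_{key}"] = self.se[t]
        return row


# ---------------------------------------------------------------------------
# step construction


def steps_from_track(
    track: pd.DataFrame,
    interval_hours: float = 2.0,
    tolerance_minutes: float = 1.0,
) -> pd.DataFrame:
    """Decompose a track into fix-interval steps, splitting at gaps.

    Consecutive fixes whose time difference matches the fix interval (within
    tolerance) form steps; any larger gap splits the track into bursts and
    the step spanning the gap is dropped. The turn angle of a step is the
    signed angular change (counterclockwise positive, wrapped to (-pi, pi])
    from the previous step's heading within the same burst; the first step
    of each burst, and steps following a zero-length step, carry no turn
    angle. Returns one row per step with start/end coordinates, length (m),
    heading, previous heading, and turn angle.
    """
    if track["animal_id"].nunique() > 1:
        parts = [
            steps_from_track(g, interval_hours, tolerance_minutes)
            for _, g in track.groupby("animal_id", sort=True)
        ]
        return pd.concat(parts, ignore_index=True)
    if len(track) < 3:
        raise InsufficientDataError("need >= 3 fixes to build iSSA steps")
    t = track.sort_values("timestamp").reset_index(drop=True)
    ts = pd.to_datetime(t["timestamp"])
    dt_h = ts.diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    tol_h = tolerance_minutes / 60.0
    good = np.abs(dt_h - interval_hours) <= tol_h

    x = t["x"].to_numpy(dtype=float)
    y = t["y"].to_numpy(dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    length = np.hypot(dx, dy)
    heading = np.where(length > 0, np.arctan2(dy, dx), np.nan)

    # burst id: increments at every bad interval; steps on bad intervals dropped
    burst = np.concatenate([[0], np.cumsum(~good)])[:-1]
    rows = pd.DataFrame(
        {
            "animal_id": t["animal_id"].iloc[0],
            "burst": burst,
            "t_start": ts.to_numpy()[:-1],
            "t_end": ts.to_numpy()[1:],
            "x1": x[:-1],
            "y1": y[:-1],
            "x2": x[1:],
            "y2": y[1:],
            "length": length,
            "heading": heading,
        }
    )[good]
    rows = rows.reset_index(drop=True)
    prev_heading = rows["heading"].shift(1)
    same_burst = rows["burst"].eq(rows["burst"].shift(1))
    prev_heading[~same_burst] = np.nan
    rows["prev_heading"] = prev_heading
    ta = _wrap_angle(rows["heading"].to_numpy() - prev_heading.to_numpy())
    ta[np.isnan(rows["heading"].to_numpy()) | np.isnan(prev_heading.to_numpy())] = np.nan
    rows["turn_angle"] = ta
    return rows


# ---------------------------------------------------------------------------
# movement kernel MLE


def _vonmises_mle(angles: np.ndarray, kappa_cap: float = 1e3):
    """Closed-form/numeric von Mises MLE via the mean resultant length."""
    C = np.cos(angles).mean()
    S = np.sin(angles).mean()
    mu = math.atan2(S, C)
    rbar = math.hypot(C, S)
    if rbar >= 1.0 - 1e-12:
        warnings.warn("turn angles fully concentrated; kappa capped")
        return mu, kappa_cap
    if rbar <= 1e-12:
        return mu, 0.0

    def f(k):
        return special.i1e(k) / special.i0e(k) - rbar

    if f(kappa_cap) < 0:
        warnings.warn("von Mises kappa exceeds cap; capped")
        return mu, kappa_cap
    kappa = optimize.brentq(f, 1e-12, kappa_cap)
    return mu, kappa


def fit_movement_kernel(
    steps: pd.DataFrame,
    kappa_cap: float = 1e3,
    min_angles: int = 10,
) -> MovementModel:
    """Maximum-likelihood gamma step-length and von Mises turn-angle fit.

    Step lengths of zero are excluded from the gamma fit (zero-length steps
    have no defined heading and the gamma support is positive).
    """
    lengths = steps["length"].to_numpy(dtype=float)
    lengths = lengths[lengths > 0]
    angles = steps["turn_angle"].to_numpy(dtype=float)
    angles = angles[~np.isnan(angles)]
    if len(angles) < min_angles:
        raise InsufficientDataError(
            f"need >= {min_angles} steps with defined turn angles"
        )
    if len(lengths) < 2 or np.std(lengths) == 0:
        raise DegenerateFitError("step lengths have zero variance")
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    mu, kappa = _vonmises_mle(angles, kappa_cap)
    # vm_mu exactly pi is legal; -pi wraps to pi
    mu = float(_wrap_angle(mu))
    return MovementModel(
        gamma_shape=float(shape), gamma_scale=float(scale), vm_mu=mu, vm_kappa=float(kappa)
    )


# ---------------------------------------------------------------------------
# available steps


def generate_available_steps(
    steps: pd.DataFrame,
    kernel: MovementModel,
    raster_c: ElementalRaster,
    raster_n: ElementalRaster,
    n_avail: int = 10,
    seed: int | np.random.Generator = 0,
    min_candidates: int = 3,
) -> pd.DataFrame:
    """Pair each observed step with kernel-sampled available steps.

    Strata are formed only for steps with a defined turn angle (a previous
    heading exists). ``n_avail`` candidate endpoints per stratum share the
    observed step's start point, with lengths and turn angles drawn from the
    fitted kernel. Candidates landing outside predicted habitat are dropped
    (not redrawn), mirroring the cleaning of analysis data to predicted
    forested habitat; strata left with fewer than ``min_candidates``
    available rows, or whose used endpoint is itself unpredicted, are
    discarded and logged.

    Returns a long table with one row per used/available step: columns
    ``stratum_id, is_used, x, y, step_length, turn_angle, cos_ta, C, N``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    elig = steps[~steps["turn_angle"].isna()].reset_index(drop=True)
    m = len(elig)
    if m == 0:
        raise InsufficientDataError("no steps with defined turn angles")
    sx = elig["x1"].to_numpy(dtype=float)
    sy = elig["y1"].to_numpy(dtype=float)
    prev_h = elig["prev_heading"].to_numpy(dtype=float)

    L = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, size=(m, n_avail))
    TA = rng.vonmises(kernel.vm_mu, kernel.vm_kappa, size=(m, n_avail))
    H = prev_h[:, None] + TA
    ax = sx[:, None] + L * np.cos(H)
    ay = sy[:, None] + L * np.sin(H)

    used_c = raster_c.value_at(elig["x2"].to_numpy(), elig["y2"].to_numpy())
    used_n = raster_n.value_at(elig["x2"].to_numpy(), elig["y2"].to_numpy())
    av_c = raster_c.value_at(ax.ravel(), ay.ravel()).reshape(m, n_avail)
    av_n = raster_n.value_at(ax.ravel(), ay.ravel()).reshape(m, n_avail)
    av_ok = ~(np.isnan(av_c) | np.isnan(av_n))
    used_ok = ~(np.isnan(used_c) | np.isnan(used_n))
    keep = used_ok & (av_ok.sum(axis=1) >= min_candidates)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info(
            "generate_available_steps: discarded %d of %d strata "
            "(unpredicted used endpoint or < %d valid candidates)",
            n_drop, m, min_candidates,
        )

    frames = []
    aid = elig["animal_id"].astype(str).to_numpy()
    stratum_ids = np.array([f"{a}:{i}" for i, a in enumerate(aid)], dtype=object)
    idx = np.nonzero(keep)[0]
    used = pd.DataFrame(
        {
            "stratum_id": stratum_ids[idx],
            "animal_id": aid[idx],
            "is_used": 1,
            "x": elig["x2"].to_numpy()[idx],
            "y": elig["y2"].to_numpy()[idx],
            "step_length": elig["length"].to_numpy()[idx],
            "turn_angle": elig["turn_angle"].to_numpy()[idx],
            "C": used_c[idx],
            "N": used_n[idx],
        }
    )
    rep = av_ok[idx].sum(axis=1)
    flat = av_ok[idx].ravel()
    grid = np.repeat(idx, n_avail).reshape(-1)[flat.ravel()]
    avail = pd.DataFrame(
        {
            "stratum_id": stratum_ids[grid],
            "animal_id": aid[grid],
            "is_used": 0,
            "x": ax[idx].ravel()[flat],
            "y": ay[idx].ravel()[flat],
            "step_length": L[idx].ravel()[flat],
            "turn_angle": TA[idx].ravel()[flat],
            "C": av_c[idx].ravel()[flat],
            "N": av_n[idx].ravel()[flat],
        }
    )
    del rep
    out = pd.concat([used, avail], ignore_index=True)
    out["cos_ta"] = np.cos(out["turn_angle"])
    # alternative step-length coding for log-linear formulas
    with np.errstate(divide="ignore"):
        out["log_step_length"] = np.where(
            out["step_length"] > 0, np.log(out["step_length"]), np.nan
        )
    out = out.sort_values(["stratum_id", "is_used"], ascending=[True, False])
    # flag strata whose candidates collapsed onto constant covariates
    av = out[out["is_used"] == 0]
    spread = av.groupby("stratum_id")[["C", "N"]].agg(lambda s: s.max() - s.min())
    n_flat = int((spread.max(axis=1) == 0).sum())
    if n_flat:
        log.warning(
            "%d strata have constant C and N across available candidates "
            "(collapsed kernel?); they are uninformative", n_flat,
        )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# design-matrix helper shared by both regressions


def build_design(table: pd.DataFrame, terms, intercept: bool) -> tuple[np.ndarray, list[str]]:
    """Column-bind model terms; ``A:B`` denotes the product of two columns."""
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(table)))
        names.append("intercept")
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            cols.append(
                np.asarray(table[a], dtype=float) * np.asarray(table[b], dtype=float)
            )
        else:
            cols.append(np.asarray(table[t], dtype=float))
        names.append(t)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# RSF: used/available logistic regression (IRLS/Newton with step halving)


def _bernoulli_loglik(y, eta):
    # log p(y | eta) with logistic link, numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_rsf(
    table: pd.DataFrame,
    terms=RSF_TERMS,
    response_col: str = "response",
    unit_id: str = "pooled",
    scale: str = "landscape",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> SelectionFit:
    """Fit a used/available RSF by logistic regression.

    Newton/IRLS on the Bernoulli log-likelihood with step halving; standard
    errors from the observed information. Complete separation is flagged via
    the ``converged`` field (the fit is returned, not dropped).
    """
    y = np.asarray(table[response_col], dtype=float)
    if not ((y == 0).any() and (y == 1).any()):
        raise ValidationError("both used (1) and available (0) rows are required")
    X, names = build_design(table, terms, intercept=True)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite predictor values")
    n, p = X.shape
    beta = np.zeros(p)
    ll = _bernoulli_loglik(y, X @ beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        g = X.T @ (y - mu)
        if np.linalg.norm(g) < tol:
            # a vanishing gradient with numerically saturated probabilities
            # (|eta| beyond ~18, p within 1e-8 of 0/1) is complete
            # separation — the MLE is at infinity — not convergence
            converged = bool(np.max(np.abs(eta)) < 18.0)
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving on likelihood decrease
        for _h in range(30):
            cand = beta + step
            ll_new = _bernoulli_loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll = _bernoulli_loglik(y, X @ beta)
    if not converged:
        warnings.warn(
            f"RSF for unit {unit_id!r} did not converge "
            "(possible complete separation); coefficients returned as-is"
        )
    mu = special.expit(X @ beta)
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    n_used = int(y.sum())
    n_avail = int(n - n_used)
    pbar = n_used / n
    ll0 = n_used * math.log(pbar) + n_avail * math.log(1 - pbar)
    return SelectionFit(
        unit_id=unit_id,
        scale=scale,
        terms=names,
        beta=dict(zip(names, beta.astype(float))),
        se=dict(zip(names, se.astype(float))),
        vcov=vcov,
        loglik=ll,
        null_loglik=ll0,
        pseudo_r2=pseudo_r2(ll, ll0),
        n_used=n_used,
        n_available=n_avail,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# conditional logistic regression (stratified partial likelihood)


def _stratum_layout(stratum_ids: np.ndarray):
    """Start offsets and counts of contiguous stratum blocks."""
    _, starts, counts = np.unique(stratum_ids, return_index=True, return_counts=True)
    order = np.argsort(starts)
    return starts[order], counts[order]


def conditional_loglik_grad(beta, X, y, starts, counts):
    """Partial log-likelihood and gradient of the conditional logit.

    ``X`` rows must be grouped contiguously by stratum with block start
    offsets ``starts`` and sizes ``counts``; ``y`` marks the single used row
    per stratum. Returns ``(loglik, gradient, hessian)``.
    """
    s = X @ beta
    smax = np.maximum.reduceat(s, starts)
    rep = np.repeat(np.arange(len(starts)), counts)
    e = np.exp(s - smax[rep])
    denom = np.add.reduceat(e, starts)
    P = e / denom[rep]
    ll = float(np.sum((s - smax[rep] - np.log(denom[rep]))[y == 1]))
    grad = X.T @ (y - P)
    PX = P[:, None] * X
    M = np.add.reduceat(PX, starts, axis=0)  # per-stratum E[x]
    H = -(X.T @ PX - M.T @ M)
    return ll, grad, H


def fit_conditional_logit(
    table: pd.DataFrame,
    terms=ISSA_TERMS,
    stratum_col: str = "stratum_id",
    case_col: str = "is_used",
    unit_id: str = "pooled",
    scale: str = "patch",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> SelectionFit:
    """Fit the stratified conditional logit (no intercept) by Newton's method.

    Each stratum must contain exactly one used row and at least two
    available rows; violating strata are dropped with a warning. Terms whose
    within-stratum variation is (numerically) zero carry no information;
    they are flagged in ``meta['zero_information_terms']``.
    """
    df = table.sort_values([stratum_col, case_col], ascending=[True, False])
    counts_per = df.groupby(stratum_col)[case_col].agg(["sum", "count"])
    bad = counts_per[(counts_per["sum"] != 1) | (counts_per["count"] < 3)].index
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} strata without exactly 1 used and >= 2 available rows"
        )
        df = df[~df[stratum_col].isin(bad)]
    if df.empty:
        raise InsufficientDataError("no valid strata for conditional logit")
    X, names = build_design(df, terms, intercept=False)
    y = np.asarray(df[case_col], dtype=float)
    starts, counts = _stratum_layout(df[stratum_col].to_numpy())
    p = X.shape[1]
    beta = np.zeros(p)
    ll, g, H = conditional_loglik_grad(beta, X, y, starts, counts)
    null_ll = float(-np.sum(np.log(counts)))
    info_diag = -np.diag(H)
    zero_info = [names[j] for j in range(p) if info_diag[j] <= 1e-12]
    if zero_info:
        warnings.warn(f"terms with zero within-stratum information: {zero_info}")
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(g) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, g, rcond=None)[0]
        for _h in range(30):
            cand = beta + step
            ll_new, g_new, H_new = conditional_loglik_grad(cand, X, y, starts, counts)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll, g, H = cand, ll_new, g_new, H_new
    if not converged:
        warnings.warn(f"conditional logit for unit {unit_id!r} did not converge")
    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(-H)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    n_used = int(y.sum())
    return SelectionFit(
        unit_id=unit_id,
        scale=scale,
        terms=names,
        beta=dict(zip(names, beta.astype(float))),
        se=dict(zip(names, se.astype(float))),
        vcov=vcov,
        loglik=ll,
        null_loglik=null_ll,
        pseudo_r2=pseudo_r2(ll, null_ll),
        n_used=n_used,
        n_available=int(len(y) - n_used),
        converged=converged,
        meta={"zero_information_terms": zero_info, "n_strata": len(starts)},
    )


def pseudo_r2(loglik: float, null_loglik: float) -> float:
    """McFadden's pseudo-R^2, ``1 - ll/ll0``, clamped to [0, 1]."""
    if null_loglik == 0:
        raise UndefinedStatisticError("null log-likelihood is 0; pseudo-R^2 undefined")
    return float(min(max(1.0 - loglik / null_loglik, 0.0), 1.0))
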