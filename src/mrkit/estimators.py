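"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure associations beta_Xj (SE
se_Xj) and outcome associations beta_Yj (SE se_Yj), the per-variant causal
estimate is the Wald ratio theta_j = beta_Yj / beta_Xj with first-order
delta-method SE se_Yj / |beta_Xj|.

Estimators implemented:

``ivw``
    Inverse-variance-weighted combination of Wald ratios, algebraically a
    weighted least-squares regression of beta_Y on beta_X through the
    origin with weights 1/se_Y^2:

        theta_hat = sum(beta_X beta_Y / se_Y^2) / sum(beta_X^2 / se_Y^2)

    Cochran's Q = sum w_j (theta_j - theta_hat)^2 with w_j =
    beta_X^2/se_Y^2 measures heterogeneity; under the null it is
    chi-square with J-1 df. The random-effects variant inflates the
    fixed-effect SE by max(1, sqrt(Q/(J-1))) — a multiplicative
    overdispersion model that never shrinks the SE below fixed effects.

``egger``
    Weighted regression of beta_Y on beta_X *with* an intercept (weights
    1/se_Y^2), instruments oriented so beta_X >= 0. Under the InSIDE
    assumption the slope is a pleiotropy-adjusted causal effect and the
    intercept estimates the average directional pleiotropic effect; a
    non-zero intercept flags directional pleiotropy. Standard errors carry
    a multiplicative residual scale max(1, sqrt(RSS/(J-2))) and p-values
    use a t distribution with J-2 df.

``weighted_median``
    The weighted median of the Wald ratios (weights beta_X^2/se_Y^2,
    cumulative-midpoint interpolation at 50%), consistent when instruments
    carrying at least half the weight are valid. Its SE comes from a
    seeded parametric bootstrap.

``leave_one_out``
    Random-effects IVW re-estimated J times, each time dropping one
    instrument — an influence diagnostic for single-SNP-driven results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientInstrumentsError
from .harmonize import HarmonizedInstrument, HarmonizedSet

logger = logging.getLogger("mrkit.estimators")

#: Two-sided 95% standard-normal critical value used for reported CIs.
Z_95 = 1.959964


@dataclass
class MREstimate:
    """One method's causal-effect estimate on the log(OR)/SD scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    z_crit: float = Z_95
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise DomainError("MREstimate requires se > 0")
        self.or_, self.ci_low, self.ci_high = format_estimate(
            self.beta, self.se, self.z_crit
        )


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test across instruments."""

    q_stat: float
    df: int
    p_het: float


@dataclass
class EggerPleiotropy:
    """Egger intercept: average directional pleiotropic effect."""

    intercept: float
    intercept_se: float
    p_pleio: float


def format_estimate(beta: float, se: float, z: float = Z_95) -> tuple[float, float, float]:
    """(OR, CI_low, CI_high) = exp(beta), exp(beta -/+ z*se)."""
    if se < 0:
        raise DomainError("se must be >= 0")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
    )


def format_or_ci(beta: float, se: float, z: float = Z_95) -> str:
    """Display string '0.96 (0.95, 0.97)' with 2-d.p. rounding."""
    or_, lo, hi = format_estimate(beta, se, z)
    return f"{or_:.2f} ({lo:.2f}, {hi:.2f})"


def _require(hset: HarmonizedSet, minimum: int, method: str) -> None:
    if len(hset) < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {minimum} instruments, got {len(hset)}"
        )


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-variant causal estimate beta_Y/beta_X (delta-method SE)."""
    if inst.beta_exposure == 0:
        raise DomainError(f"{inst.variant_id}: beta_exposure is 0")
    beta = inst.beta_outcome / inst.beta_exposure
    se = inst.se_outcome / abs(inst.beta_exposure)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MREstimate(method="wald", beta=float(beta), se=float(se), pval=p, n_snps=1)


# ---------------------------------------------------------------------------
# Array-level kernels (shared by leave-one-out, PRESSO and the simulations).


def ivw_arrays(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """(theta_hat, fixed-effect SE, Cochran Q) for plain arrays."""
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    if sxx <= 0:
        raise DomainError("all exposure betas are zero")
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    ratios = by / bx
    wq = bx * bx * w  # weights beta_X^2 / se_Y^2 on the Wald-ratio scale
    q = float(np.sum(wq * (ratios - theta) ** 2))
    return theta, se_fixed, q


def weighted_median_arrays(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    """Weighted median of Wald ratios via cumulative-midpoint interpolation."""
    ratios = by / bx
    w = bx * bx / sy**2
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    wn = w[order] / np.sum(w[order])
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


def _weighted_median_matrix(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (B, J) bootstrap matrices."""
    ratios = by / bx
    w = bx * bx / sy**2
    order = np.argsort(ratios, axis=1, kind="stable")
    r = np.take_along_axis(ratios, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    wn = ws / ws.sum(axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - wn / 2.0
    out = np.empty(r.shape[0])
    for i in range(r.shape[0]):  # np.interp is 1-D only
        out[i] = np.interp(0.5, s[i], r[i])
    return out


# ---------------------------------------------------------------------------
# Public estimators on HarmonizedSet.


def ivw(
    hset: HarmonizedSet, model: str = "random"
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    ``model='fixed'`` uses the analytic fixed-effect SE; ``'random'``
    (the default, and the primary analysis) multiplies it by
    max(1, sqrt(Q/(J-1))).
    """
    if model not in ("fixed", "random"):
        raise DomainError(f"unknown IVW model '{model}'")
    _require(hset, 2, "ivw")
    bx, _, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise DomainError("ivw requires non-zero exposure betas (Wald ratios undefined)")
    theta, se_fixed, q = ivw_arrays(bx, by, sy)
    j = len(hset)
    df = j - 1
    p_het = float(stats.chi2.sf(q, df))
    if model == "random":
        se = se_fixed * max(1.0, np.sqrt(q / df))
        method = "ivw_random"
    else:
        se = se_fixed
        method = "ivw_fixed"
    p = float(2.0 * stats.norm.sf(abs(theta / se)))
    est = MREstimate(method=method, beta=theta, se=float(se), pval=p, n_snps=j)
    return est, HeterogeneityResult(q_stat=q, df=df, p_het=p_het)


def egger(hset: HarmonizedSet) -> tuple[MREstimate, EggerPleiotropy]:
    """MR-Egger regression: pleiotropy-adjusted slope plus intercept test.

    Instruments are oriented so beta_X >= 0 (both betas negated when
    beta_X < 0); instruments with beta_X exactly 0 are dropped with a log
    line since they carry no orientation.
    """
    _require(hset, 3, "egger")
    bx, _, by, sy = hset.arrays()
    nz = bx != 0
    if not np.all(nz):
        logger.info("egger: dropping %d instrument(s) with beta_exposure == 0", int((~nz).sum()))
        bx, by, sy = bx[nz], by[nz], sy[nz]
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError(f"egger needs >= 3 usable instruments, got {j}")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2

    # Closed-form 2-parameter WLS: solve (X'WX) b = X'Wy.
    sw = np.sum(w)
    swx = np.sum(w * x)
    swxx = np.sum(w * x * x)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise DomainError("degenerate Egger design (no spread in exposure betas)")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss / (j - 2)))
    se_intercept = scale * np.sqrt(swxx / det)
    se_slope = scale * np.sqrt(sw / det)
    dfree = j - 2
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), dfree))
    p_intercept = float(2.0 * stats.t.sf(abs(intercept / se_intercept), dfree))
    est = MREstimate(
        method="egger", beta=float(slope), se=float(se_slope), pval=p_slope, n_snps=j
    )
    pleio = EggerPleiotropy(
        intercept=float(intercept), intercept_se=float(se_intercept), p_pleio=p_intercept
    )
    return est, pleio


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimate; SE from a seeded parametric bootstrap.

    The bootstrap redraws beta_Xj ~ N(beta_Xj, se_Xj) and
    beta_Yj ~ N(beta_Yj, se_Yj), recomputes the weighted median each
    time, and reports the standard deviation over ``n_boot`` draws.
    """
    _require(hset, 3, "weighted_median")
    if n_boot < 1:
        raise DomainError("n_boot must be >= 1")
    bx, sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise DomainError("weighted_median requires non-zero exposure betas")
    est = weighted_median_arrays(bx, by, sy)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)  # guard degenerate draw
    boots = _weighted_median_matrix(bxs, bys, np.broadcast_to(sy, bxs.shape))
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float(np.std(boots))
    if se == 0:
        se = np.finfo(float).tiny
    p = float(2.0 * stats.norm.sf(abs(est / se)))
    return MREstimate(
        method="weighted_median", beta=est, se=se, pval=p, n_snps=len(hset)
    )


def leave_one_out(hset: HarmonizedSet) -> list[tuple[str, MREstimate]]:
    """Random-effects IVW dropping each instrument in turn (input order)."""
    _require(hset, 3, "leave_one_out")
    results = []
    for i, inst in enumerate(hset.instruments):
        sub = HarmonizedSet(
            instruments=hset.instruments[:i] + hset.instruments[i + 1 :],
            exclusions=[],
        )
        est, _ = ivw(sub, model="random")
        results.append((inst.variant_id, est))
    return results


def scatter_data(hset: HarmonizedSet, z: float = Z_95):
    """Per-SNP table behind the scatter/forest plots.

    Columns: variant_id, beta_exposure, se_exposure, beta_outcome,
    se_outcome, wald_ratio, wald_se, ci_low, ci_high.
    """
    import pandas as pd

    bx, sx, by, sy = hset.arrays()
    ratio = by / bx
    rse = sy / np.abs(bx)
    return pd.DataFrame(
        {
            "variant_id": hset.ids,
            "beta_exposure": bx,
            "se_exposure": sx,
            "beta_outcome": by,
            "se_outcome": sy,
            "wald_ratio": ratio,
            "wald_se": rse,
            "ci_low": ratio - z * rse,
            "ci_high": ratio + z * rse,
        }
    )
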