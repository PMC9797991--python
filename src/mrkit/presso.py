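"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

The test asks whether any instrument's outcome association deviates from
what the other instruments' causal estimate predicts. For instrument j,
let theta_-j be the IVW slope computed without j. The observed residual is

    RSS_j = (beta_Yj - theta_-j * beta_Xj)^2 / se_Yj^2

and the global statistic is the sum over j. Its null distribution is
simulated: replicate datasets draw beta*_Xj ~ N(beta_Xj, se_Xj) and
beta*_Yj ~ N(theta_-j * beta_Xj, se_Yj) and the statistic is recomputed in
full (leave-one-out slopes re-estimated on the simulated data). P-values
use the add-one estimator (1 + #{sim >= obs}) / (n_sim + 1), so they are
never exactly zero; per-instrument outlier p-values are Bonferroni
adjusted by J.

When outliers are flagged, the outlier-corrected estimate is the
random-effects IVW on the remaining instruments, and the distortion test
asks whether correction changed the estimate more than removing a random
subset of the same size would: D = 100 * (theta_corr - theta_orig) /
|theta_orig|, with a two-sided tail proportion against the random-removal
null.

Note on resolution: the smallest attainable Bonferroni-adjusted outlier
p-value is J/(n_sim+1). If that already exceeds ``outlier_alpha`` no
instrument can ever be flagged; the function warns and the caller should
raise ``n_sim`` (e.g. 5000 for J around 50-100 at alpha 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, ivw
from .exceptions import DomainError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet

DEFAULT_N_SIM = 1000
DEFAULT_OUTLIER_ALPHA = 0.05
N_DISTORTION = 1000


@dataclass
class PressoResult:
    """Global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    outlier_pvals: np.ndarray  # Bonferroni-adjusted, input order
    outlier_ids: list[str]
    corrected: MREstimate | None
    distortion_p: float  # NaN when not applicable (no outliers)
    n_sim: int
    seed: int | None


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope excluding each instrument in turn, vectorized.

    Works on 1-D arrays or (B, J) matrices (row-wise).
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    seed: int | None = None,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized set.

    Requires at least 4 instruments and ``n_sim >= 100``; exposure-side
    standard errors are required inputs for the simulation draws.
    """
    j = len(hset)
    if j < 4:
        raise InsufficientInstrumentsError(f"presso needs >= 4 instruments, got {j}")
    if n_sim < 100:
        raise DomainError("n_sim must be >= 100")
    bx, sx, by, sy = hset.arrays()
    if np.any(~np.isfinite(sx)) or np.any(sx <= 0):
        raise DomainError("presso requires positive exposure standard errors")
    if np.any(bx == 0):
        raise DomainError("presso requires non-zero exposure betas")

    min_adj_p = j / (n_sim + 1.0)
    if min_adj_p >= outlier_alpha:
        warnings.warn(
            f"n_sim={n_sim} too small to flag outliers at alpha={outlier_alpha} "
            f"with J={j} (smallest adjusted p is {min_adj_p:.3g}); increase n_sim",
            stacklevel=2,
        )

    w = 1.0 / sy**2
    theta_loo = _loo_slopes(bx, by, w)
    obs_rss_j = w * (by - theta_loo * bx) ** 2
    global_rss = float(np.sum(obs_rss_j))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, j))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    theta_loo_s = _loo_slopes(bx_s, by_s, w)
    rss_j_s = w * (by_s - theta_loo_s * bx_s) ** 2
    global_s = rss_j_s.sum(axis=1)

    global_p = float((1 + np.sum(global_s >= global_rss)) / (n_sim + 1))
    raw_p = (1 + np.sum(rss_j_s >= obs_rss_j, axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * j)
    flagged = adj_p < outlier_alpha
    outlier_ids = [vid for vid, f in zip(hset.ids, flagged) if f]

    corrected: MREstimate | None = None
    distortion_p = float("nan")
    if outlier_ids:
        keep = [i for i, f in zip(hset.instruments, flagged) if not f]
        if len(keep) >= 2:
            corrected, _ = ivw(HarmonizedSet(instruments=keep, exclusions=[]), "random")
            theta_orig, _, _ = _ivw_point(bx, by, w)
            d_obs = 100.0 * (corrected.beta - theta_orig) / abs(theta_orig)
            k = int(flagged.sum())
            d_null = np.empty(N_DISTORTION)
            for i in range(N_DISTORTION):
                drop = rng.choice(j, size=k, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                theta_sub, _, _ = _ivw_point(bx[mask], by[mask], w[mask])
                d_null[i] = 100.0 * (theta_sub - theta_orig) / abs(theta_orig)
            distortion_p = float(np.mean(np.abs(d_null) >= abs(d_obs)))
        else:
            warnings.warn("fewer than 2 non-outlier instruments; no corrected estimate")
    else:
        full, _ = ivw(hset, "random")
        corrected = full  # no outliers: corrected equals original

    return PressoResult(
        global_rss=global_rss,
        global_p=global_p,
        outlier_pvals=adj_p,
        outlier_ids=outlier_ids,
        corrected=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def _ivw_point(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    sxx = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by)) / sxx
    return theta, sxx, 0.0
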