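"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the summary-statistics layout of a two-sample MR
study of a standardized continuous exposure on a standardized continuous
outcome. For each of J independent variants:

* MAF ~ Uniform(maf_range); the effect allele is the minor one.
* True exposure effect gamma_j: drawn zero-mean normal, then rescaled so
  the aggregate variance explained sum 2*MAF(1-MAF)*gamma^2 equals
  ``r2_target`` exactly.
* se_Xj = (2*MAF(1-MAF)*n_exposure)^(-1/2) — the standard-error anatomy of
  a per-allele regression on a unit-variance trait — and observed
  beta_Xj ~ N(gamma_j, se_Xj).
* Direct (pleiotropic) outcome effect alpha_j ~ N(mu_alpha, sigma_alpha);
  ``n_outliers`` randomly chosen variants instead get |alpha_j| =
  outlier_scale * se_Yj (gross horizontal pleiotropy).
* se_Yj = (2*MAF(1-MAF)*n_outcome)^(-1/2) and observed
  beta_Yj ~ N(theta*gamma_j + alpha_j, se_Yj), with exposure and outcome
  noise independent (non-overlapping samples).

A configurable fraction of variants receives palindromic (A/T, C/G)
allele pairs, and configurable fractions of outcome records are written
allele-swapped or strand-recoded, so harmonization is exercised end to
end. The returned truth table records gamma, alpha, the unperturbed
observed betas and the perturbation applied per variant.

All randomness flows from one seed through named child streams (one
stream per quantity, one draw per SNP in index order), so enlarging
``j_snps`` appends new draws without reshuffling earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import GenerationError
from .sumstats_io import MIN_PVAL, SummaryDataset, SummaryStatRecord

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Stream names, in spawn order (stable across versions of this module).
_STREAMS = ("maf", "gamma", "pleiotropy", "noise_x", "noise_y", "alleles")


@dataclass
class SyntheticScenario:
    """Generative parameters for one two-sample summary-statistics draw.

    Defaults mirror the urate -> telomere-length study design: 101
    LD-independent instruments from an exposure GWAS of n=288,649
    explaining ~10.2% of exposure variance, and an outcome GWAS of
    n=472,174, with a causal effect of -0.040 SD per SD.
    """

    j_snps: int = 101
    n_exposure: float = 288_649
    n_outcome: float = 472_174
    theta: float = -0.040
    r2_target: float = 0.1021
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    outlier_scale: float = 10.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.0
    frac_swapped: float = 0.0
    frac_strand_flipped: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_snps < 3:
            raise GenerationError("j_snps must be >= 3")
        if not (0.0 < self.r2_target < 1.0):
            raise GenerationError("r2_target must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise GenerationError("maf_range bounds must lie in (0, 0.5] with lo <= hi")
        if self.n_outliers < 0 or self.n_outliers > self.j_snps:
            raise GenerationError("n_outliers must lie in [0, j_snps]")
        for frac in (self.frac_palindromic, self.frac_swapped, self.frac_strand_flipped):
            if not (0.0 <= frac <= 1.0):
                raise GenerationError("fractions must lie in [0, 1]")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _records(ids, ea, oa, eaf, beta, se, n) -> list[SummaryStatRecord]:
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return [
        SummaryStatRecord(
            variant_id=i, effect_allele=a1, other_allele=a2,
            eaf=float(f), beta=float(b), se=float(s),
            pval=float(max(p, MIN_PVAL)), n=n,
        )
        for i, a1, a2, f, b, s, p in zip(ids, ea, oa, eaf, beta, se, pvals)
    ]


def generate(
    scenario: SyntheticScenario,
) -> tuple[SummaryDataset, SummaryDataset, pd.DataFrame]:
    """Draw one two-sample dataset; returns (exposure, outcome, truth).

    The truth table has one row per variant (variant_id, maf, gamma,
    alpha, beta_x, beta_y, se_x, se_y, is_outlier, is_palindromic,
    swapped, strand_flipped) plus ``truth.attrs['theta']``.
    """
    sc = scenario
    rng = _rngs(sc.seed)
    j = sc.j_snps

    maf = rng["maf"].uniform(sc.maf_range[0], sc.maf_range[1], size=j)
    var_per_allele = 2.0 * maf * (1.0 - maf)

    # Effects are reported for the exposure-increasing allele (half-normal
    # magnitudes), the convention of published instrument lists; directional
    # pleiotropy is then directional *relative to that orientation*, which
    # is what the Egger intercept estimates.
    raw_gamma = np.abs(rng["gamma"].standard_normal(j))
    denom = float(np.sum(var_per_allele * raw_gamma**2))
    if denom <= 0:
        raise GenerationError("degenerate draw: zero aggregate variance before rescaling")
    gamma = raw_gamma * np.sqrt(sc.r2_target / denom)
    if np.any(var_per_allele * gamma**2 >= 1.0):
        raise GenerationError(
            "r2_target infeasible: a single variant would explain >= 100% of variance"
        )

    se_x = 1.0 / np.sqrt(var_per_allele * sc.n_exposure)
    se_y = 1.0 / np.sqrt(var_per_allele * sc.n_outcome)

    rng_p = rng["pleiotropy"]
    alpha = rng_p.normal(sc.pleiotropy_mean, sc.pleiotropy_sd, size=j) \
        if sc.pleiotropy_sd > 0 else np.full(j, sc.pleiotropy_mean)
    is_outlier = np.zeros(j, dtype=bool)
    if sc.n_outliers:
        idx = rng_p.choice(j, size=sc.n_outliers, replace=False)
        signs = rng_p.choice([-1.0, 1.0], size=sc.n_outliers)
        alpha[idx] = signs * sc.outlier_scale * se_y[idx]
        is_outlier[idx] = True

    beta_x = gamma + rng["noise_x"].normal(0.0, se_x)
    beta_y = sc.theta * gamma + alpha + rng["noise_y"].normal(0.0, se_y)

    rng_a = rng["alleles"]
    ids = [f"rs{100000 + k}" for k in range(j)]
    is_pal = rng_a.random(j) < sc.frac_palindromic
    pair_pick = rng_a.integers(0, 8, size=j)  # drawn per SNP regardless of branch
    ea = np.empty(j, dtype=object)
    oa = np.empty(j, dtype=object)
    for k in range(j):
        pool = _PALINDROMIC_PAIRS if is_pal[k] else _NONPALINDROMIC_PAIRS
        a1, a2 = pool[pair_pick[k] % len(pool)]
        ea[k], oa[k] = a1, a2
    swapped = rng_a.random(j) < sc.frac_swapped
    strand = rng_a.random(j) < sc.frac_strand_flipped

    exposure = SummaryDataset(
        trait_label="synthetic_exposure",
        records=_records(ids, ea, oa, maf, beta_x, se_x, sc.n_exposure),
        default_n=sc.n_exposure,
        metadata={"scenario": "synthetic", "seed": sc.seed},
    )

    # Outcome file: optionally allele-swapped and/or strand-recoded records.
    out_ea, out_oa = ea.copy(), oa.copy()
    out_beta, out_eaf = beta_y.copy(), maf.copy()
    for k in range(j):
        if swapped[k]:
            out_ea[k], out_oa[k] = out_oa[k], out_ea[k]
            out_beta[k] = -out_beta[k]
            out_eaf[k] = 1.0 - out_eaf[k]
        if strand[k]:
            out_ea[k] = _COMPLEMENT[out_ea[k]]
            out_oa[k] = _COMPLEMENT[out_oa[k]]
    outcome = SummaryDataset(
        trait_label="synthetic_outcome",
        records=_records(ids, out_ea, out_oa, out_eaf, out_beta, se_y, sc.n_outcome),
        default_n=sc.n_outcome,
        metadata={"scenario": "synthetic", "seed": sc.seed},
    )

    truth = pd.DataFrame(
        {
            "variant_id": ids,
            "maf": maf,
            "gamma": gamma,
            "alpha": alpha,
            "beta_x": beta_x,
            "beta_y": beta_y,
            "se_x": se_x,
            "se_y": se_y,
            "is_outlier": is_outlier,
            "is_palindromic": is_pal,
            "swapped": swapped,
            "strand_flipped": strand,
        }
    )
    truth.attrs["theta"] = sc.theta
    return exposure, outcome, truth


#: Named scenarios mirroring the study's data sources.
_PRESETS: dict[str, SyntheticScenario] = {
    # LTL-like: UK Biobank-scale outcome (n=472,174), 101 instruments
    # explaining 10.21% of exposure variance, causal effect -0.040 SD/SD.
    "ltl-like": SyntheticScenario(),
    # INTERVAL-protein-like: small proteomics outcome (n=3,301), 113
    # instruments, R^2=11.24%; effect ln(0.8), the size the design is
    # powered for.
    "interval-protein-like": SyntheticScenario(
        j_snps=113, n_outcome=3_301, r2_target=0.1124,
        theta=float(np.log(0.8)),
    ),
    # Directional pleiotropy: every variant carries a positive direct
    # effect (violates IVW's no-pleiotropy assumption; Egger's target).
    "directional-pleiotropy": SyntheticScenario(
        pleiotropy_mean=0.002, pleiotropy_sd=0.001
    ),
    # A handful of gross outliers on an otherwise clean set (PRESSO's
    # target).
    "outlier-contaminated": SyntheticScenario(n_outliers=4, outlier_scale=10.0),
}


def scenario_presets() -> dict[str, SyntheticScenario]:
    """Copies of the named scenario presets."""
    return {name: replace(sc) for name, sc in _PRESETS.items()}


def get_preset(name: str, seed: int | None = None) -> SyntheticScenario:
    """Look one preset up by name, optionally overriding the seed."""
    try:
        sc = replace(_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset '{name}'; available: {sorted(_PRESETS)}"
        ) from None
    if seed is not None:
        sc = replace(sc, seed=seed)
    return sc
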