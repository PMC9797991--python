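"""Instrument-strength QC: F-statistics, variance explained, weak filter.

The per-variant F-statistic is approximated by the squared t-ratio
F = (beta/se)^2, the standard large-sample identity for a single-SNP
regression. Variance explained per variant follows from the same
regression anatomy: R^2 = F / (F + n - 2). The aggregate R^2 is a plain
sum over instruments, valid because the instrument set is LD-pruned to
independence upstream. A frequency-based alternative
R^2 = 2*MAF*(1-MAF)*beta^2 (standardized trait) is available when sample
size is unreliable but frequencies are not.

Instruments with F below a threshold (conventionally 10) are moved to the
exclusion log as weak: weak instruments bias two-sample MR estimates
toward the null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DomainError
from .harmonize import WEAK_INSTRUMENT, HarmonizedSet

DEFAULT_F_THRESHOLD = 10.0


@dataclass
class InstrumentStrength:
    """Per-variant and aggregate strength of an instrument set."""

    f_stat: np.ndarray
    r2: np.ndarray
    r2_total: float


def f_statistic(beta_exposure, se_exposure):
    """Approximate per-variant F-statistic, (beta/se)^2.

    Accepts scalars or arrays; raises
    :class:`~mrkit.exceptions.DomainError` for non-positive SEs.
    """
    beta = np.asarray(beta_exposure, dtype=float)
    se = np.asarray(se_exposure, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se_exposure must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def variance_explained(f_stat, n):
    """Per-variant R^2 from the F-statistic: F / (F + n - 2)."""
    f = np.asarray(f_stat, dtype=float)
    if np.any(f < 0):
        raise DomainError("f_stat must be >= 0")
    if n is None or n <= 2:
        raise DomainError("exposure sample size n must exceed 2")
    out = f / (f + n - 2.0)
    return float(out) if out.ndim == 0 else out


def r2_from_frequency(beta, eaf):
    """Frequency-based R^2 = 2*eaf*(1-eaf)*beta^2 for a unit-variance trait."""
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf < 0) | (eaf > 1)):
        raise DomainError("eaf must lie in [0, 1]")
    out = 2.0 * eaf * (1.0 - eaf) * beta**2
    return float(out) if out.ndim == 0 else out


def attach_strength(
    hset: HarmonizedSet, n_exposure: float, method: str = "f"
) -> InstrumentStrength:
    """Fill ``f_stat`` on every instrument and return strength summaries.

    ``method`` selects the R^2 formula: ``"f"`` (from the F-statistic and
    n, the default) or ``"frequency"`` (from eaf; requires eaf on every
    instrument).
    """
    bx = np.array([i.beta_exposure for i in hset.instruments], dtype=float)
    sx = np.array([i.se_exposure for i in hset.instruments], dtype=float)
    f = f_statistic(bx, sx) if len(bx) else np.empty(0)
    for inst, fj in zip(hset.instruments, np.atleast_1d(f)):
        inst.f_stat = float(fj)
    if method == "f":
        r2 = variance_explained(f, n_exposure) if len(bx) else np.empty(0)
    elif method == "frequency":
        eaf = [i.eaf_exposure for i in hset.instruments]
        if any(e is None for e in eaf):
            raise DomainError("frequency-based R^2 requires eaf on every instrument")
        r2 = r2_from_frequency(bx, np.array(eaf, dtype=float))
    else:
        raise DomainError(f"unknown R^2 method '{method}'")
    r2 = np.atleast_1d(r2)
    return InstrumentStrength(
        f_stat=np.atleast_1d(f), r2=r2, r2_total=float(np.sum(r2))
    )


def filter_weak(
    hset: HarmonizedSet, threshold: float = DEFAULT_F_THRESHOLD
) -> HarmonizedSet:
    """Move instruments with F below ``threshold`` to the exclusion log."""
    if any(i.f_stat is None for i in hset.instruments):
        raise DomainError("f_stat not populated; call attach_strength first")
    kept = [replace(i) for i in hset.instruments if i.f_stat >= threshold]
    excl = list(hset.exclusions) + [
        (i.variant_id, WEAK_INSTRUMENT)
        for i in hset.instruments
        if i.f_stat < threshold
    ]
    return HarmonizedSet(instruments=kept, exclusions=excl)
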