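"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR combines per-variant associations estimated in different
studies, which may report effects relative to different alleles or on
opposite DNA strands. Harmonization re-expresses every outcome effect per
copy of the exposure's effect allele:

* same allele pair, same order — kept unchanged;
* swapped alleles — outcome beta negated, frequency complemented;
* complementary-strand report — alleles recoded (A<->T, C<->G) before
  comparison, then aligned as above;
* palindromic variants (A/T or C/G) — strand cannot be inferred from the
  alleles; they are aligned by allele-frequency agreement when the
  frequency is informative, and excluded as ambiguous when it is near 0.5
  or missing.

Every excluded variant is logged with a reason code so the instrument
accounting stays auditable: |instruments| + |exclusions| equals the number
of exposure instruments presented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InputError
from .sumstats_io import SummaryDataset, SummaryStatRecord

logger = logging.getLogger("mrkit.harmonize")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Exclusion reason codes.
NOT_IN_OUTCOME = "not_in_outcome"
PALINDROMIC_AMBIGUOUS = "palindromic_ambiguous"
ALLELE_MISMATCH = "allele_mismatch"
WEAK_INSTRUMENT = "weak_instrument"
CONFOUNDER_ASSOCIATED = "confounder_associated"

KNOWN_REASONS = frozenset(
    {NOT_IN_OUTCOME, PALINDROMIC_AMBIGUOUS, ALLELE_MISMATCH, WEAK_INSTRUMENT,
     CONFOUNDER_ASSOCIATED}
)

#: Default half-width of the ambiguous-frequency window for palindromic
#: variants: eaf in (0.5 - w, 0.5 + w) cannot be strand-resolved reliably.
DEFAULT_PALINDROMIC_WINDOW = 0.08


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand is ambiguous."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedInstrument:
    """An exposure/outcome-aligned variant ready for MR estimation."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None = None
    flags: frozenset[str] = frozenset()
    f_stat: float | None = None


@dataclass
class HarmonizedSet:
    """Aligned instruments plus a per-variant exclusion log."""

    instruments: list[HarmonizedInstrument]
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def ids(self) -> list[str]:
        return [inst.variant_id for inst in self.instruments]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_X, se_X, beta_Y, se_Y) as float arrays."""
        bx = np.array([i.beta_exposure for i in self.instruments], dtype=float)
        sx = np.array([i.se_exposure for i in self.instruments], dtype=float)
        by = np.array([i.beta_outcome for i in self.instruments], dtype=float)
        sy = np.array([i.se_outcome for i in self.instruments], dtype=float)
        return bx, sx, by, sy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.ids,
                "beta_exposure": [i.beta_exposure for i in self.instruments],
                "se_exposure": [i.se_exposure for i in self.instruments],
                "beta_outcome": [i.beta_outcome for i in self.instruments],
                "se_outcome": [i.se_outcome for i in self.instruments],
                "eaf_exposure": [
                    np.nan if i.eaf_exposure is None else i.eaf_exposure
                    for i in self.instruments
                ],
                "flags": [";".join(sorted(i.flags)) for i in self.instruments],
                "f_stat": [np.nan if i.f_stat is None else i.f_stat for i in self.instruments],
            }
        )

    def exclusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["variant_id", "reason"])


def _in_window(eaf: float, w: float) -> bool:
    return (0.5 - w) < eaf < (0.5 + w)


def resolve_alleles(
    exp_ea: str,
    exp_oa: str,
    out_ea: str,
    out_oa: str,
    exp_eaf: float | None,
    out_eaf: float | None,
    window: float,
) -> tuple[str, frozenset[str] | None]:
    """Classify one variant's allele configuration.

    Returns ``(verdict, flags)`` where verdict is one of ``keep``,
    ``flip``, ``palindromic_ambiguous`` or ``allele_mismatch``; flags may
    contain ``flipped`` and/or ``strand_corrected``.
    """
    if is_palindromic(exp_ea, exp_oa):
        # Strand recoding equals an allele swap, so the labels alone cannot
        # orient the variant; alignment rests on frequency agreement alone.
        if {out_ea, out_oa} != {exp_ea, exp_oa}:
            return ALLELE_MISMATCH, None
        if exp_eaf is None or out_eaf is None:
            return PALINDROMIC_AMBIGUOUS, None
        if _in_window(exp_eaf, window) or _in_window(out_eaf, window):
            return PALINDROMIC_AMBIGUOUS, None
        if (exp_eaf < 0.5) == (out_eaf < 0.5):
            return "keep", frozenset()
        return "flip", frozenset({"flipped"})

    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "keep", frozenset()
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "flip", frozenset({"flipped"})
    rec_ea, rec_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
    if (rec_ea, rec_oa) == (exp_ea, exp_oa):
        return "keep", frozenset({"strand_corrected"})
    if (rec_ea, rec_oa) == (exp_oa, exp_ea):
        return "flip", frozenset({"flipped", "strand_corrected"})
    return ALLELE_MISMATCH, None


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_window: float = DEFAULT_PALINDROMIC_WINDOW,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Iterates the exposure instruments in order; each is either retained
    (possibly sign-flipped / strand-recoded) or logged with an exclusion
    reason. Raises :class:`~mrkit.exceptions.InputError` when no exposure
    variant is present in the outcome dataset.
    """
    if not (0.0 <= palindromic_window < 0.5):
        raise InputError("palindromic_window must lie in [0, 0.5)")
    out_by_id = outcome.by_id()
    instruments: list[HarmonizedInstrument] = []
    exclusions: list[tuple[str, str]] = []

    shared = [r.variant_id for r in exposure.records if r.variant_id in out_by_id]
    if not shared:
        raise InputError(
            f"no shared variants between exposure '{exposure.trait_label}' and "
            f"outcome '{outcome.trait_label}'; exposure IDs: "
            f"{[r.variant_id for r in exposure.records[:10]]} ..."
        )

    for exp in exposure.records:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            exclusions.append((exp.variant_id, NOT_IN_OUTCOME))
            continue
        verdict, flags = resolve_alleles(
            exp.effect_allele,
            exp.other_allele,
            out.effect_allele,
            out.other_allele,
            exp.eaf,
            out.eaf,
            palindromic_window,
        )
        if verdict in (PALINDROMIC_AMBIGUOUS, ALLELE_MISMATCH):
            exclusions.append((exp.variant_id, verdict))
            continue
        beta_out = out.beta if verdict == "keep" else -out.beta
        instruments.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                eaf_exposure=exp.eaf,
                flags=flags,
            )
        )
    logger.info(
        "harmonized %d instruments, excluded %d", len(instruments), len(exclusions)
    )
    return HarmonizedSet(instruments=instruments, exclusions=exclusions)


def harmonized_to_datasets(
    hset: HarmonizedSet, exposure_label: str = "exposure", outcome_label: str = "outcome"
) -> tuple[SummaryDataset, SummaryDataset]:
    """Re-export a harmonized set as two aligned datasets (A/G placeholder
    alleles, shared orientation) — used to check idempotence and to feed
    tools expecting raw summary statistics."""
    from scipy import stats

    def _records(betas, ses, eafs, ids):
        recs = []
        for vid, b, s, f in zip(ids, betas, ses, eafs):
            p = float(2.0 * stats.norm.sf(abs(b / s)))
            recs.append(
                SummaryStatRecord(
                    variant_id=vid, effect_allele="A", other_allele="G",
                    beta=float(b), se=float(s), pval=max(p, np.nextafter(0, 1)),
                    eaf=f,
                )
            )
        return recs

    bx, sx, by, sy = hset.arrays()
    eafs = [i.eaf_exposure for i in hset.instruments]
    exp = SummaryDataset(exposure_label, _records(bx, sx, eafs, hset.ids))
    out = SummaryDataset(outcome_label, _records(by, sy, eafs, hset.ids))
    return exp, out


def apply_exclusions(
    hset: HarmonizedSet, exclude_ids, reason: str = CONFOUNDER_ASSOCIATED
) -> HarmonizedSet:
    """Move named instruments to the exclusion log (order preserved).

    IDs not present are ignored with a log line. The input set is not
    modified.
    """
    if reason not in KNOWN_REASONS:
        raise InputError(f"unknown exclusion reason '{reason}'; known: {sorted(KNOWN_REASONS)}")
    exclude = set(exclude_ids)
    present = {i.variant_id for i in hset.instruments}
    for vid in exclude - present:
        logger.info("exclusion id %s not among instruments; ignored", vid)
    kept = [replace(i) for i in hset.instruments if i.variant_id not in exclude]
    new_exclusions = list(hset.exclusions) + [
        (i.variant_id, reason) for i in hset.instruments if i.variant_id in exclude
    ]
    return HarmonizedSet(instruments=kept, exclusions=new_exclusions)
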