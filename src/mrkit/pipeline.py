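"""End-to-end pipeline: harmonize -> QC -> estimate -> diagnostics -> report.

One configuration drives the whole analysis for one exposure against any
number of outcomes. Per outcome the pipeline writes:

* ``<label>.harmonized.tsv`` / ``<label>.exclusions.tsv`` — aligned
  instruments with F-statistics, and the per-variant exclusion log;
* ``<label>.results.tsv`` — the per-method causal-effect table (IVW
  random-effects as primary, Egger, weighted median, plus PRESSO
  outlier-corrected and distortion rows), with heterogeneity and
  Egger-intercept p-values;
* ``<label>.loo.tsv`` — leave-one-out estimates;
* ``<label>.scatter.tsv`` — per-SNP effects and Wald ratios (the data
  behind scatter/forest plots);

plus one ``manifest.json`` recording package/library versions, the seed
and a hash of the configuration, so a rerun is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (
    egger,
    format_or_ci,
    ivw,
    leave_one_out,
    scatter_data,
    weighted_median,
)
from .exceptions import ConfigurationError, PipelineError
from .harmonize import DEFAULT_PALINDROMIC_WINDOW, apply_exclusions, harmonize
from .instruments import DEFAULT_F_THRESHOLD, attach_strength, filter_weak
from .presso import presso as run_presso
from .sumstats_io import read_sumstats, write_results_table

logger = logging.getLogger("mrkit.pipeline")

ALL_METHODS = ("ivw", "egger", "weighted_median", "presso")


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline once."""

    exposure_path: str
    outcome_paths: dict[str, str]  # label -> path
    out_dir: str = "mr_results"
    exposure_n: float | None = None
    outcome_ns: dict[str, float] = field(default_factory=dict)
    exclude_path: str | None = None  # file of rsIDs (confounder-associated)
    palindromic_window: float = DEFAULT_PALINDROMIC_WINDOW
    min_f: float = DEFAULT_F_THRESHOLD
    methods: tuple[str, ...] = ALL_METHODS
    nboot: int = 1000
    nsim: int = 1000
    alpha: float = 0.05
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class OutcomeResult:
    """In-memory bundle of one outcome's results."""

    label: str
    hset: object
    estimates: list
    diagnostics: dict
    presso_result: object | None
    loo: list
    results_table: pd.DataFrame


def _stage(label: str, stage: str):
    """Context that re-raises stage errors with outcome/stage attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{label}/{stage}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict[str, OutcomeResult]:
    """Run the full analysis; returns per-outcome results, writes files."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("exposure", "read"):
        exposure = read_sumstats(
            config.exposure_path, default_n=config.exposure_n, trait_label="exposure"
        )
    exclude_ids: list[str] = []
    if config.exclude_path:
        exclude_ids = [
            line.strip()
            for line in Path(config.exclude_path).read_text().splitlines()
            if line.strip()
        ]

    results: dict[str, OutcomeResult] = {}
    for label, path in config.outcome_paths.items():
        results[label] = _run_one_outcome(config, exposure, label, path, exclude_ids, out_dir)

    manifest = {
        "mrkit_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "outcomes": sorted(results),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results


def _run_one_outcome(
    config: PipelineConfig,
    exposure,
    label: str,
    path: str,
    exclude_ids: list[str],
    out_dir: Path,
) -> OutcomeResult:
    with _stage(label, "read"):
        outcome = read_sumstats(
            path, default_n=config.outcome_ns.get(label), trait_label=label
        )
    with _stage(label, "harmonize"):
        hset = harmonize(exposure, outcome, config.palindromic_window)
        if exclude_ids:
            hset = apply_exclusions(hset, exclude_ids)
    with _stage(label, "qc"):
        n_exp = config.exposure_n or exposure.default_n
        if n_exp is None:
            # Fall back to per-record n if any; frequency method otherwise.
            ns = [exposure.record_n(r) for r in exposure.records]
            n_exp = float(np.nanmedian([n for n in ns if n is not None])) if any(ns) else None
        strength = None
        if n_exp:
            attach_strength(hset, n_exposure=n_exp)
            hset = filter_weak(hset, config.min_f)
            # Recompute on the retained set so per-variant columns align.
            strength = attach_strength(hset, n_exposure=n_exp)

    estimates = []
    diagnostics: dict[str, dict] = {}
    presso_result = None
    loo: list = []

    if "ivw" in config.methods:
        with _stage(label, "ivw"):
            est, het = ivw(hset, model="random")
            estimates.append(est)
            diagnostics[est.method] = {"p_het": het.p_het, "q": het.q_stat, "df": het.df}
    if "egger" in config.methods:
        with _stage(label, "egger"):
            est, pleio = egger(hset)
            _, het = ivw(hset, model="random")
            estimates.append(est)
            diagnostics[est.method] = {
                "p_het": het.p_het,
                "p_pleio": pleio.p_pleio,
                "intercept": pleio.intercept,
                "intercept_se": pleio.intercept_se,
            }
    if "weighted_median" in config.methods:
        with _stage(label, "weighted_median"):
            est = weighted_median(hset, n_boot=config.nboot, seed=config.seed)
            estimates.append(est)
    if "presso" in config.methods:
        with _stage(label, "presso"):
            presso_result = run_presso(
                hset, n_sim=config.nsim, outlier_alpha=config.alpha, seed=config.seed
            )
            if presso_result.corrected is not None:
                # Corrected equals the original estimate when nothing is
                # flagged; the row is kept either way, as in the published
                # table layout.
                from dataclasses import replace as _replace

                estimates.append(_replace(presso_result.corrected, method="mr_presso"))

    with _stage(label, "leave_one_out"):
        loo = leave_one_out(hset)

    with _stage(label, "report"):
        table = write_results_table(
            estimates, diagnostics, out_dir / f"{label}.results.tsv", outcome=label
        )
        # Distortion row mirrors the published table layout.
        if presso_result is not None:
            extra = {
                "outcome": label,
                "n_snps": len(hset),
                "method": "mr_presso_distortion",
                "OR_95CI": "NA",
                "p": presso_result.distortion_p,
                "p_het": presso_result.global_p,
            }
            table = pd.concat([table, pd.DataFrame([extra])], ignore_index=True)
            table.to_csv(
                out_dir / f"{label}.results.tsv",
                sep="\t", index=False, float_format="%.17g", na_rep="NA",
            )
        hf = hset.to_frame()
        if strength is not None and len(hf):
            hf["r2"] = strength.r2
        hf.to_csv(out_dir / f"{label}.harmonized.tsv", sep="\t", index=False,
                  float_format="%.17g", na_rep="NA")
        hset.exclusion_frame().to_csv(
            out_dir / f"{label}.exclusions.tsv", sep="\t", index=False
        )
        loo_df = pd.DataFrame(
            {
                "left_out": [vid for vid, _ in loo],
                "beta": [e.beta for _, e in loo],
                "se": [e.se for _, e in loo],
                "p": [e.pval for _, e in loo],
                "OR_95CI": [format_or_ci(e.beta, e.se) for _, e in loo],
            }
        )
        loo_df.to_csv(out_dir / f"{label}.loo.tsv", sep="\t", index=False,
                      float_format="%.17g")
        scatter_data(hset).to_csv(
            out_dir / f"{label}.scatter.tsv", sep="\t", index=False,
            float_format="%.17g",
        )

    return OutcomeResult(
        label=label,
        hset=hset,
        estimates=estimates,
        diagnostics=diagnostics,
        presso_result=presso_result,
        loo=loo,
        results_table=table,
    )
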