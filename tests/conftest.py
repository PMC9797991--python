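"""Shared fixtures: tiny hand-built datasets and harmonized sets."""

from __future__ import annotations

import numpy as np
import pytest

from mrkit.harmonize import HarmonizedInstrument, HarmonizedSet
from mrkit.sumstats_io import SummaryDataset, SummaryStatRecord


def make_record(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-10,
    eaf=0.3,
    n=None,
):
    return SummaryStatRecord(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        eaf=eaf,
        n=n,
    )


def make_dataset(records, label="trait", default_n=10_000):
    return SummaryDataset(trait_label=label, records=records, default_n=default_n)


def make_hset(bx, sx, by, sy, ids=None):
    """HarmonizedSet straight from arrays (bypasses allele bookkeeping)."""
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    ids = ids or [f"rs{i}" for i in range(len(bx))]
    return HarmonizedSet(
        instruments=[
            HarmonizedInstrument(
                variant_id=v,
                beta_exposure=float(a),
                se_exposure=float(b),
                beta_outcome=float(c),
                se_outcome=float(d),
                eaf_exposure=0.3,
            )
            for v, a, b, c, d in zip(ids, bx, sx, by, sy)
        ],
        exclusions=[],
    )


def random_hset(rng, j=10):
    """A random, well-conditioned instrument set."""
    bx = rng.uniform(0.02, 0.2, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.002, 0.01, j)
    by = rng.normal(0.0, 0.05, j)
    sy = rng.uniform(0.005, 0.05, j)
    return make_hset(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def exposure_ds():
    return make_dataset(
        [
            make_record("rs1", "A", "G", beta=0.10, se=0.010, eaf=0.30),
            make_record("rs2", "C", "T", beta=0.20, se=0.015, eaf=0.20),
            make_record("rs3", "G", "A", beta=-0.05, se=0.008, eaf=0.60),
        ],
        label="exposure",
        default_n=288_649,
    )


@pytest.fixture
def outcome_ds():
    return make_dataset(
        [
            make_record("rs1", "A", "G", beta=0.010, se=0.004, eaf=0.31),
            make_record("rs2", "T", "C", beta=-0.022, se=0.005, eaf=0.79),
            make_record("rs3", "G", "A", beta=-0.006, se=0.003, eaf=0.61),
        ],
        label="outcome",
        default_n=472_174,
    )
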