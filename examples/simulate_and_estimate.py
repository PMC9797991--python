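"""Full estimator suite on a synthetic two-sample dataset.

Generates summary statistics with a known causal effect (theta = -0.040
SD outcome per SD exposure, 101 instruments), harmonizes alleles, applies
the weak-instrument screen, and runs all four estimators.
"""

import numpy as np

from mrkit import (
    attach_strength,
    egger,
    filter_weak,
    format_or_ci,
    generate,
    get_preset,
    harmonize,
    ivw,
    weighted_median,
)

scenario = get_preset("ltl-like", seed=7)
exposure, outcome, truth = generate(scenario)
print(f"true causal effect theta = {scenario.theta}")

hset = harmonize(exposure, outcome)
strength = attach_strength(hset, n_exposure=scenario.n_exposure)
hset = filter_weak(hset, threshold=10.0)
print(f"{len(hset)} instruments pass F>=10 "
      f"(F range {min(i.f_stat for i in hset.instruments):.1f}-"
      f"{max(i.f_stat for i in hset.instruments):.1f})")

est_ivw, het = ivw(hset, model="random")
est_egger, pleio = egger(hset)
est_wm = weighted_median(hset, n_boot=1000, seed=7)

print(f"\n{'method':<16}{'beta':>9}{'se':>9}{'p':>11}   OR (95% CI)")
for est in (est_ivw, est_egger, est_wm):
    print(f"{est.method:<16}{est.beta:>9.4f}{est.se:>9.4f}{est.pval:>11.3g}"
          f"   {format_or_ci(est.beta, est.se)}")
print(f"\nCochran Q = {het.q_stat:.1f} on {het.df} df (p_het = {het.p_het:.3g})")
print(f"Egger intercept = {pleio.intercept:.5f} (p_pleio = {pleio.p_pleio:.2f})")
print(
    "\nAll three estimators should bracket theta = -0.040; a p_pleio well\n"
    "above 0.05 means no evidence of directional pleiotropy, as expected\n"
    "for this clean scenario."
)
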