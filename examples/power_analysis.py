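"""Analytic power for two-sample MR designs with continuous outcomes.

Evaluates the chance of detecting a causal effect of a given size (as an
odds ratio per SD of exposure) for two study designs: a biobank-scale
outcome GWAS (n=472,174) and a small proteomics panel (n=3,301), with
instruments explaining ~10-11% of exposure variance.
"""

from mrkit import power_table

for label, n, r2 in [
    ("biobank-scale outcome (LTL-like)", 472_174, 0.1021),
    ("proteomics outcome (INTERVAL-like)", 3_301, 0.1124),
]:
    tbl = power_table(n_outcome=n, r2_exposure=r2, odds_ratios=[0.80, 1.20])
    print(f"\n{label}: n={n:,}, R^2={r2:.2%}")
    print(tbl.to_string(index=False, formatters={"beta": "{:+.4f}".format,
                                                 "power": "{:.4f}".format}))

print(
    "\npower_pct is the probability (in %) of a p<0.05 result if the true\n"
    "effect equals ln(OR) per SD of exposure; the large design detects a\n"
    "20% effect essentially always, the small one 94-99% of the time."
)
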