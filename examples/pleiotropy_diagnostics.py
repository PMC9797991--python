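"""Directional pleiotropy: how the diagnostics and robust estimators react.

Every instrument carries a positive direct effect on the outcome
(mu_alpha = 0.002), violating the exclusion-restriction assumption that
plain IVW relies on. Egger's intercept estimates that average direct
effect; its slope, and to a lesser degree the weighted median, resist the
resulting bias.
"""

from mrkit import egger, generate, get_preset, harmonize, ivw, weighted_median

scenario = get_preset("directional-pleiotropy", seed=3)
exposure, outcome, _ = generate(scenario)
hset = harmonize(exposure, outcome)

est_ivw, het = ivw(hset, model="random")
est_egger, pleio = egger(hset)
est_wm = weighted_median(hset, n_boot=1000, seed=3)

print(f"true theta = {scenario.theta}, true mean direct effect = "
      f"{scenario.pleiotropy_mean}")
print(f"\nIVW beta             = {est_ivw.beta:+.4f} (biased upward)")
print(f"weighted median beta = {est_wm.beta:+.4f}")
print(f"Egger slope          = {est_egger.beta:+.4f}")
print(f"Egger intercept      = {pleio.intercept:+.5f} "
      f"(p_pleio = {pleio.p_pleio:.2g})")
print(f"Cochran Q/df         = {het.q_stat / het.df:.2f} "
      f"(p_het = {het.p_het:.2g})")
print(
    "\nThe intercept should sit near the true mean direct effect with a\n"
    "small p_pleio, flagging the violation; inflated Q/df tells the same\n"
    "story. The Egger slope stays closest to theta."
)
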