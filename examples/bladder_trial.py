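"""Eight views of one trial: the VA bladder-tumor chemoprophylaxis study.

Loads the bundled recurrence data (85 patients, thiotepa vs placebo,
followed up to 64 months) and estimates the treatment effect with every
model in the package.  The unstratified rate-style models (AG, LWYY,
Poisson, NB) read the effect off all events pooled; the PWP models give
each recurrence its own baseline hazard; the weighted PWP additionally
re-balances each risk set on the baseline covariates (initial tumor
count and largest tumor size) before fitting.
"""

import repwp
from repwp.counts import aggregate_counts, fit_negbin, fit_poisson

h = repwp.load_bladder_fixture()
st = h.subject_table()
print(f"{h.n_subjects} patients "
      f"({int((st.treatment == 1).sum())} thiotepa / "
      f"{int((st.treatment == 0).sum())} placebo), {h.n_events} recurrences")

counts = aggregate_counts(h)
fits = [
    repwp.fit_cox_first_event(h),
    repwp.fit_ag(h),
    repwp.fit_lwyy(h),
    fit_poisson(counts),
    fit_negbin(counts),
    repwp.fit_pwp_gt(h),
    repwp.fit_pwp_robust(h),
    repwp.fit_weighted_pwp(h),
]
print(f"{'model':20s} {'HR':>7s}   95% CI")
for fr in fits:
    lo, hi = fr.ci95
    print(f"{fr.model_label:20s} {fr.hr:7.4f}   ({lo:.4f}, {hi:.4f})")

# An HR below 1 favors thiotepa.  The pooled-rate models (~0.67) overstate
# the effect because later recurrences recur faster regardless of arm; the
# plain PWP (~0.89) understates it because its later risk sets condition
# on having recurred; the weighted PWP (~0.84) sits between, with each
# risk set re-balanced to look like a randomized sample.
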