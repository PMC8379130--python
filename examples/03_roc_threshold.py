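"""ROC analysis of DPAR as a predictor of early complete response.

Computes the empirical ROC curve and AUC with DeLong CI, then selects a
dichotomization threshold by three criteria (Youden's J, harmonic mean of
sensitivity and specificity, distance to the upper-left corner).  On the
calibrated synthetic cohort all three land near the published 120 cut.
"""

import numpy as np

from hccwashout import CohortSpec, generate_cohort, roc_auc, select_threshold
from hccwashout import io as hio
from hccwashout.synthetic import dpar_sampler

cohort = hio.add_indices(generate_cohort(CohortSpec()))
scores = cohort["dpar"].to_numpy()
labels = (cohort["response"] == "CR").to_numpy()

roc = roc_auc(scores, labels)
print(f"AUC = {roc['auc']:.2f} (95% CI {roc['ci_low']:.2f}-{roc['ci_high']:.2f})")

sel = select_threshold(scores, labels)
for crit in ("by_youden", "by_harmonic_mean", "by_corner_distance"):
    r = sel[crit]
    print(f"{crit:>20}: threshold {r['threshold']:.1f} "
          f"(sens {r['sensitivity']:.2f}, spec {r['specificity']:.2f})")
print(f"consensus threshold: {sel['consensus']['threshold']:.1f}")
# An AUC around 0.7 from the quartile-calibrated generator is expected:
# printed quartiles pin the central distribution but not the tails, so the
# synthetic discrimination sits below the patient-data 0.80 by design.
u = (np.arange(20_000) + 0.5) / 20_000
# P(DPAR+ > DPAR-) = E[F-(Q+(u))] over uniform u
concordance = np.mean(dpar_sampler("CR-").cdf(dpar_sampler("CR+").ppf(u)))
print(f"(population concordance of the generator itself: {concordance:.3f})")
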