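"""Parameter-recovery calibration of the whole pipeline.

Simulates replicate cohorts whose disease model carries a KNOWN
dichotomized-score odds ratio, re-estimates it with the reporting
pipeline's adjusted logistic model, and compares the replicate mean to
the truth. A mean near the truth with ~95% CI coverage says the
generator and the estimator agree about the model.
"""

import math

from grsmr.pipeline import dichotomized_recovery

TRUTH = 1.44
reps = dichotomized_recovery(true_or=TRUTH, n_replicates=50, seed=1)

mean_log = reps["estimate"].mean()
z = 1.959964
covered = (
    (reps["estimate"] - z * reps["se"] <= math.log(TRUTH))
    & (math.log(TRUTH) <= reps["estimate"] + z * reps["se"])
).mean()

print(f"replicates          : {len(reps)} cohorts of 821 cases / 851 controls")
print(f"true odds ratio     : {TRUTH}")
print(f"mean estimated OR   : {math.exp(mean_log):.3f}")
print(f"95% CI coverage     : {covered:.0%}")
# Coverage near 95% and a mean close to 1.44 confirm the adjusted
# logistic estimate is unbiased for the simulated dichotomized effect.
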