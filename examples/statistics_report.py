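"""The statistical battery used for cohort comparisons and model tests.

First: checks computable from a published study's printed counts
(chi-square across cross-validation cohorts, the exact binomial CI of a
pooled accuracy).  Second: paired model comparisons on simulated
predictions (DeLong for correlated AUCs, McNemar for paired
accuracies, Wilcoxon for paired per-case scores).
"""

import numpy as np

from npcstage.stats import (
    chi_square_test,
    clopper_pearson,
    delong_test,
    mcnemar_test,
    wilcoxon_signed_rank,
)

print("-- cohort comparability from printed counts --")
sex = chi_square_test([[77, 28], [73, 32]])
print(f"sex, cohort1 vs cohort2:      chi2={sex.statistic:.3f}, p={sex.p_value:.3f}")
tstage = chi_square_test([[8, 47, 28, 22], [10, 46, 31, 23]])
print(f"T-stage, cohort1 vs cohort3:  chi2={tstage.statistic:.3f}, p={tstage.p_value:.3f}")
ci = clopper_pearson(225, 320)
print(f"staging accuracy 225/320 = {ci.proportion:.2f} "
      f"(95% CI {ci.lower:.2f}, {ci.upper:.2f})")

print("\n-- paired model comparisons on simulated predictions --")
rng = np.random.default_rng(2)
n = 200
y = (rng.random(n) < 0.4).astype(int)
scores_a = y + rng.normal(0, 0.9, n)          # the better model
scores_b = y + rng.normal(0, 1.6, n)          # a weaker model, same cases
dl = delong_test(scores_a, scores_b, y)
print(f"DeLong AUC difference:  z={dl.statistic:+.2f}, p={dl.p_value:.4f}")
correct_a = scores_a > 0.5
correct_b = scores_b > 0.5
mc = mcnemar_test(correct_a == y.astype(bool), correct_b == y.astype(bool))
print(f"McNemar accuracy diff:  p={mc.p_value:.4f}")
wx = wilcoxon_signed_rank(np.abs(scores_a - y), np.abs(scores_b - y))
print(f"Wilcoxon per-case error: W={wx.statistic:.0f}, p={wx.p_value:.4f}")
# Interpretation: the cohort chi-squares are non-significant (cohorts are
# exchangeable); the paired tests detect that model A ranks and classifies
# better than model B on the same cases.
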