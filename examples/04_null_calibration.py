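"""Check the examination-level Wald test keeps its nominal size under the null.

Simulates cohorts with zero lesion and precursor contrast — the positive and
negative cohorts are then statistically identical — scores every exam with a
fixed network, fits the scanner-adjusted logistic model, and reports how often
the score coefficient is (spuriously) significant at alpha = 0.05. The rate
should sit near 0.05; 50 cohorts keep this demo quick (the acceptance script
uses 400).
"""

from diffanomaly import null_calibration

result = null_calibration(n_cohorts=50, seed=1)
lo, hi = result.binomial_interval(0.99)

print(f"cohorts simulated:            {result.n_cohorts} "
      f"({result.n_exams_per_cohort} exams each)")
print(f"Wald rejections at alpha=.05: {result.rejections} "
      f"(rate {result.rejection_rate:.3f})")
print(f"99% binomial band around .05: ({lo:.3f}, {hi:.3f})")
print(f"non-convergent fits:          {result.n_nonconverged}")
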