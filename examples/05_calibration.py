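"""Statistical calibration of the burden test by replicate simulation.

Two replicate studies at the carrier-count level: (1) family-wise type-I
error under the null (case rate equals control rate) with per-disease
Bonferroni correction; (2) detection rate and excess recovery for a planted
8.2% enrichment in a 720-case group.
"""

from cardiosplice.models import Disease
from cardiosplice.simulate import replicate_enrichment, replicate_null_rates

null_rate = replicate_null_rates(
    disease=Disease.HCM, n_cases=720, control_rate=0.0035, control_n=1e5,
    n_replicates=2000, seed=1, alpha=0.05,
)
print(f"family-wise null rejection rate over 2000 cohorts: {null_rate:.4f} "
      "(should be at most 0.05; Fisher is conservative)")

sig_rate, mean_excess = replicate_enrichment(
    n_cases=720, case_rate=0.082, control_rate=1e-4, control_n=1e5,
    n_replicates=200, seed=2, alpha=0.05, m_tests=8,
)
print(f"planted 8.2% enrichment: detected in {100 * sig_rate:.0f}% of 200 "
      f"replicates; mean estimated excess {100 * mean_excess:.2f}%")
print("\nA detection rate near 100% with an unbiased excess estimate shows "
      "the test is well powered at this effect size and sample size.")
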