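"""Per-variant association under three inheritance modes.

Runs the covariate-adjusted logistic scan (additive / dominant / recessive
coding of each variant's minor-allele dosage) on a synthetic null cohort
and prints the published-style table: best mode, odds ratio, 95% CI and
Wald p per variant, plus the Bonferroni threshold for 11 tests.
"""

from sipiscan import (bonferroni_threshold, make_stratum_cohort,
                      snp_association, snp_table)

cohort = make_stratum_cohort("EA", seed=404)
results = [snp_association(cohort, vid) for vid in cohort.variant_ids]

print(snp_table(cohort, results).to_string(index=False))
threshold = bonferroni_threshold(len(results))
print(f"\nBonferroni criterion for {len(results)} variants: "
      f"p < {threshold:.4f}")
n_sig = sum(r.best_p < threshold for r in results if r.best_mode)
print(f"variants passing it: {n_sig}")
print("\nThe outcome was generated independently of every genotype, so "
      "odds ratios hover around 1 and (typically) nothing clears the "
      "multiplicity-corrected threshold.")
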