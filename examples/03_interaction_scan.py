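"""Detect an injected SNP-SNP interaction with the 45-pattern scan.

Plants a protective interaction-only effect (OR = 0.59) under the
DR_int_or pattern — dominant coding of rs1801133, reverse-recessive coding
of rs2236225, product term only — then scans all 45 candidate models for
that pair and reports the BIC-selected one.
"""

import numpy as np

from sipiscan import EffectSpec, make_stratum_cohort, scan_pair

effect = EffectSpec(pattern="DR_int_or", variant_1="rs1801133",
                    variant_2="rs2236225",
                    beta_interaction=float(np.log(0.59)))
cohort = make_stratum_cohort("EA", effect=effect, seed=13, n=20_000)
res = scan_pair(cohort, "rs1801133", "rs2236225")

print(f"pair: {res.pair_id}  (complete cases: {res.n_used})")
print(f"selected pattern: {res.selected_pattern.label}  "
      f"(BIC = {res.bic_selected:.1f})")
lo, hi = res.ci_95
print(f"interaction OR = {res.interaction_or:.2f} "
      f"({lo:.2f}, {hi:.2f}), p = {res.p_pair:.2g}")
n_fit = sum(isinstance(v, float) for v in res.all_pattern_bics.values())
print(f"patterns fitted: {n_fit}/45")
print("\nAt this sample size the scan recovers the generating model (or an "
      "aliased coding inducing the same genotype grouping) and an odds "
      "ratio near the injected 0.59.")
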