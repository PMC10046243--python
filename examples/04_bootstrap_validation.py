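"""Bootstrap internal validation of a candidate interaction pair.

Resamples individuals with replacement, refits the selected pattern in
every replicate, and counts how often the pair passes the 3pRule
(interaction p < 0.01 and smaller than both component variants' best
single-SNP p-values).  A pair is retained when its original p < 0.05 and
its bootstrap significance percentage exceeds 65%.
"""

import numpy as np

from sipiscan import (EffectSpec, bootstrap_significance, make_stratum_cohort,
                      scan_pair)

effect = EffectSpec(pattern="DR_int_or", variant_1="rs1801133",
                    variant_2="rs2236225",
                    beta_interaction=float(np.log(0.4)))
cohort = make_stratum_cohort("EA", effect=effect, seed=17)
res = scan_pair(cohort, "rs1801133", "rs2236225")
val = bootstrap_significance(cohort, "rs1801133", "rs2236225",
                             res.selected_pattern, B=500, seed=19,
                             p_pair=res.p_pair)

print(f"pair {res.pair_id}: pattern {res.selected_pattern.label}, "
      f"OR = {res.interaction_or:.2f}, p = {res.p_pair:.3f}")
print(f"bootstrap: {val.significant_replicates}/{val.B} replicates pass "
      f"the 3pRule -> significance = {val.significance_pct:.1f}%")
print(f"selected (p < 0.05 and > 65%): {val.selected}")
print("\nThe percentage measures how stably the interaction outperforms "
      "its component SNPs under resampling; a strong planted effect at "
      "n=690 usually clears the 65% bar, a null pair almost never does.")
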