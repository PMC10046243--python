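"""Bootstrap internal validation of interaction pairs (the "3pRule").

For each candidate pair, individuals are resampled with replacement B
times (default 500).  In every replicate the pair's previously selected
pattern is refit as a FIXED hypothesis — re-running model selection inside
the bootstrap would conflate model instability with significance — and
each component variant's best-of-three-modes p-value is recomputed.  A
replicate counts as significant when the pair passes the 3pRule:
p_pair < 0.01 and p_pair below each (default) or either (configurable)
component SNP's individual p-value.  A pair is finally selected when its
original-data p_pair < 0.05 and its bootstrap significance percentage
exceeds 65%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .cohort import Cohort, DataError
from .single_snp import (MODES, DegenerateOutcomeError, DegeneratePredictorError,
                         code_single, fit_logistic, snp_design)
from .sipi import PairResult, PatternSpec, build_design

log = logging.getLogger(__name__)

__all__ = [
    "ThreePRuleConfig",
    "ValidationResult",
    "three_p_rule",
    "bootstrap_significance",
    "select_significant_pairs",
]


@dataclass(frozen=True)
class ThreePRuleConfig:
    """Thresholds for per-replicate and final significance decisions."""

    p_bound: float = 0.01
    comparison_rule: str = "both"   # "both" or "any"
    alpha_final: float = 0.05
    pct_threshold: float = 65.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_bound < self.alpha_final:
            raise ValueError("need 0 < p_bound < alpha_final")
        if self.comparison_rule not in ("both", "any"):
            raise ValueError("comparison_rule must be 'both' or 'any'")


DEFAULT_RULE = ThreePRuleConfig()


def three_p_rule(p_pair: float, p_snp1: float, p_snp2: float,
                 config: ThreePRuleConfig = DEFAULT_RULE) -> bool:
    """Does the pair's p-value beat the bound and its component SNPs'?

    'both' (default): p_pair < p_bound and p_pair < p_snp1 and p_pair < p_snp2.
    'any': p_pair < p_bound and p_pair below at least one of the two.
    """
    for p in (p_pair, p_snp1, p_snp2):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    if p_pair >= config.p_bound:
        return False
    if config.comparison_rule == "both":
        return p_pair < p_snp1 and p_pair < p_snp2
    return p_pair < p_snp1 or p_pair < p_snp2


@dataclass
class ValidationResult:
    """Bootstrap outcome for one pair."""

    pair_id: str
    B: int
    significant_replicates: int
    degenerate_replicates: int = 0
    p_pair: float = float("nan")
    selected: bool | None = None

    @property
    def significance_pct(self) -> float:
        return 100.0 * self.significant_replicates / self.B


def _pair_p_value(y, g1, g2, cov, pattern: PatternSpec) -> float | None:
    X, names, pidx = build_design(pattern, g1, g2, cov)
    if np.ptp(X[:, pidx]) == 0:
        return None
    try:
        fit = fit_logistic(y, X, names)
    except (DegenerateOutcomeError, DegeneratePredictorError):
        return None
    return fit.p("snp1:snp2") if fit.converged else None


def _best_mode_p(y, g, cov) -> float | None:
    best = None
    for mode in MODES:
        x = code_single(g, mode)
        if np.ptp(x) == 0:
            continue
        X, names = snp_design(x, cov)
        try:
            fit = fit_logistic(y, X, names)
        except (DegenerateOutcomeError, DegeneratePredictorError):
            continue
        if fit.converged:
            p = fit.p("snp")
            best = p if best is None else min(best, p)
    return best


def bootstrap_significance(cohort: Cohort, variant_1: str, variant_2: str,
                           selected_pattern: PatternSpec | str,
                           B: int = 500, seed: int = 0,
                           config: ThreePRuleConfig = DEFAULT_RULE,
                           stratified: bool = False,
                           p_pair: float = float("nan")) -> ValidationResult:
    """Percentage of bootstrap replicates in which a pair passes the 3pRule.

    The selected pattern is refit unchanged in every replicate; each
    variant's individual p-value is the per-replicate best of the three
    inheritance modes.  Replicates that are degenerate (single-class
    outcome, constant codings, separation) count as non-significant and
    are tallied.  ``stratified=True`` resamples within outcome classes,
    preserving the case/control split.
    """
    if B < 1:
        raise ValueError("replicate count B must be >= 1")
    if isinstance(selected_pattern, str):
        selected_pattern = PatternSpec.from_label(selected_pattern)

    g1_all, g2_all = cohort.dosage(variant_1), cohort.dosage(variant_2)
    cov_all, y_all = cohort.covariates(), cohort.phenotype
    mask = (np.isfinite(y_all) & np.isfinite(g1_all) & np.isfinite(g2_all)
            & np.all(np.isfinite(cov_all), axis=1))
    g1_all, g2_all = g1_all[mask], g2_all[mask]
    cov_all, y_all = cov_all[mask], y_all[mask]
    n = int(y_all.size)
    if n == 0:
        raise DataError("no complete cases for this pair")

    rng = np.random.default_rng(seed)
    if stratified:
        cases = np.flatnonzero(y_all == 1)
        ctrls = np.flatnonzero(y_all == 0)

    n_sig = n_degen = 0
    for _ in range(B):
        if stratified:
            idx = np.concatenate([rng.choice(cases, size=cases.size, replace=True),
                                  rng.choice(ctrls, size=ctrls.size, replace=True)])
        else:
            idx = rng.integers(0, n, size=n)
        y, g1, g2, cov = y_all[idx], g1_all[idx], g2_all[idx], cov_all[idx]
        if np.ptp(y) == 0:
            n_degen += 1
            continue
        pp = _pair_p_value(y, g1, g2, cov, selected_pattern)
        p1 = _best_mode_p(y, g1, cov)
        p2 = _best_mode_p(y, g2, cov)
        if pp is None or p1 is None or p2 is None:
            n_degen += 1
            continue
        if three_p_rule(pp, p1, p2, config):
            n_sig += 1
    if n_degen:
        log.info("%s_%s: %d/%d degenerate bootstrap replicates counted "
                 "non-significant", variant_1, variant_2, n_degen, B)

    result = ValidationResult(pair_id=f"{variant_1}_{variant_2}", B=B,
                              significant_replicates=n_sig,
                              degenerate_replicates=n_degen, p_pair=p_pair)
    if np.isfinite(p_pair):
        result.selected = (p_pair < config.alpha_final
                           and result.significance_pct > config.pct_threshold)
    return result


def select_significant_pairs(pairs: list[PairResult],
                             validations: list[ValidationResult],
                             config: ThreePRuleConfig = DEFAULT_RULE) -> pd.DataFrame:
    """Final selection: p_pair < alpha AND significance% > threshold.

    Returns a table (one row per selected pair, sorted by p_pair) joining
    the scan estimates with the bootstrap significance percentages.
    """
    by_id = {v.pair_id: v for v in validations}
    rows = []
    for pr in pairs:
        val = by_id.get(pr.pair_id)
        if val is None or not np.isfinite(pr.p_pair):
            continue
        if pr.p_pair < config.alpha_final and val.significance_pct > config.pct_threshold:
            rows.append({
                "pair": pr.pair_id,
                "pattern": pr.selected_pattern.label if pr.selected_pattern else "",
                "interaction_or": pr.interaction_or,
                "ci_low": pr.ci_95[0], "ci_high": pr.ci_95[1],
                "p_pair": pr.p_pair,
                "significance_pct": val.significance_pct,
            })
    df = pd.DataFrame(rows, columns=["pair", "pattern", "interaction_or",
                                     "ci_low", "ci_high", "p_pair",
                                     "significance_pct"])
    return df.sort_values("p_pair", kind="mergesort").reset_index(drop=True)
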