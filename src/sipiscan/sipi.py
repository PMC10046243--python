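"""The 45-pattern pairwise interaction engine.

For a pair of variants the engine enumerates 45 candidate logistic models
built from three ingredients:

* inheritance-mode combination of the two variants — AA, DD, DR, RD, RR
  (first letter = variant 1; A = additive, D = dominant, R = recessive);
* model structure — ``Full`` (both main effects + product), ``M1_int`` /
  ``M2_int`` (one main effect + product), ``int_only`` (product only);
* risk direction per variant — ``o`` (original: coded on the minor allele)
  or ``r`` (reverse: coded on the major allele, i.e. the complement coding).

``Full`` appears once per mode combination because reversing a direction
inside a full model is an affine reparametrisation with identical fit;
``M1_int``/``M2_int`` vary only the direction of the variant whose main
effect is kept; ``int_only`` varies both — 1 + 2 + 2 + 4 = 9 models per
combination, 45 in total.  The model with the lowest BIC is selected, and
the pair's effect is the product-term odds ratio of that model.  Every
model is adjusted for the cohort covariates (age, site, ancestry).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, DataError
from .single_snp import (DegenerateOutcomeError, DegeneratePredictorError,
                         FitResult, fit_logistic)

log = logging.getLogger(__name__)

__all__ = [
    "MODE_COMBOS",
    "PatternSpec",
    "PairResult",
    "encode",
    "enumerate_patterns",
    "build_design",
    "bic",
    "scan_pair",
    "scan_all_pairs",
    "all_pairs",
]

MODE_COMBOS = ("AA", "DD", "DR", "RD", "RR")
_MODE_NAME = {"A": "additive", "D": "dominant", "R": "recessive"}
STRUCTURES = ("Full", "M1_int", "M2_int", "int_only")


def encode(g, mode: str, direction: str = "o"):
    """Code a dosage vector under a one-letter mode and a risk direction.

    Original ('o') codings count the minor allele: additive g, dominant
    carrier indicator, recessive homozygote indicator.  Reverse ('r') is
    the major-allele orientation: 2 - g for additive, the complement
    indicator for dominant/recessive.
    """
    g = np.asarray(g, dtype=float)
    if mode not in _MODE_NAME:
        raise ValueError(f"mode must be one of A/D/R, got {mode!r}")
    if direction not in ("o", "r"):
        raise ValueError(f"direction must be 'o' or 'r', got {direction!r}")
    if mode == "A":
        base = g
        return 2.0 - base if direction == "r" else base
    if mode == "D":
        base = np.where(np.isfinite(g), (g >= 1).astype(float), np.nan)
    else:
        base = np.where(np.isfinite(g), (g == 2).astype(float), np.nan)
    return 1.0 - base if direction == "r" else base


@dataclass(frozen=True)
class PatternSpec:
    """One candidate interaction model (mode combo, structure, directions)."""

    mode1: str
    mode2: str
    structure: str
    direction1: str = "o"
    direction2: str = "o"

    def __post_init__(self):
        if self.mode1 not in _MODE_NAME or self.mode2 not in _MODE_NAME:
            raise ValueError("modes must be A, D or R")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "Full" and (self.direction1, self.direction2) != ("o", "o"):
            raise ValueError("Full patterns use original directions only")
        if self.structure == "M1_int" and self.direction2 != "o":
            raise ValueError("M1_int varies direction 1 only")
        if self.structure == "M2_int" and self.direction1 != "o":
            raise ValueError("M2_int varies direction 2 only")

    @property
    def combo(self) -> str:
        return self.mode1 + self.mode2

    @property
    def label(self) -> str:
        if self.structure == "Full":
            return f"{self.combo}_Full"
        if self.structure == "M1_int":
            return f"{self.combo}_M1_int_{self.direction1}1"
        if self.structure == "M2_int":
            return f"{self.combo}_M2_int_{self.direction2}2"
        return f"{self.combo}_int_{self.direction1}{self.direction2}"

    @classmethod
    def from_label(cls, label: str) -> "PatternSpec":
        combo, rest = label.split("_", 1)
        m1, m2 = combo[0], combo[1]
        if rest == "Full":
            return cls(m1, m2, "Full")
        if rest.startswith("M1_int_"):
            return cls(m1, m2, "M1_int", direction1=rest[-2])
        if rest.startswith("M2_int_"):
            return cls(m1, m2, "M2_int", direction2=rest[-2])
        if rest.startswith("int_"):
            dd = rest.split("_")[1]
            return cls(m1, m2, "int_only", direction1=dd[0], direction2=dd[1])
        raise ValueError(f"unparseable pattern label {label!r}")

    @property
    def n_genetic_terms(self) -> int:
        return {"Full": 3, "M1_int": 2, "M2_int": 2, "int_only": 1}[self.structure]


def enumerate_patterns() -> list[PatternSpec]:
    """The canonical catalogue: 9 patterns per mode combination, 45 total.

    Order within a combo: Full, M1_int_o1, M1_int_r1, M2_int_o2, M2_int_r2,
    int_oo, int_or, int_ro, int_rr.
    """
    out: list[PatternSpec] = []
    for combo in MODE_COMBOS:
        m1, m2 = combo[0], combo[1]
        out.append(PatternSpec(m1, m2, "Full"))
        for d in ("o", "r"):
            out.append(PatternSpec(m1, m2, "M1_int", direction1=d))
        for d in ("o", "r"):
            out.append(PatternSpec(m1, m2, "M2_int", direction2=d))
        for d1, d2 in itertools.product("or", "or"):
            out.append(PatternSpec(m1, m2, "int_only", direction1=d1, direction2=d2))
    return out


def build_design(pattern: PatternSpec, g1, g2, covariates=None):
    """Design matrix for one pattern: (X, term_names, product_column_index).

    The direction reversal is applied to the variant's coding once, so it
    affects both its main-effect column (when present) and the product
    column.  Covariates are appended to every structure, including
    interaction-only models.
    """
    x1 = encode(g1, pattern.mode1, pattern.direction1)
    x2 = encode(g2, pattern.mode2, pattern.direction2)
    prod = x1 * x2
    cols = [np.ones_like(prod)]
    names = ["intercept"]
    if pattern.structure in ("Full", "M1_int"):
        cols.append(x1)
        names.append("snp1")
    if pattern.structure in ("Full", "M2_int"):
        cols.append(x2)
        names.append("snp2")
    cols.append(prod)
    names.append("snp1:snp2")
    if covariates is not None:
        cols.append(np.asarray(covariates, dtype=float))
        names += list(Cohort.covariate_names)
    X = np.column_stack(cols)
    return X, tuple(names), names.index("snp1:snp2")


def bic(fit: FitResult) -> float:
    """Bayesian information criterion: -2*logL + k*ln(n)."""
    return -2.0 * fit.llf + fit.k * math.log(fit.n_used)


@dataclass
class PairResult:
    """The BIC-selected interaction model for one variant pair."""

    variant_1: str
    variant_2: str
    selected_pattern: PatternSpec | None
    interaction_or: float = float("nan")
    ci_95: tuple[float, float] = (float("nan"), float("nan"))
    p_pair: float = float("nan")
    bic_selected: float = float("nan")
    all_pattern_bics: dict = field(default_factory=dict)  # label -> BIC | reason
    n_used: int = 0
    fit: FitResult | None = None

    @property
    def pair_id(self) -> str:
        return f"{self.variant_1}_{self.variant_2}"


_BIC_TIE_TOL = 1e-9


def scan_pair(cohort: Cohort, variant_1: str, variant_2: str,
              patterns: list[PatternSpec] | None = None) -> PairResult:
    """Fit the pattern catalogue for one pair and select the min-BIC model.

    Unfittable patterns (constant product column, collinear design,
    separation, degenerate outcome) are skipped with a recorded reason.
    BIC ties (within 1e-9) break toward fewer parameters, then catalogue
    order.  If nothing fits, a pair-level failure record is returned.
    """
    patterns = patterns if patterns is not None else enumerate_patterns()
    g1, g2 = cohort.dosage(variant_1), cohort.dosage(variant_2)
    cov, y = cohort.covariates(), cohort.phenotype
    mask = (np.isfinite(y) & np.isfinite(g1) & np.isfinite(g2)
            & np.all(np.isfinite(cov), axis=1))
    g1, g2, cov, y = g1[mask], g2[mask], cov[mask], y[mask]
    for vid, g in ((variant_1, g1), (variant_2, g2)):
        if g.size == 0 or np.ptp(g) == 0:
            raise DataError(f"variant {vid!r} is not polymorphic in the complete cases")

    result = PairResult(variant_1=variant_1, variant_2=variant_2,
                        selected_pattern=None, n_used=int(y.size))
    fitted = []  # (bic, n_params, catalogue_index, pattern, fit, prod_term)
    for idx, pat in enumerate(patterns):
        X, names, pidx = build_design(pat, g1, g2, cov)
        if np.ptp(X[:, pidx]) == 0:
            result.all_pattern_bics[pat.label] = "constant interaction term"
            continue
        try:
            fit = fit_logistic(y, X, names)
        except (DegeneratePredictorError, DegenerateOutcomeError) as exc:
            result.all_pattern_bics[pat.label] = str(exc)
            continue
        if not fit.converged:
            result.all_pattern_bics[pat.label] = "non-converged / separation"
            continue
        b = bic(fit)
        result.all_pattern_bics[pat.label] = b
        fitted.append((b, fit.k, idx, pat, fit))

    if not fitted:
        log.warning("%s-%s: all %d patterns unfittable",
                    variant_1, variant_2, len(patterns))
        return result

    best_bic = min(entry[0] for entry in fitted)
    candidates = [e for e in fitted if e[0] <= best_bic + _BIC_TIE_TOL]
    _, _, _, pat, fit = min(candidates, key=lambda e: (e[1], e[2]))
    or_, lo, hi = fit.or_ci("snp1:snp2")
    result.selected_pattern = pat
    result.interaction_or = or_
    result.ci_95 = (lo, hi)
    result.p_pair = fit.p("snp1:snp2")
    result.bic_selected = bic(fit)
    result.fit = fit
    return result


def all_pairs(variant_ids: list[str]) -> list[tuple[str, str]]:
    """All C(k, 2) unordered variant pairs, in catalogue order."""
    return list(itertools.combinations(variant_ids, 2))


def scan_all_pairs(cohort: Cohort,
                   variant_ids: list[str] | None = None) -> list[PairResult]:
    """Scan every unordered pair; rows sorted by the pair p-value ascending."""
    ids = variant_ids if variant_ids is not None else cohort.variant_ids
    if len(ids) < 2:
        raise ValueError("need at least two variants to scan pairs")
    results = [scan_pair(cohort, v1, v2) for v1, v2 in all_pairs(ids)]
    return sorted(results, key=lambda r: (math.isnan(r.p_pair), r.p_pair))
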