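"""Single-variant association under three inheritance modes.

Each polymorphism is tested with a covariate-adjusted logistic regression
under additive (0/1/2), dominant (minor-allele carrier) and recessive
(minor-homozygote) codings of the minor-allele dosage.  The best mode is
the one with the smallest Wald p-value of the genotype term; modes whose
coding is constant in the analysed samples (e.g. recessive with no minor
homozygotes) are excluded and recorded.  Multiplicity is handled with a
Bonferroni threshold over the number of variants tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import Cohort, DataError

log = logging.getLogger(__name__)

__all__ = [
    "MODES",
    "FitResult",
    "SnpResult",
    "DegenerateOutcomeError",
    "DegeneratePredictorError",
    "code_single",
    "fit_logistic",
    "snp_association",
    "bonferroni_threshold",
]

MODES = ("additive", "dominant", "recessive")

# |beta| beyond this is taken as quasi-separation rather than a real MLE
_PARAM_BOUND = 30.0


class DegenerateOutcomeError(DataError):
    """The outcome has a single class; no logistic model is identifiable."""


class DegeneratePredictorError(DataError):
    """A non-intercept column is constant or the design is rank-deficient."""


def code_single(g, mode: str):
    """Code minor-allele dosage under one inheritance mode.

    additive -> g; dominant -> 1[g >= 1]; recessive -> 1[g == 2].
    Missing (nan) propagates.
    """
    g = np.asarray(g, dtype=float)
    if mode == "additive":
        return g
    if mode == "dominant":
        return np.where(np.isfinite(g), (g >= 1).astype(float), np.nan)
    if mode == "recessive":
        return np.where(np.isfinite(g), (g == 2).astype(float), np.nan)
    raise ValueError(f"unknown inheritance mode {mode!r}")


@dataclass
class FitResult:
    """A fitted logistic model: per-term estimates plus fit diagnostics."""

    terms: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    llf: float
    n_used: int
    k: int
    converged: bool

    def _idx(self, term: str) -> int:
        return self.terms.index(term)

    def coef(self, term: str) -> float:
        return float(self.params[self._idx(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self._idx(term)])

    def p(self, term: str) -> float:
        return float(self.pvalues[self._idx(term)])

    def or_ci(self, term: str, z: float = 1.96) -> tuple[float, float, float]:
        """(odds ratio, CI low, CI high) = exp(beta), exp(beta -/+ z*SE)."""
        b, s = self.coef(term), self.se(term)
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s))


def _failed_fit(terms: tuple[str, ...], n: int) -> FitResult:
    k = len(terms)
    nan = np.full(k, np.nan)
    return FitResult(terms=terms, params=nan.copy(), bse=nan.copy(),
                     pvalues=nan.copy(), llf=float("nan"), n_used=n, k=k,
                     converged=False)


def fit_logistic(y, X, term_names: tuple[str, ...] | None = None) -> FitResult:
    """Maximum-likelihood logistic fit with Wald inference.

    The design must already be complete-case (rows with nan are dropped
    defensively) and include an intercept column named ``"intercept"`` if
    one is wanted.  Separation / non-convergence is flagged on the result
    instead of returning spurious estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("y and design shapes are inconsistent")
    terms = tuple(term_names) if term_names is not None else tuple(
        f"x{j}" for j in range(X.shape[1]))
    if len(terms) != X.shape[1]:
        raise ValueError("term_names length != number of design columns")

    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[mask], X[mask]
    n = int(y.size)
    if n == 0 or np.all(y == y[0] if n else True):
        raise DegenerateOutcomeError("outcome has a single class (or no data)")
    for j, name in enumerate(terms):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise DegeneratePredictorError(f"predictor {name!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegeneratePredictorError("design matrix is rank-deficient (collinear)")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=200, tol=1e-10,
                                     disp=0, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        log.debug("separation / singular Hessian for terms %s", terms)
        return _failed_fit(terms, n)

    ok = (bool(res.mle_retvals.get("converged", False))
          and np.all(np.isfinite(res.bse))
          and float(np.max(np.abs(res.params))) < _PARAM_BOUND)
    return FitResult(terms=terms, params=np.asarray(res.params, dtype=float),
                     bse=np.asarray(res.bse, dtype=float),
                     pvalues=np.asarray(res.pvalues, dtype=float),
                     llf=float(res.llf), n_used=n, k=X.shape[1], converged=ok)


@dataclass
class SnpResult:
    """Best-of-three-modes association for one variant."""

    variant_id: str
    mode_fits: dict = field(default_factory=dict)      # mode -> FitResult
    excluded_modes: dict = field(default_factory=dict)  # mode -> reason
    best_mode: str | None = None
    best_or: float = float("nan")
    best_ci: tuple[float, float] = (float("nan"), float("nan"))
    best_p: float = float("nan")


def snp_design(g, covariates):
    """[intercept, snp, age, site, ancestry] design for one coded genotype."""
    cols = [np.ones_like(g), g]
    names = ["intercept", "snp"]
    if covariates is not None:
        cols.append(covariates)
        names += list(Cohort.covariate_names)
    return np.column_stack(cols), tuple(names)


def snp_association(cohort: Cohort, variant_id: str,
                    adjust: bool = True) -> SnpResult:
    """Fit all three inheritance modes for one variant and pick the best.

    Best = smallest Wald p of the genotype term among the fittable modes;
    ties break in the fixed order additive > dominant > recessive.  Modes
    with a constant coding, collinearity or a separated fit are excluded
    with a recorded reason; if all three are excluded the result is a
    variant-level failure record (``best_mode is None``).
    """
    g = cohort.dosage(variant_id)
    cov = cohort.covariates() if adjust else None
    y = cohort.phenotype
    mask = np.isfinite(y) & np.isfinite(g)
    if cov is not None:
        mask &= np.all(np.isfinite(cov), axis=1)

    result = SnpResult(variant_id=variant_id)
    for mode in MODES:
        x = code_single(g[mask], mode)
        if np.ptp(x) == 0:
            result.excluded_modes[mode] = "constant genotype coding"
            log.info("%s: %s mode excluded (constant coding)", variant_id, mode)
            continue
        X, names = snp_design(x, cov[mask] if cov is not None else None)
        try:
            fit = fit_logistic(y[mask], X, names)
        except DataError as exc:
            result.excluded_modes[mode] = str(exc)
            continue
        result.mode_fits[mode] = fit
        if not fit.converged:
            result.excluded_modes[mode] = "non-converged / separation"

    usable = [(m, f) for m, f in result.mode_fits.items()
              if f.converged and m not in result.excluded_modes]
    if not usable:
        log.warning("%s: all inheritance modes degenerate", variant_id)
        return result
    best_mode, best_fit = min(
        usable, key=lambda mf: (mf[1].p("snp"), MODES.index(mf[0])))
    or_, lo, hi = best_fit.or_ci("snp")
    result.best_mode = best_mode
    result.best_or, result.best_ci, result.best_p = or_, (lo, hi), best_fit.p("snp")
    return result


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """alpha / m.  Summaries round it to 4 decimals; comparisons must not."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m
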