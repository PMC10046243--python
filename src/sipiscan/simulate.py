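"""Synthetic case-control cohorts with the structure the analysis assumes.

Genotypes are drawn under Hardy-Weinberg equilibrium at stated minor-allele
frequencies; one designated variant pair can be generated in linkage
disequilibrium at a target r² via the implied four-haplotype distribution.
Covariates follow the stratum summary statistics (normal age, Bernoulli
site, truncated-normal ancestry proportion), and the binary outcome comes
from a logistic model whose genetic part is a configurable interaction
pattern; the intercept is calibrated so the marginal prevalence matches the
stratum's case fraction.  Two bundled profiles ("EA": n=690, prevalence
21.4%; "AA": n=604, prevalence 30.6%) reproduce the published strata so the
whole pipeline runs without any restricted data.

All randomness flows through explicit seeds; a base seed deterministically
derives independent substreams per variant and per stage.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats
from scipy.special import expit

from .cohort import Cohort, Variant
from .sipi import PatternSpec, encode

__all__ = [
    "CohortProfile",
    "EffectSpec",
    "load_profile",
    "simulate_genotypes",
    "simulate_ld_pair",
    "simulate_covariates",
    "calibrate_intercept",
    "simulate_outcome",
    "make_stratum_cohort",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class CohortProfile:
    """Generative parameters for one stratum."""

    stratum: str
    n: int
    target_prevalence: float
    variants: list[Variant]
    maf: dict[str, float]
    age_mean: float
    age_sd: float
    site_prob: float
    ancestry_mean: float
    ancestry_sd: float
    ld_spec: tuple[str, str, float] | None = None  # (variant1, variant2, r2)

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target prevalence must lie strictly in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for vid, p in self.maf.items():
            if not 0.0 < p <= 0.5:
                raise ValueError(f"{vid}: MAF {p} outside (0, 0.5]")


@dataclass
class EffectSpec:
    """Log-odds effects for outcome generation under one interaction pattern.

    ``covariate_betas`` is (age, site, ancestry); defaults are zero so a
    profile with no effect spec yields a pure-null cohort.  ``intercept``
    of ``None`` means "calibrate to the profile's target prevalence".
    """

    pattern: PatternSpec
    variant_1: str
    variant_2: str
    beta_interaction: float
    beta_main_1: float = 0.0
    beta_main_2: float = 0.0
    covariate_betas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intercept: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.pattern, str):
            self.pattern = PatternSpec.from_label(self.pattern)
        values = [self.beta_interaction, self.beta_main_1, self.beta_main_2,
                  *self.covariate_betas]
        if self.intercept is not None:
            values.append(self.intercept)
        if not np.all(np.isfinite(values)):
            raise ValueError("effect coefficients must be finite")


def load_profile(stratum: str) -> CohortProfile:
    """Load a bundled stratum profile ("EA" or "AA")."""
    name = stratum.lower()
    resource = importlib.resources.files("sipiscan") / "profiles" / f"{name}.yaml"
    try:
        text = resource.read_text()
    except FileNotFoundError:
        raise KeyError(f"no bundled profile for stratum {stratum!r}") from None
    raw = yaml.safe_load(text)
    variants = [
        Variant(variant_id=v["id"], chromosome=str(v["chromosome"]),
                position=v["position"], gene=v["gene"],
                allele_a=str(v["minor"]), allele_b=str(v["major"]),
                minor_allele=str(v["minor"]), maf=float(v["maf"]))
        for v in raw["variants"]
    ]
    ld = raw.get("ld")
    ld_spec = (ld["pair"][0], ld["pair"][1], float(ld["r2"])) if ld else None
    return CohortProfile(
        stratum=raw["stratum"], n=int(raw["n"]),
        target_prevalence=float(raw["target_prevalence"]),
        variants=variants,
        maf={v.variant_id: v.maf for v in variants},
        age_mean=float(raw["age_mean"]), age_sd=float(raw["age_sd"]),
        site_prob=float(raw["site_prob"]),
        ancestry_mean=float(raw["ancestry_mean"]),
        ancestry_sd=float(raw["ancestry_sd"]),
        ld_spec=ld_spec,
    )


def simulate_genotypes(maf: float, n: int, seed) -> np.ndarray:
    """i.i.d. Hardy-Weinberg dosages: g ~ Binomial(2, maf)."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    return _rng(seed).binomial(2, maf, size=n).astype(float)


def ld_feasible_bound(maf1: float, maf2: float) -> float:
    """Largest attainable r² for two loci with these minor-allele freqs."""
    p1, p2 = maf1, maf2
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    d_max = min(p1 * (1 - p2), (1 - p1) * p2)
    return (d_max / denom) ** 2


def simulate_ld_pair(maf1: float, maf2: float, r2_target: float,
                     n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Two dosage vectors with expected dosage r² equal to ``r2_target``.

    Haplotypes are drawn from the four-haplotype distribution implied by
    (maf1, maf2, D) with D = r*sqrt(p1 q1 p2 q2) > 0 and paired at random
    into genotypes.  Targets beyond the feasibility bound
    |D| <= min(p1(1-p2), p2(1-p1)) are rejected.
    """
    for p in (maf1, maf2):
        if not 0.0 < p <= 0.5:
            raise ValueError(f"MAF {p} outside (0, 0.5]")
    if not 0.0 <= r2_target <= 1.0:
        raise ValueError("r2 target must lie in [0, 1]")
    p1, p2 = maf1, maf2
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    d = math.sqrt(r2_target) * denom
    d_max = min(p1 * (1 - p2), (1 - p1) * p2)
    if d > d_max + 1e-12:
        raise ValueError(
            f"r²={r2_target} infeasible for MAFs ({p1}, {p2}): requires "
            f"D={d:.4f} > bound {d_max:.4f} (max feasible r² = "
            f"{ld_feasible_bound(p1, p2):.4f})")
    # haplotype order: (minor1 minor2), (minor1 major2), (major1 minor2), (major1 major2)
    probs = np.array([p1 * p2 + d, p1 * (1 - p2) - d,
                      (1 - p1) * p2 - d, (1 - p1) * (1 - p2) + d])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    haps = _rng(seed).choice(4, size=(n, 2), p=probs)
    g1 = np.sum(haps <= 1, axis=1).astype(float)      # haplotypes carrying minor1
    g2 = np.sum(haps % 2 == 0, axis=1).astype(float)  # haplotypes carrying minor2
    return g1, g2


def simulate_covariates(profile: CohortProfile, seed):
    """(age, site, ancestry) vectors for one stratum profile."""
    rng = _rng(seed)
    age = rng.normal(profile.age_mean, profile.age_sd, size=profile.n)
    site = rng.binomial(1, profile.site_prob, size=profile.n).astype(float)
    m, s = profile.ancestry_mean, profile.ancestry_sd
    if s == 0:
        ancestry = np.full(profile.n, float(m))
    else:
        a, b = (0.0 - m) / s, (1.0 - m) / s
        ancestry = stats.truncnorm.rvs(a, b, loc=m, scale=s, size=profile.n,
                                       random_state=rng)
    return age, site, ancestry


def calibrate_intercept(linear_predictor_sample, target_prevalence: float,
                        tol: float = 1e-6, max_iter: int = 200) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) = target, by bisection.

    The mean response is strictly increasing in b0, so a solution always
    exists inside a wide bracket; iteration stops when the realised
    prevalence is within ``tol`` of the target.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie strictly in (0, 1)")
    eta = np.asarray(linear_predictor_sample, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictor sample must be finite")

    lo, hi = -50.0, 50.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        gap = float(np.mean(expit(mid + eta))) - target_prevalence
        if abs(gap) < tol:
            return mid
        if gap < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def linear_predictor(cohort: Cohort, effect: EffectSpec) -> np.ndarray:
    """Genetic + covariate linear predictor (no intercept) for a cohort."""
    pat = effect.pattern
    x1 = encode(cohort.dosage(effect.variant_1), pat.mode1, pat.direction1)
    x2 = encode(cohort.dosage(effect.variant_2), pat.mode2, pat.direction2)
    b_age, b_site, b_anc = effect.covariate_betas
    return (effect.beta_main_1 * x1 + effect.beta_main_2 * x2
            + effect.beta_interaction * x1 * x2
            + b_age * cohort.age + b_site * cohort.site
            + b_anc * cohort.ancestry)


def simulate_outcome(cohort: Cohort, effect: EffectSpec | None, seed,
                     target_prevalence: float | None = None) -> np.ndarray:
    """Draw y ~ Bernoulli(expit(b0 + eta)) for a cohort.

    With ``effect=None`` the outcome is independent of genotypes and
    covariates (pure-null generation).  The intercept is taken from the
    effect spec if set, otherwise calibrated to ``target_prevalence``.
    """
    if effect is None:
        eta = np.zeros(cohort.n)
        b0 = None
    else:
        eta = linear_predictor(cohort, effect)
        b0 = effect.intercept
    if b0 is None:
        if target_prevalence is None:
            raise ValueError("need an intercept or a target prevalence")
        b0 = calibrate_intercept(eta, target_prevalence)
    return _rng(seed).binomial(1, expit(b0 + eta)).astype(float)


def make_stratum_cohort(stratum: str | CohortProfile = "EA",
                        effect: EffectSpec | None = None,
                        seed: int = 0, n: int | None = None) -> Cohort:
    """Generate a full synthetic cohort from a stratum profile.

    ``stratum`` is "EA"/"AA" (bundled profiles) or a custom
    :class:`CohortProfile`; ``n`` overrides the profile sample size.
    With ``effect=None`` the cohort is null: the outcome is independent
    of every genotype and covariate but still matches the stratum's
    marginal prevalence in expectation.
    """
    profile = load_profile(stratum) if isinstance(stratum, str) else stratum
    if n is not None:
        profile = replace(profile, n=n)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(profile.variants) + 2)

    geno = np.empty((profile.n, len(profile.variants)), dtype=float)
    ids = [v.variant_id for v in profile.variants]
    ld_done = False
    for j, vid in enumerate(ids):
        if profile.ld_spec and vid in profile.ld_spec[:2]:
            if not ld_done:
                v1, v2, r2 = profile.ld_spec
                g1, g2 = simulate_ld_pair(profile.maf[v1], profile.maf[v2], r2,
                                          profile.n, np.random.default_rng(children[j]))
                geno[:, ids.index(v1)] = g1
                geno[:, ids.index(v2)] = g2
                ld_done = True
            continue
        geno[:, j] = simulate_genotypes(profile.maf[vid], profile.n,
                                        np.random.default_rng(children[j]))

    age, site, ancestry = simulate_covariates(
        profile, np.random.default_rng(children[-2]))
    cohort = Cohort(
        samples=[f"{profile.stratum}-{i:05d}" for i in range(profile.n)],
        variants=copy.deepcopy(profile.variants),
        genotypes=geno,
        phenotype=np.zeros(profile.n),
        age=age, site=site, ancestry=ancestry,
        stratum_label=profile.stratum,
    )
    cohort.phenotype = simulate_outcome(
        cohort, effect, np.random.default_rng(children[-1]),
        target_prevalence=profile.target_prevalence)
    return cohort
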