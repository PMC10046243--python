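"""Pattern catalogue, design construction, BIC selection and the pair scan."""

import numpy as np
import pytest

from sipiscan import (EffectSpec, FitResult, PatternSpec, all_pairs, bic,
                      build_design, encode, enumerate_patterns,
                      make_stratum_cohort, scan_all_pairs, scan_pair,
                      simulate_genotypes)
from sipiscan.single_snp import fit_logistic

from _oracle import irls_logit
from conftest import build_cohort


# ---------------------------------------------------------------------------
# Coding and catalogue
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("g, mode, direction, expected", [
    (2, "A", "r", 0.0),
    (0, "D", "r", 1.0),   # non-carrier of minor = carrier of major
    (1, "R", "r", 1.0),
    (1, "A", "o", 1.0),
    (2, "R", "o", 1.0),
])
def test_encode(g, mode, direction, expected):
    assert encode(np.array([float(g)]), mode, direction)[0] == expected


def test_pattern_labels_round_trip():
    for pat in enumerate_patterns():
        assert PatternSpec.from_label(pat.label) == pat


def test_pattern_spec_rejects_invalid_direction_combos():
    with pytest.raises(ValueError):
        PatternSpec("D", "D", "Full", direction1="r")
    with pytest.raises(ValueError):
        PatternSpec("D", "D", "M1_int", direction2="r")


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def test_build_design_product_columns():
    g1 = np.array([0.0, 1.0, 2.0])
    g2 = np.array([0.0, 1.0, 2.0])
    X, names, pidx = build_design(PatternSpec.from_label("DD_int_rr"), g1, g2)
    assert names == ("intercept", "snp1:snp2")
    assert X[:, pidx].tolist() == [1.0, 0.0, 0.0]

    X, names, pidx = build_design(PatternSpec.from_label("AA_Full"),
                                  g1, np.array([2.0, 1.0, 0.0]))
    assert names == ("intercept", "snp1", "snp2", "snp1:snp2")
    assert X[:, pidx].tolist() == [0.0, 1.0, 0.0]


def test_build_design_reversal_applies_to_main_and_product():
    g1 = np.array([0.0, 1.0, 2.0, 0.0])
    g2 = np.array([1.0, 0.0, 2.0, 2.0])
    X, names, pidx = build_design(PatternSpec.from_label("DD_M1_int_r1"), g1, g2)
    x1r = 1.0 - (g1 >= 1)
    assert np.array_equal(X[:, names.index("snp1")], x1r)
    assert np.array_equal(X[:, pidx], x1r * (g2 >= 1))


def test_constant_product_is_flagged_unfittable():
    # no minor-homozygote overlap: RR product identically zero
    cohort = build_cohort({"v1": [2, 2, 0, 0, 1, 0], "v2": [0, 0, 2, 2, 1, 0]},
                          [1, 0, 1, 0, 1, 0])
    res = scan_pair(cohort, "v1", "v2",
                    patterns=[PatternSpec.from_label("RR_int_oo")])
    assert res.selected_pattern is None
    assert res.all_pattern_bics["RR_int_oo"] == "constant interaction term"


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------

def test_bic_formula():
    def fr(llf, k, n):
        return FitResult(terms=("x",) * k, params=np.zeros(k), bse=np.zeros(k),
                         pvalues=np.zeros(k), llf=llf, n_used=n, k=k,
                         converged=True)
    assert bic(fr(0.0, 1, 1)) == 0.0
    assert bic(fr(-100.0, 5, 148)) == pytest.approx(200 + 5 * np.log(148))


def test_bic_matches_oracle_refit():
    rng = np.random.default_rng(31)
    g1 = simulate_genotypes(0.3, 400, rng)
    g2 = simulate_genotypes(0.4, 400, rng)
    y = rng.binomial(1, 0.35, 400).astype(float)
    X, names, _ = build_design(PatternSpec.from_label("DR_int_or"), g1, g2)
    fit = fit_logistic(y, X, names)
    _, llf, _ = irls_logit(y, X)
    assert bic(fit) == pytest.approx(-2 * llf + X.shape[1] * np.log(400), abs=1e-6)


# ---------------------------------------------------------------------------
# Aliasing and invariance
# ---------------------------------------------------------------------------

def test_aliased_codings_fit_identically():
    """When no heterozygotes exist, dominant and recessive codings coincide,
    so DD_int_oo and RR_int_oo induce the same fit (label aliasing)."""
    rng = np.random.default_rng(5)
    g1 = rng.choice([0.0, 2.0], 300)
    g2 = rng.choice([0.0, 2.0], 300)
    y = rng.binomial(1, 0.4, 300).astype(float)
    cohort = build_cohort({"v1": g1, "v2": g2}, y)
    pats = [PatternSpec.from_label(s) for s in ("DD_int_oo", "RR_int_oo")]
    res = scan_pair(cohort, "v1", "v2", patterns=pats)
    b1, b2 = (res.all_pattern_bics[p.label] for p in pats)
    assert b1 == pytest.approx(b2, abs=1e-8)
    # the tie breaks to catalogue order
    assert res.selected_pattern.label == "DD_int_oo"


def test_identical_variants_full_models_degenerate():
    g = simulate_genotypes(0.4, 500, 8)
    y = np.random.default_rng(9).binomial(1, 0.3, 500).astype(float)
    cohort = build_cohort({"v1": g, "v2": g.copy()}, y)
    res = scan_pair(cohort, "v1", "v2")
    full_entries = {lab: v for lab, v in res.all_pattern_bics.items()
                    if lab.endswith("_Full")}
    assert full_entries and all(isinstance(v, str) for v in full_entries.values())
    assert res.selected_pattern is not None  # interaction-only models still fit


# ---------------------------------------------------------------------------
# Pair scanning
# ---------------------------------------------------------------------------

def test_scan_pair_selects_min_bic_and_reports_product_term():
    cohort = make_stratum_cohort("EA", seed=23)
    res = scan_pair(cohort, "rs1801133", "rs2236225")
    numeric = {k: v for k, v in res.all_pattern_bics.items()
               if isinstance(v, float)}
    assert res.bic_selected == pytest.approx(min(numeric.values()), abs=1e-9)
    assert 0 < res.p_pair <= 1
    assert res.ci_95[0] < res.interaction_or < res.ci_95[1]
    assert res.n_used == cohort.n


def test_scan_pair_recovers_generating_partition():
    """Data generated under DD_int_ro with |beta| = 1: the selected
    pattern's exposed-cell partition of the 3x3 genotype grid matches the
    generating one (labels may alias, the partition may not)."""
    effect = EffectSpec(pattern="DD_int_ro", variant_1="rs1801133",
                        variant_2="rs2236225", beta_interaction=1.0)
    cohort = make_stratum_cohort("EA", effect=effect, seed=29, n=50_000)
    res = scan_pair(cohort, "rs1801133", "rs2236225")
    dos = np.arange(3.0)

    def partition(pat):
        x1 = encode(dos, pat.mode1, pat.direction1)
        x2 = encode(dos, pat.mode2, pat.direction2)
        return np.outer(x1, x2) != 0

    assert np.array_equal(partition(res.selected_pattern),
                          partition(effect.pattern))


def test_scan_all_pairs_row_counts_and_ordering():
    rng = np.random.default_rng(41)
    geno = {f"v{i}": simulate_genotypes(0.2 + 0.05 * i, 150, rng)
            for i in range(5)}
    y = rng.binomial(1, 0.35, 150).astype(float)
    cohort = build_cohort(geno, y)
    results = scan_all_pairs(cohort)
    assert len(results) == 10
    ps = [r.p_pair for r in results if np.isfinite(r.p_pair)]
    assert ps == sorted(ps)
    assert len(scan_all_pairs(cohort, ["v0", "v1"])) == 1
    assert len(all_pairs(list(geno))) == 10


def test_scan_power_increases_with_effect_size():
    """Average power to call p_pair < 0.05 rises monotonically in |beta|."""
    betas = [0.0, 0.8, 1.6]
    reps = 12
    power = []
    for b in betas:
        hits = 0
        for r in range(reps):
            effect = (None if b == 0.0 else
                      EffectSpec(pattern="DD_int_oo", variant_1="rs1801133",
                                 variant_2="rs2236225", beta_interaction=b))
            cohort = make_stratum_cohort("EA", effect=effect,
                                         seed=1000 + r, n=1000)
            res = scan_pair(cohort, "rs1801133", "rs2236225")
            hits += res.selected_pattern is not None and res.p_pair < 0.05
        power.append(hits / reps)
    assert power[0] < power[1] <= power[2]
    assert power[2] > 0.9
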