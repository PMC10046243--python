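import numpy as np
import pytest

from sipiscan import Cohort, Variant


def build_cohort(genotypes: dict, y, age=None, site=None, ancestry=None,
                 variants=None, stratum="TEST") -> Cohort:
    """Assemble a small Cohort from per-variant dosage vectors."""
    ids = list(genotypes)
    n = len(np.atleast_1d(y))
    if variants is None:
        variants = [Variant(variant_id=v) for v in ids]
    rng = np.random.default_rng(12345)
    return Cohort(
        samples=[f"s{i}" for i in range(n)],
        variants=variants,
        genotypes=np.column_stack([np.asarray(genotypes[v], dtype=float)
                                   for v in ids]),
        phenotype=np.asarray(y, dtype=float),
        age=np.asarray(age, dtype=float) if age is not None
            else rng.normal(64.0, 7.7, n),
        site=np.asarray(site, dtype=float) if site is not None
            else rng.binomial(1, 0.5, n).astype(float),
        ancestry=np.asarray(ancestry, dtype=float) if ancestry is not None
            else rng.uniform(0.8, 1.0, n),
        stratum_label=stratum,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
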