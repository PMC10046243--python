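"""Result tables, genotype-combination prevalence grids, and the pipeline
driver.

The layouts mirror the study's printed surfaces: a per-variant association
table (variant, minor<major, MAF, best mode, OR, CI, p), a pair table
(pattern, OR, CI, p, bootstrap significance %), a 3x3 case-prevalence grid
per genotype combination with the selected pattern's exposed cells marked,
and a participants summary (n, age, site split, prevalence).  ORs are
rendered to 2 decimals, p-values to 3, MAFs to 2.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .bootstrap import (ThreePRuleConfig, ValidationResult,
                        bootstrap_significance, select_significant_pairs)
from .cohort import Cohort, DataError, TableDialect, Variant, \
    determine_minor_alleles, read_genotype_table, read_variant_table
from .simulate import EffectSpec, make_stratum_cohort
from .single_snp import SnpResult, bonferroni_threshold, snp_association
from .sipi import PairResult, PatternSpec, encode, scan_all_pairs

log = logging.getLogger(__name__)

__all__ = [
    "PrevalenceGrid",
    "prevalence_grid",
    "cohort_summary",
    "snp_table",
    "pair_table",
    "PipelineConfig",
    "run_pipeline",
]


def fmt_or_ci(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.2f} ({lo:.2f}, {hi:.2f})"


def fmt_p(p: float) -> str:
    return f"{p:.3f}"


# ---------------------------------------------------------------------------
# Prevalence grids
# ---------------------------------------------------------------------------

@dataclass
class PrevalenceGrid:
    """Case prevalence and sample size per genotype combination (3x3).

    ``overlay[i, j]`` marks the cells where the selected pattern's product
    term is non-zero, i.e. the genotype combinations the interaction model
    groups into the exposed class.
    """

    variant_1: str
    variant_2: str
    labels_1: tuple[str, str, str]
    labels_2: tuple[str, str, str]
    prevalence: np.ndarray  # (3, 3), nan where the cell is empty
    n: np.ndarray           # (3, 3) int
    overlay: np.ndarray | None
    overall_prevalence: float

    def to_frame(self) -> pd.DataFrame:
        """Printable grid: 'prev (n)' per cell, variant 1 on rows."""
        cells = np.empty((3, 3), dtype=object)
        for i in range(3):
            for j in range(3):
                if self.n[i, j] == 0:
                    cells[i, j] = ""
                else:
                    mark = "*" if self.overlay is not None and self.overlay[i, j] else ""
                    cells[i, j] = f"{self.prevalence[i, j]:.2f} ({self.n[i, j]}){mark}"
        return pd.DataFrame(cells, index=list(self.labels_1),
                            columns=list(self.labels_2))


def prevalence_grid(cohort: Cohort, variant_1: str, variant_2: str,
                    pattern: PatternSpec | str | None = None) -> PrevalenceGrid:
    """Per-genotype-combination case prevalence for a variant pair."""
    if isinstance(pattern, str):
        pattern = PatternSpec.from_label(pattern)
    g1, g2, y = cohort.dosage(variant_1), cohort.dosage(variant_2), cohort.phenotype
    mask = np.isfinite(g1) & np.isfinite(g2) & np.isfinite(y)
    if not mask.any():
        raise DataError("no complete cases for this pair")
    g1, g2, y = g1[mask], g2[mask], y[mask]

    prev = np.full((3, 3), np.nan)
    n = np.zeros((3, 3), dtype=int)
    for a in range(3):
        for b in range(3):
            cell = (g1 == a) & (g2 == b)
            n[a, b] = int(cell.sum())
            if n[a, b]:
                prev[a, b] = float(y[cell].mean())

    overlay = None
    if pattern is not None:
        dosages = np.arange(3, dtype=float)
        x1 = encode(dosages, pattern.mode1, pattern.direction1)
        x2 = encode(dosages, pattern.mode2, pattern.direction2)
        overlay = np.outer(x1, x2) != 0

    return PrevalenceGrid(
        variant_1=variant_1, variant_2=variant_2,
        labels_1=cohort.variant(variant_1).genotype_labels(),
        labels_2=cohort.variant(variant_2).genotype_labels(),
        prevalence=prev, n=n, overlay=overlay,
        overall_prevalence=float(y.mean()),
    )


# ---------------------------------------------------------------------------
# Summaries and tables
# ---------------------------------------------------------------------------

def cohort_summary(cohort: Cohort, other: Cohort | None = None) -> dict:
    """Participants summary: n, age mean+-SD, site split, case prevalence.

    With a second cohort, adds between-stratum tests: Welch-free two-sample
    t-test for age, Pearson chi-square (no continuity correction) for site
    and for the outcome split.
    """
    def one(c: Cohort) -> dict:
        y = c.phenotype[np.isfinite(c.phenotype)]
        cases = int(y.sum())
        return {
            "stratum": c.stratum_label,
            "n": c.n,
            "age_mean": float(np.nanmean(c.age)),
            "age_sd": float(np.nanstd(c.age, ddof=1)),
            "site_louisiana_n": int(np.nansum(c.site)),
            "site_louisiana_pct": round(100.0 * np.nanmean(c.site), 1),
            "cases_n": cases,
            "prevalence_pct": round(100.0 * cases / y.size, 1),
        }

    out = one(cohort)
    if other is not None:
        out2 = one(other)
        t_p = stats.ttest_ind(cohort.age[np.isfinite(cohort.age)],
                              other.age[np.isfinite(other.age)]).pvalue

        def chi2_2x2(x1, x2):
            tab = np.array([[np.nansum(x1), np.sum(np.isfinite(x1)) - np.nansum(x1)],
                            [np.nansum(x2), np.sum(np.isfinite(x2)) - np.nansum(x2)]])
            if np.any(tab.sum(axis=0) == 0):
                return 1.0
            return float(stats.chi2_contingency(tab, correction=False)[1])

        out = {
            "strata": (out, out2),
            "age_p": float(t_p),
            "site_p": chi2_2x2(cohort.site, other.site),
            "outcome_p": chi2_2x2(cohort.phenotype, other.phenotype),
        }
    return out


def snp_table(cohort: Cohort, results: list[SnpResult]) -> pd.DataFrame:
    """Per-variant association table in the printed layout."""
    mode_label = {"additive": "Add", "dominant": "Dom", "recessive": "Rec"}
    rows = []
    for r in results:
        var = cohort.variant(r.variant_id)
        minmaj = (f"{var.minor_allele} < {var.major_allele}"
                  if var.minor_allele and var.major_allele else "")
        rows.append({
            "SNP": r.variant_id,
            "Chr": var.chromosome,
            "Gene": var.gene,
            "Min < Maj": minmaj,
            "MAF": f"{var.maf:.2f}" if var.maf is not None else "",
            "Mode": mode_label.get(r.best_mode, ""),
            "OR (95% CI)": (fmt_or_ci(r.best_or, *r.best_ci)
                            if r.best_mode else ""),
            "p": fmt_p(r.best_p) if r.best_mode else "",
        })
    return pd.DataFrame(rows)


def pair_table(cohort: Cohort, results: list[PairResult],
               validations: list[ValidationResult] | None = None) -> pd.DataFrame:
    """Pair scan table; adds Significance% when validations are supplied."""
    by_id = {v.pair_id: v for v in validations} if validations else {}
    rows = []
    for r in results:
        row = {
            "SNP Pair": r.pair_id,
            "Gene1": cohort.variant(r.variant_1).gene,
            "Gene2": cohort.variant(r.variant_2).gene,
            "Pattern": r.selected_pattern.label if r.selected_pattern else "unfittable",
            "OR (95% CI)": (fmt_or_ci(r.interaction_or, *r.ci_95)
                            if r.selected_pattern else ""),
            "p-Value": fmt_p(r.p_pair) if r.selected_pattern else "",
        }
        if validations is not None:
            val = by_id.get(r.pair_id)
            row["Significance%"] = (f"{val.significance_pct:.1f}"
                                    if val is not None else "")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulated stratum or genotype files)."""

    out_dir: str | Path
    stratum: str | None = None            # simulate a bundled profile ...
    n: int | None = None                  # override the profile sample size
    effect: EffectSpec | None = None
    genotype_table: str | Path | None = None  # ... or read real files
    variants_table: str | Path | None = None
    dialect: TableDialect | None = None
    seed: int = 0
    B: int = 500
    alpha_single: float = 0.05
    rule: ThreePRuleConfig = ThreePRuleConfig()

    def validate(self) -> None:
        if (self.stratum is None) == (self.genotype_table is None):
            raise DataError("config must set exactly one of stratum / genotype_table")
        if self.genotype_table is not None:
            dialect = self.dialect or TableDialect()
            if not dialect.phenotype:
                raise DataError("config dialect must name the phenotype column")
        if self.B < 1:
            raise DataError("bootstrap replicate count must be >= 1")


def _load_cohort(config: PipelineConfig) -> Cohort:
    if config.stratum is not None:
        return make_stratum_cohort(config.stratum, effect=config.effect,
                                   seed=config.seed, n=config.n)
    variants = (read_variant_table(config.variants_table)
                if config.variants_table else None)
    cohort = read_genotype_table(config.genotype_table, variants=variants,
                                 dialect=config.dialect)
    determine_minor_alleles(cohort)
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Run cohort -> single-variant scan -> pair scan -> bootstrap -> report.

    Writes ``single_snp.tsv``, ``pairs.tsv``, ``validated.tsv``,
    ``selected.tsv`` and a ``manifest.json`` recording seeds, thresholds
    and per-stage status into ``out_dir``; returns the manifest dict.
    Completed stages are preserved if a later one fails.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "B": config.B,
        "rule": dataclasses.asdict(config.rule),
        "stages": {},
        "outputs": {},
    }

    def finish(stage: str, t0: float, **extra) -> None:
        manifest["stages"][stage] = {"status": "ok",
                                     "seconds": round(time.perf_counter() - t0, 3),
                                     **extra}
        log.info("stage %-12s ok (%.1fs)", stage,
                 time.perf_counter() - t0)

    def write_manifest() -> None:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "load"
    try:
        t0 = time.perf_counter()
        cohort = _load_cohort(config)
        finish(stage, t0, n=cohort.n, variants=len(cohort.variants))

        stage = "single_snp"
        t0 = time.perf_counter()
        snp_results = [snp_association(cohort, vid) for vid in cohort.variant_ids]
        table = snp_table(cohort, snp_results)
        path = out_dir / "single_snp.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["single_snp"] = path.name
        thr = bonferroni_threshold(len(cohort.variant_ids))
        finish(stage, t0, bonferroni=round(thr, 4))

        stage = "pair_scan"
        t0 = time.perf_counter()
        pair_results = scan_all_pairs(cohort)
        path = out_dir / "pairs.tsv"
        pair_table(cohort, pair_results).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["pairs"] = path.name
        n_pairs = len(pair_results)
        finish(stage, t0, pairs=n_pairs,
               bonferroni=round(bonferroni_threshold(n_pairs), 4))

        stage = "bootstrap"
        t0 = time.perf_counter()
        top = [r for r in pair_results
               if r.selected_pattern is not None
               and r.p_pair < config.rule.alpha_final]
        ss = np.random.SeedSequence([config.seed, 7_919])
        validations = []
        for r, child in zip(top, ss.spawn(max(len(top), 1))):
            validations.append(bootstrap_significance(
                cohort, r.variant_1, r.variant_2, r.selected_pattern,
                B=config.B, seed=child, config=config.rule, p_pair=r.p_pair))
        path = out_dir / "validated.tsv"
        pair_table(cohort, top, validations).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["validated"] = path.name
        finish(stage, t0, validated_pairs=len(top))

        stage = "select"
        t0 = time.perf_counter()
        selected = select_significant_pairs(top, validations, config.rule)
        path = out_dir / "selected.tsv"
        selected.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"]["selected"] = path.name
        finish(stage, t0, selected_pairs=len(selected))
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest["failure_point"] = stage
        write_manifest()
        raise

    write_manifest()
    return manifest
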