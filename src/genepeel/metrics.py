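"""Imputation accuracy statistics.

The headline statistic is the animal-specific *corrected* accuracy: the
Pearson correlation, over SNPs, of (true genotype - mean gene content) with
(imputed dosage - mean gene content), where mean gene content (2p) is the
per-SNP average genotype code in the genotyped reference set.  Subtracting
it removes the between-SNP variance driven by allele-frequency differences,
which otherwise inflates the raw ("uncorrected") correlation — most
severely when the imputation is poor.  SNP-specific accuracy is the raw
correlation across test animals, and call rates split hard calls into
percent correct / incorrect / not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelativeCategory
from .peeling import ImputationResult
from .simulate import MISSING, GenotypeMatrix, ScenarioSpec

__all__ = [
    "AccuracyReport",
    "mean_gene_content",
    "animal_accuracy",
    "snp_accuracy",
    "genotype_call_rates",
    "score_scenario",
    "summarize",
]

_CATEGORY_ORDER = [c.value for c in RelativeCategory]


def mean_gene_content(obs: GenotypeMatrix, reference: Sequence[str]) -> np.ndarray:
    """Per-SNP mean genotype code (2p) over the reference individuals."""
    reference = list(reference)
    if not reference:
        raise ValueError("reference set is empty")
    rows = obs.codes[obs.positions(reference)]
    known = rows != MISSING
    counts = known.sum(axis=0)
    if np.any(counts == 0):
        j = int(np.argmax(counts == 0))
        raise ValueError(f"no observed reference genotype at SNP index {j}")
    return (rows * known).sum(axis=0) / counts


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, or NaN when either variance is zero (flagged undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    vx = (xc**2).sum()
    vy = (yc**2).sum()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    return float((xc * yc).sum() / np.sqrt(vx * vy))


def animal_accuracy(
    true_row: np.ndarray, dosage_row: np.ndarray, mgc: np.ndarray
) -> tuple[float, float]:
    """(corrected r, uncorrected r) for one animal over its SNPs."""
    true_row = np.asarray(true_row, dtype=float)
    dosage_row = np.asarray(dosage_row, dtype=float)
    if not (true_row.shape == dosage_row.shape == np.shape(mgc)):
        raise ValueError("true, dosage and mean-gene-content rows must align")
    corrected = _pearson(true_row - mgc, dosage_row - mgc)
    uncorrected = _pearson(true_row, dosage_row)
    return corrected, uncorrected


def snp_accuracy(true_col: np.ndarray, dosage_col: np.ndarray) -> float:
    """Correlation of true genotypes with dosages across test animals."""
    if np.shape(true_col) != np.shape(dosage_col):
        raise ValueError("true and dosage columns must align")
    return _pearson(true_col, dosage_col)


def genotype_call_rates(
    true: GenotypeMatrix, called: GenotypeMatrix, tests: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent correct / incorrect / not-imputed per test animal and per SNP."""
    tests = list(tests)
    t = true.codes[true.positions(tests)].astype(int)
    c = called.codes[called.positions(tests)].astype(int)
    if t.shape != c.shape:
        raise ValueError("true and called matrices must align")
    not_imp = c == MISSING
    correct = (c == t) & ~not_imp
    incorrect = ~correct & ~not_imp

    per_animal = pd.DataFrame(
        {
            "id": tests,
            "pct_correct": 100.0 * correct.mean(axis=1),
            "pct_incorrect": 100.0 * incorrect.mean(axis=1),
            "pct_not_imputed": 100.0 * not_imp.mean(axis=1),
        }
    )
    per_snp = pd.DataFrame(
        {
            "snp": np.arange(t.shape[1]),
            "pct_correct": 100.0 * correct.mean(axis=0),
            "pct_incorrect": 100.0 * incorrect.mean(axis=0),
            "pct_not_imputed": 100.0 * not_imp.mean(axis=0),
        }
    )
    return per_animal, per_snp


def score_scenario(
    ped: Pedigree,
    true_g: GenotypeMatrix,
    result: ImputationResult,
    spec: ScenarioSpec,
    observed: Optional[GenotypeMatrix] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal and per-SNP accuracy tables for one imputation run.

    Mean gene content and MAF come from the scenario's genotyped reference
    (``observed`` defaults to the true matrix restricted to the reference,
    which is identical under all-or-nothing masking).
    """
    reference = sorted(spec.genotyped_ids)
    tests = sorted(spec.test_ids)
    source = observed if observed is not None else true_g
    mgc = mean_gene_content(source, reference)
    genotyped = set(spec.genotyped_ids)

    probs = result.probabilities
    rows = []
    t_mat = np.empty((len(tests), true_g.n_snps))
    d_mat = np.empty((len(tests), true_g.n_snps))
    for k, ind_id in enumerate(tests):
        t_row = true_g.row(ind_id).astype(float)
        d_row = probs.dosage_row(ind_id)
        t_mat[k] = t_row
        d_mat[k] = d_row
        r_c, r_u = animal_accuracy(t_row, d_row, mgc)
        rows.append(
            {
                "id": ind_id,
                "category": ped.classify_relatives(genotyped, ind_id).value,
                "r_corrected": r_c,
                "r_uncorrected": r_u,
            }
        )
    per_animal = pd.DataFrame(rows)
    call_animal, call_snp = genotype_call_rates(true_g, result.called, tests)
    per_animal = per_animal.merge(call_animal, on="id")

    maf = np.minimum(mgc / 2.0, 1.0 - mgc / 2.0)
    r_snp = np.array(
        [snp_accuracy(t_mat[:, j], d_mat[:, j]) for j in range(true_g.n_snps)]
    )
    per_snp = pd.DataFrame({"snp": np.arange(true_g.n_snps), "maf": maf, "r": r_snp})
    per_snp = per_snp.merge(call_snp, on="snp")
    return per_animal, per_snp


@dataclass
class AccuracyReport:
    """Aggregated accuracy tables (animals x replicates pooled)."""

    per_animal: pd.DataFrame
    per_snp: pd.DataFrame
    by_category: pd.DataFrame
    overall: pd.Series
    maf_binned: pd.DataFrame

    def write(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in (
            ("per_animal", self.per_animal),
            ("per_snp", self.per_snp),
            ("by_category", self.by_category),
            ("maf_binned", self.maf_binned),
        ):
            table.to_csv(directory / f"{prefix}{name}.tsv", sep="\t", index=False)
        self.overall.to_csv(
            directory / f"{prefix}overall.tsv", sep="\t", header=False
        )


def summarize(
    per_animal: pd.DataFrame,
    per_snp: pd.DataFrame,
    maf_bins: int = 20,
) -> AccuracyReport:
    """Pool per-animal and per-SNP tables (possibly many replicates).

    Undefined (NaN) correlations are excluded from the means rather than
    zero-filled; percentages are averaged over all animals.  SNP accuracy is
    additionally averaged within equal-width MAF bins on [0, 0.5].
    """
    per_animal = per_animal.reset_index(drop=True)
    per_snp = per_snp.reset_index(drop=True)

    def agg(group: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(group),
                "r_corrected_mean": group["r_corrected"].mean(),
                "r_corrected_sd": group["r_corrected"].std(ddof=1),
                "r_uncorrected_mean": group["r_uncorrected"].mean(),
                "r_uncorrected_sd": group["r_uncorrected"].std(ddof=1),
                "pct_correct": group["pct_correct"].mean(),
                "pct_incorrect": group["pct_incorrect"].mean(),
                "pct_not_imputed": group["pct_not_imputed"].mean(),
            }
        )

    parts = []
    for cat, group in per_animal.groupby("category", sort=False):
        row = agg(group)
        row["category"] = cat
        parts.append(row)
    by_cat = pd.DataFrame(parts)
    by_cat["category"] = pd.Categorical(
        by_cat["category"], categories=_CATEGORY_ORDER, ordered=True
    )
    by_cat = (
        by_cat.sort_values("category")
        .reset_index(drop=True)[
            ["category", "n", "r_corrected_mean", "r_corrected_sd",
             "r_uncorrected_mean", "r_uncorrected_sd", "pct_correct",
             "pct_incorrect", "pct_not_imputed"]
        ]
    )
    overall = agg(per_animal)

    edges = np.linspace(0.0, 0.5, maf_bins + 1)
    binned = per_snp.copy()
    binned["maf_bin"] = pd.cut(binned["maf"], edges, include_lowest=True)
    maf_binned = (
        binned.groupby("maf_bin", observed=True)
        .agg(
            n=("r", "size"),
            r_mean=("r", "mean"),
            pct_correct=("pct_correct", "mean"),
            pct_incorrect=("pct_incorrect", "mean"),
            pct_not_imputed=("pct_not_imputed", "mean"),
        )
        .reset_index()
    )
    return AccuracyReport(per_animal, per_snp, by_cat, overall, maf_binned)
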