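"""Selection-index prediction of animal-specific imputation accuracy.

Gene content at a biallelic locus behaves as an additively inherited trait
with heritability 1 (absent genotyping errors), so the accuracy of the best
linear prediction of an individual's gene content from its genotyped
relatives is the classical selection-index accuracy

    r = sqrt(G' P^-1 G),

where P holds the additive relationships among the information sources
(diagonal 1 + F) and G the additive relationships between each source and
the candidate.  The standard prediction grid covers candidates with both
parents, sire + maternal grandsire, or a single parent genotyped, combined
with 0/1/2/4 genotyped maternal half-sib offspring whose own sires (the
candidate's mates) are unrelated and ungenotyped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .pedigree import UNKNOWN, Individual, Pedigree

__all__ = [
    "InfoSet",
    "build_P_G",
    "predicted_accuracy",
    "predict_accuracy_from_pedigree",
    "predict_grid",
    "GRID_ANCESTOR_CONFIGS",
    "GRID_OFFSPRING_COUNTS",
]

GRID_ANCESTOR_CONFIGS = ("BothParents", "SireMGS", "Sire")
GRID_OFFSPRING_COUNTS = (0, 1, 2, 4)

#: Display labels matching the symmetric ancestor configurations.
_GRID_LABELS = {
    "BothParents": "Both parents",
    "SireMGS": "SireMGS/DamPGS",
    "Sire": "Sire/Dam",
}


@dataclass(frozen=True)
class InfoSet:
    """A candidate, its genotyped information sources, and their pedigree."""

    candidate: str
    sources: tuple[str, ...]
    pedigree: Pedigree

    def __post_init__(self) -> None:
        if self.candidate in self.sources:
            raise ValueError("candidate cannot be one of its information sources")
        if len(set(self.sources)) != len(self.sources):
            raise ValueError("information sources must be distinct")


def build_P_G(info: InfoSet) -> tuple[np.ndarray, np.ndarray]:
    """Source covariance matrix P and source-candidate covariance vector G."""
    ped = info.pedigree
    ids = list(info.sources)
    k = len(ids)
    P = np.empty((k, k))
    for i in range(k):
        P[i, i] = 1.0 + ped.inbreeding(ids[i])
        for j in range(i + 1, k):
            P[i, j] = P[j, i] = ped.additive_relationship(ids[i], ids[j])
    G = np.array([ped.additive_relationship(s, info.candidate) for s in ids])
    return P, G


def predicted_accuracy(P: np.ndarray, G: np.ndarray) -> float:
    """Selection-index accuracy r = sqrt(G' P^-1 G); 0 for no sources."""
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.size == 0:
        return 0.0
    try:
        c, low = linalg.cho_factor(P)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "P is not positive definite (duplicated or linearly dependent "
            "information sources)"
        ) from exc
    r2 = float(G @ linalg.cho_solve((c, low), G))
    return float(np.sqrt(min(max(r2, 0.0), 1.0)))


def predict_accuracy_from_pedigree(
    ped: Pedigree, candidate: str, sources: Sequence[str]
) -> float:
    """Convenience wrapper: build P and G from a pedigree and solve."""
    info = InfoSet(candidate, tuple(sources), ped)
    return predicted_accuracy(*build_P_G(info))


def _grid_pedigree(n_offspring: int) -> Pedigree:
    """Fixture pedigree: candidate cow with ancestors and half-sib offspring.

    Parents mutually unrelated and non-inbred, the dam a daughter of the
    maternal grandsire, offspring from distinct unrelated mate sires (so the
    offspring are maternal half sibs with pairwise relationship 1/4).
    """
    records = [
        Individual("mgs", sex="male"),
        Individual("sire", sex="male"),
        Individual("dam", "mgs", UNKNOWN, sex="female"),
        Individual("cand", "sire", "dam", sex="female"),
    ]
    for j in range(n_offspring):
        records.append(Individual(f"mate{j}", sex="male"))
        records.append(Individual(f"off{j}", f"mate{j}", "cand"))
    return Pedigree(records)


def predict_grid(
    ancestor_configs: Sequence[str] = GRID_ANCESTOR_CONFIGS,
    offspring_counts: Sequence[int] = GRID_OFFSPRING_COUNTS,
) -> pd.DataFrame:
    """Accuracy grid (rounded to 2 decimals), ancestor config x offspring count."""
    source_map = {
        "BothParents": ["sire", "dam"],
        "SireMGS": ["sire", "mgs"],
        "Sire": ["sire"],
    }
    rows = {}
    for config in ancestor_configs:
        if config not in source_map:
            raise ValueError(f"unknown ancestor configuration {config!r}")
        row = {}
        for k in offspring_counts:
            ped = _grid_pedigree(k)
            sources = source_map[config] + [f"off{j}" for j in range(k)]
            row[k] = round(predict_accuracy_from_pedigree(ped, "cand", sources), 2)
        rows[_GRID_LABELS.get(config, config)] = row
    grid = pd.DataFrame(rows).T
    grid.index.name = "ancestors"
    grid.columns.name = "n_offspring"
    return grid
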