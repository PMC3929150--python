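"""Replicated end-to-end experiments: simulate, mask, impute, score, predict.

One pedigree is generated per experiment (the family structure is a design
constant); founder haplotypes and gene drop are re-simulated per replicate,
and each scenario of a replicate shares the same true genotypes, differing
only in which individuals are masked.  Accuracy tables are pooled over
animals x replicates, and each ancestor-category / offspring-count cell is
set beside its selection-index prediction.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .peeling import PeelingOptions, impute_all
from .pedigree import Pedigree
from .selection_index import predict_grid
from .simulate import (
    FounderModel,
    StudyDesign,
    StudyPedigree,
    apply_scenario,
    build_study_pedigree,
    gene_drop,
    simulate_founder_haplotypes,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

logger = logging.getLogger("genepeel")

_SCENARIO_RE = re.compile(r"^Off([0-9]+)$")

#: Category -> ancestor configuration of the prediction grid (symmetric
#: configurations share a prediction).
_CATEGORY_TO_GRID = {
    "BothParents": "Both parents",
    "SireMGS": "SireMGS/DamPGS",
    "DamPGS": "SireMGS/DamPGS",
    "Sire": "Sire/Dam",
    "Dam": "Sire/Dam",
}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    design: StudyDesign = field(default_factory=StudyDesign)
    founder: FounderModel = field(default_factory=FounderModel)
    scenarios: tuple[str, ...] = ("Off0", "Off1", "Off2", "Off4")
    peeling: PeelingOptions = field(default_factory=PeelingOptions)
    n_replicates: int = 10
    base_seed: int = 1
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in self.scenarios:
            if self._offspring_count(name) > self.design.n_offspring_per_cow:
                raise ValueError(
                    f"scenario {name!r} needs more offspring than the design "
                    f"provides ({self.design.n_offspring_per_cow})"
                )

    @staticmethod
    def _offspring_count(name: str) -> int:
        m = _SCENARIO_RE.match(name)
        if m:
            return int(m.group(1))
        if name in ("SireMGS", "RealLike"):
            return 0
        raise ValueError(f"unknown scenario name {name!r}")

    # -- config file --------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for section, klass in (
            ("design", StudyDesign),
            ("founder", FounderModel),
            ("peeling", PeelingOptions),
        ):
            if section in raw:
                kwargs[section] = klass(**raw.pop(section))
        if "scenarios" in raw:
            kwargs["scenarios"] = tuple(raw.pop("scenarios"))
        kwargs.update(raw)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "design": dataclasses.asdict(self.design),
            "founder": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.founder).items()
            },
            "peeling": dataclasses.asdict(self.peeling),
            "scenarios": list(self.scenarios),
            "n_replicates": self.n_replicates,
            "base_seed": self.base_seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ExperimentResult:
    """Pooled reports per scenario plus the cross-scenario summary grids."""

    study: StudyPedigree
    reports: dict[str, metrics.AccuracyReport]
    accuracy_grid: pd.DataFrame  # category x scenario, mean corrected r
    callrate_grid: pd.DataFrame  # (scenario, measure) rows x category columns
    theory: pd.DataFrame  # selection-index predictions per category x scenario

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, report in self.reports.items():
            report.write(directory, prefix=f"{name}_")
        self.accuracy_grid.to_csv(directory / "accuracy_by_category.tsv", sep="\t")
        self.callrate_grid.to_csv(directory / "call_rates.tsv", sep="\t")
        self.theory.to_csv(directory / "theory_predictions.tsv", sep="\t")


def _replicate_seeds(base_seed: int, replicate: int) -> tuple[int, int]:
    """Independent founder-simulation and gene-drop streams per replicate."""
    ss = np.random.SeedSequence(entropy=base_seed + replicate, spawn_key=(7,))
    founder_ss, drop_ss = ss.spawn(2)
    return (
        int(founder_ss.generate_state(1)[0] % 2**31),
        int(drop_ss.generate_state(1)[0] % 2**31),
    )


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every replicate and scenario; write reports if out_dir is set."""
    ped_seed = int(
        np.random.SeedSequence(entropy=cfg.base_seed, spawn_key=(11,))
        .generate_state(1)[0]
        % 2**31
    )
    study = build_study_pedigree(cfg.design, ped_seed)
    ped = study.pedigree
    logger.info(
        "experiment: pedigree of %d individuals (seed %d), %d replicate(s), "
        "scenarios %s",
        len(ped), ped_seed, cfg.n_replicates, ", ".join(cfg.scenarios),
    )

    per_animal: dict[str, list[pd.DataFrame]] = {s: [] for s in cfg.scenarios}
    per_snp: dict[str, list[pd.DataFrame]] = {s: [] for s in cfg.scenarios}
    n_failed = 0
    for rep in range(cfg.n_replicates):
        founder_seed, drop_seed = _replicate_seeds(cfg.base_seed, rep)
        logger.info(
            "replicate %d: founder seed %d, gene-drop seed %d",
            rep, founder_seed, drop_seed,
        )
        try:
            pool, gmap = simulate_founder_haplotypes(
                cfg.founder, 2 * len(ped), founder_seed
            )
            true = gene_drop(ped, pool, gmap, drop_seed)
            for name in cfg.scenarios:
                k = cfg._offspring_count(name)
                spec = study.scenario(k, name=name)
                obs = apply_scenario(true, spec)
                result = impute_all(ped, obs, cfg.peeling)
                pa, ps = metrics.score_scenario(ped, true, result, spec, obs)
                pa = pa.assign(replicate=rep, scenario=name)
                ps = ps.assign(replicate=rep, scenario=name)
                per_animal[name].append(pa)
                per_snp[name].append(ps)
        except Exception:
            n_failed += 1
            logger.exception("replicate %d failed; continuing", rep)
    if n_failed == cfg.n_replicates:
        raise RuntimeError("all replicates failed")

    reports = {
        name: metrics.summarize(
            pd.concat(per_animal[name], ignore_index=True),
            pd.concat(per_snp[name], ignore_index=True),
        )
        for name in cfg.scenarios
    }

    accuracy_grid = pd.DataFrame(
        {
            name: report.by_category.set_index("category")["r_corrected_mean"]
            for name, report in reports.items()
        }
    )
    accuracy_grid.loc["Total"] = {
        name: report.overall["r_corrected_mean"] for name, report in reports.items()
    }

    call_parts = []
    for name, report in reports.items():
        t = report.by_category.set_index("category")[
            ["pct_correct", "pct_incorrect", "pct_not_imputed"]
        ].T
        t["Total"] = [
            report.overall["pct_correct"],
            report.overall["pct_incorrect"],
            report.overall["pct_not_imputed"],
        ]
        t.index = pd.MultiIndex.from_product([[name], t.index])
        call_parts.append(t)
    callrate_grid = pd.concat(call_parts)

    grid = predict_grid()
    theory = pd.DataFrame(index=accuracy_grid.index, columns=list(cfg.scenarios))
    for name in cfg.scenarios:
        k = cfg._offspring_count(name)
        if k not in grid.columns:
            continue
        for cat in accuracy_grid.index:
            label = _CATEGORY_TO_GRID.get(str(cat))
            if label is not None:
                theory.loc[cat, name] = grid.loc[label, k]
    theory = theory.astype(float)

    result = ExperimentResult(study, reports, accuracy_grid, callrate_grid, theory)
    if cfg.out_dir is not None:
        result.write(cfg.out_dir)
        logger.info("reports written to %s", cfg.out_dir)
    return result
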