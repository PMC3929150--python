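"""Study-like pedigree generation, founder haplotypes, gene drop, masking.

Emulates the data structure of the dairy-cattle imputation study this
package reproduces: ungenotyped test cows whose sires and maternal
grandsires are genotyped, a shared pool of ungenotyped mate sires, and
0/1/2/4 genotyped maternal half-sib offspring per cow.  Founder haplotypes
come either from an msprime coalescent simulation under a piecewise cattle
demography, or from a calibrated site-frequency ("sfs") model with
independent sites; base haplotypes are then dropped through the pedigree
with Haldane (no-interference) recombination on a 100 cM chromosome.

The sfs mode is the default for accuracy experiments because the imputation
method under study is strictly single-locus (no linkage or LD information),
so only the per-SNP allele-frequency spectrum matters; the coalescent mode
exists to reproduce that spectrum from the stated demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pedigree import UNKNOWN, Individual, Pedigree

__all__ = [
    "MISSING",
    "StudyDesign",
    "FounderModel",
    "GeneticMap",
    "ScenarioSpec",
    "HaplotypePool",
    "GenotypeMatrix",
    "TrueGenotypes",
    "StudyPedigree",
    "build_study_pedigree",
    "generate_study_pedigree",
    "simulate_founder_haplotypes",
    "gene_drop",
    "apply_scenario",
]

#: Genotype code for a missing / not-imputed genotype.
MISSING = 9

#: Beta(b, b) shape for the sfs-mode allele-frequency distribution,
#: calibrated so the expected minor-allele frequency E[min(p, 1-p)] equals
#: 0.23, the mean MAF produced by the coalescent mode under the default
#: cattle demography.
SFS_BETA_SHAPE = 0.8149


# ---------------------------------------------------------------------------
# genotype containers


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of genotype codes {0, 1, 2, 9=missing}."""

    ids: list[str]
    codes: np.ndarray  # (n_individuals, n_snps) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.ids):
            raise ValueError("genotype matrix shape does not match ids")
        self._pos = {i: k for k, i in enumerate(self.ids)}

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def row(self, ind_id: str) -> np.ndarray:
        return self.codes[self._pos[ind_id]]

    def positions(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self._pos[i] for i in ids], dtype=int)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), self.codes.copy())

    def write(self, path: str | Path) -> None:
        """AlphaImpute-style layout: id then one 0/1/2/9 code per SNP."""
        with open(path, "w") as fh:
            for ind_id, row in zip(self.ids, self.codes):
                fh.write(ind_id + " " + " ".join(map(str, row)) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "GenotypeMatrix":
        ids, rows = [], []
        with open(path) as fh:
            for line in fh:
                tokens = line.split()
                if not tokens:
                    continue
                ids.append(tokens[0])
                rows.append([int(round(float(t))) for t in tokens[1:]])
        return cls(ids, np.array(rows, dtype=np.int8))


@dataclass
class TrueGenotypes(GenotypeMatrix):
    """Phased true genotypes: per individual one gamete from each parent.

    ``gametes[k, 0]`` is the sire-derived gamete of individual k,
    ``gametes[k, 1]`` the dam-derived one; ``codes`` is their sum.
    ``crossovers[(id, side)]`` records the starting parental strand and the
    crossover positions (cM) of the meiosis that produced each gamete.
    """

    gametes: np.ndarray = None  # (n, 2, n_snps) int8
    crossovers: dict = field(default_factory=dict)

    def write_phased(self, path: str | Path) -> None:
        """Truth file: two gamete rows (sire-derived, dam-derived) per id."""
        with open(path, "w") as fh:
            for k, ind_id in enumerate(self.ids):
                for side in (0, 1):
                    fh.write(
                        ind_id
                        + " "
                        + " ".join(map(str, self.gametes[k, side]))
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# study design and pedigree generation


@dataclass(frozen=True)
class StudyDesign:
    """Counts defining the study-like pedigree.

    Every test cow has an ungenotyped dam (daughter of a maternal
    grandsire) and a sire drawn from the genotyped sire pool; offspring of
    the cows are maternal half sibs whose sires come from a shared pool of
    ungenotyped mate sires.
    """

    n_test_cows: int = 805
    n_mate_sires: int = 60
    n_offspring_per_cow: int = 4
    n_genotyped_sires: int = 50
    n_genotyped_mgs: int = 50
    #: Genotyped base reference unrelated to the test cows; the study's
    #: reference sets always contain the genotyped base population on top of
    #: the test cows' ancestors, which anchors allele-frequency estimates.
    extra_reference: int = 4000
    #: Fraction of cows whose sire and maternal grandsire are taken from the
    #: genotyped pools; the remainder get ungenotyped founder ancestors
    #: (used by the approximate "RealLike" scenario only).
    frac_cows_with_genotyped_ancestors: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "n_test_cows",
            "n_mate_sires",
            "n_offspring_per_cow",
            "n_genotyped_sires",
            "n_genotyped_mgs",
            "extra_reference",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_offspring_per_cow not in (0, 1, 2, 4):
            raise ValueError("n_offspring_per_cow must be one of 0, 1, 2, 4")
        if self.n_offspring_per_cow > self.n_mate_sires:
            raise ValueError(
                "n_offspring_per_cow exceeds the mate-sire pool: maternal "
                "half sibs need distinct mate sires within a cow"
            )
        if not 0.0 <= self.frac_cows_with_genotyped_ancestors <= 1.0:
            raise ValueError("frac_cows_with_genotyped_ancestors must be in [0,1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """Which individuals are genotyped (reference) vs to impute (test)."""

    name: str
    genotyped_ids: frozenset[str]
    test_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.genotyped_ids & self.test_ids:
            raise ValueError("genotyped and test sets must be disjoint")


@dataclass
class StudyPedigree:
    """A generated study pedigree plus the bookkeeping to derive scenarios."""

    pedigree: Pedigree
    design: StudyDesign
    sires: list[str]
    mgs: list[str]
    dams: list[str]
    cows: list[str]
    mate_sires: list[str]
    offspring: dict[str, list[str]]  # cow id -> ordered offspring ids
    extra_reference: list[str]

    def scenario(self, n_offspring: Optional[int] = None, name: Optional[str] = None) -> ScenarioSpec:
        """Masking spec with the first ``n_offspring`` offspring per cow genotyped."""
        k = self.design.n_offspring_per_cow if n_offspring is None else n_offspring
        if k > self.design.n_offspring_per_cow:
            raise ValueError(
                f"scenario requests {k} offspring but the pedigree has "
                f"{self.design.n_offspring_per_cow} per cow"
            )
        genotyped = set(self.sires) | set(self.mgs) | set(self.extra_reference)
        for cow in self.cows:
            genotyped.update(self.offspring[cow][:k])
        genotyped -= set(self.cows)  # cows are never genotyped
        return ScenarioSpec(
            name or f"Off{k}",
            frozenset(genotyped),
            frozenset(self.cows),
        )


def build_study_pedigree(design: StudyDesign, seed: int) -> StudyPedigree:
    """Generate the study-like pedigree for a design, reproducibly."""
    rng = np.random.default_rng(seed)
    records: list[Individual] = []

    sires = [f"sire{i:04d}" for i in range(design.n_genotyped_sires)]
    mgs = [f"mgs{i:04d}" for i in range(design.n_genotyped_mgs)]
    mates = [f"mate{i:04d}" for i in range(design.n_mate_sires)]
    extra = [f"ref{i:04d}" for i in range(design.extra_reference)]
    for sid in sires + mgs + mates:
        records.append(Individual(sid, sex="male"))
    for rid in extra:
        records.append(Individual(rid))

    n_linked = int(round(design.frac_cows_with_genotyped_ancestors * design.n_test_cows))
    # Ungenotyped founder ancestors for the cows beyond the linked fraction.
    unl_sires = [f"usire{i:04d}" for i in range(design.n_test_cows - n_linked)]
    unl_mgs = [f"umgs{i:04d}" for i in range(design.n_test_cows - n_linked)]
    for sid in unl_sires + unl_mgs:
        records.append(Individual(sid, sex="male"))

    dams, cows = [], []
    offspring: dict[str, list[str]] = {}
    for i in range(design.n_test_cows):
        linked = i < n_linked
        dam_id = f"dam{i:04d}"
        cow_id = f"cow{i:04d}"
        dam_sire = (
            mgs[rng.integers(len(mgs))] if linked and mgs else
            (unl_mgs[i - n_linked] if not linked else UNKNOWN)
        )
        cow_sire = (
            sires[rng.integers(len(sires))] if linked and sires else
            (unl_sires[i - n_linked] if not linked else UNKNOWN)
        )
        records.append(Individual(dam_id, dam_sire, UNKNOWN, sex="female"))
        records.append(Individual(cow_id, cow_sire, dam_id, sex="female"))
        dams.append(dam_id)
        cows.append(cow_id)
        # Maternal half sibs: mate sires drawn without replacement within a
        # cow, shared across cows.
        chosen = rng.choice(
            len(mates), size=design.n_offspring_per_cow, replace=False
        ) if design.n_offspring_per_cow else []
        kids = []
        for j, m in enumerate(chosen):
            kid = f"off{i:04d}_{j}"
            records.append(Individual(kid, mates[m], cow_id))
            kids.append(kid)
        offspring[cow_id] = kids

    ped = Pedigree(records)
    return StudyPedigree(
        ped, design, sires, mgs, dams, cows, mates, offspring, extra
    )


def generate_study_pedigree(
    design: StudyDesign, seed: int
) -> tuple[Pedigree, ScenarioSpec]:
    """Pedigree plus the scenario spec for the design's offspring count."""
    study = build_study_pedigree(design, seed)
    return study.pedigree, study.scenario()


# ---------------------------------------------------------------------------
# founder haplotypes


@dataclass(frozen=True)
class FounderModel:
    """How founder haplotypes are produced.

    ``coalescent`` simulates sequence under a piecewise-constant cattle
    demography (effective size 100 now, 1256 at 1000 y, 4350 at 10 000 y,
    43 500 at 100 000 y; per-site mutation rate 2.5e-8) and samples
    segregating sites uniformly at random, without MAF filtering.  ``sfs``
    draws per-SNP allele frequencies from Beta(b, b) (b calibrated so the
    mean MAF matches the coalescent mode's 0.23) and fills haplotypes with
    independent Bernoulli draws per site.
    """

    mode: str = "sfs"  # "sfs" | "coalescent"
    n_snps: int = 2000
    chromosome_length_cM: float = 100.0
    # coalescent mode
    sequence_length_bp: float = 5e7
    mutation_rate: float = 2.5e-8
    recombination_rate_per_bp: float = 1e-8
    epochs_years_size: tuple = ((0, 100), (1_000, 1_256), (10_000, 4_350), (100_000, 43_500))
    generation_interval_years: float = 5.0
    # sfs mode
    sfs_beta_shape: float = SFS_BETA_SHAPE
    sfs_point_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.mode not in ("sfs", "coalescent"):
            raise ValueError(f"unknown founder model mode {self.mode!r}")
        object.__setattr__(
            self,
            "epochs_years_size",
            tuple((float(t), float(n)) for t, n in self.epochs_years_size),
        )
        if self.sfs_point_frequency is not None and not (
            0.0 < self.sfs_point_frequency < 1.0
        ):
            raise ValueError("sfs_point_frequency must be in (0, 1)")


@dataclass
class GeneticMap:
    """Per-SNP cM positions on one chromosome, non-decreasing."""

    snp_ids: list[str]
    positions_cM: np.ndarray
    chromosome_length_cM: float = 100.0

    def __post_init__(self) -> None:
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        if len(self.snp_ids) != self.positions_cM.size:
            raise ValueError("map ids and positions differ in length")
        if self.positions_cM.size and (
            np.any(np.diff(self.positions_cM) < 0)
            or self.positions_cM.min() < 0
            or self.positions_cM.max() > self.chromosome_length_cM
        ):
            raise ValueError("map positions must be sorted within the chromosome")

    def __len__(self) -> int:
        return self.positions_cM.size

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, pos in zip(self.snp_ids, self.positions_cM):
                fh.write(f"{sid} 1 {pos:.6f}\n")

    @classmethod
    def read(cls, path: str | Path, chromosome_length_cM: float = 100.0) -> "GeneticMap":
        ids, pos = [], []
        with open(path) as fh:
            for line in fh:
                tokens = line.split()
                if not tokens:
                    continue
                ids.append(tokens[0])
                pos.append(float(tokens[-1]))
        return cls(ids, np.array(pos), chromosome_length_cM)


@dataclass
class HaplotypePool:
    """Founder haplotypes (0/1 alleles), every SNP segregating in the pool."""

    haplotypes: np.ndarray  # (n_haplotypes, n_snps) int8

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        freq = self.frequencies
        if np.any((freq <= 0) | (freq >= 1)):
            raise ValueError("haplotype pool contains non-segregating SNPs")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Pool frequency of the allele coded 1, per SNP."""
        return self.haplotypes.mean(axis=0)


def _coalescent_haplotypes(
    model: FounderModel, n_haplotypes: int, n_snps: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_haplotypes, n_snps) alleles at segregating sites sampled uniformly."""
    import msprime

    dem = msprime.Demography()
    (t0, size0), *rest = model.epochs_years_size
    dem.add_population(name="pop", initial_size=size0)
    for years, size in rest:
        dem.add_population_parameters_change(
            time=years / model.generation_interval_years, initial_size=size
        )
    if n_haplotypes % 2:
        raise ValueError("coalescent mode samples diploids: n_haplotypes must be even")
    ts = msprime.sim_ancestry(
        samples=n_haplotypes // 2,
        ploidy=2,
        demography=dem,
        sequence_length=model.sequence_length_bp,
        recombination_rate=model.recombination_rate_per_bp,
        random_seed=int(rng.integers(1, 2**31)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=model.mutation_rate,
        random_seed=int(rng.integers(1, 2**31)),
        model=msprime.BinaryMutationModel(),
    )
    # first pass: segregating biallelic sites; second pass: collect the sample
    counts = np.array(
        [v.genotypes.sum() for v in ts.variants()], dtype=np.int64
    )
    segregating = np.flatnonzero((counts > 0) & (counts < n_haplotypes))
    if segregating.size < n_snps:
        raise ValueError(
            f"only {segregating.size} segregating sites simulated, "
            f"need {n_snps}; increase sequence_length_bp"
        )
    chosen = np.sort(rng.choice(segregating, size=n_snps, replace=False))
    haps = np.empty((n_haplotypes, n_snps), dtype=np.int8)
    chosen_set = {int(c): j for j, c in enumerate(chosen)}
    for i, v in enumerate(ts.variants()):
        j = chosen_set.get(i)
        if j is not None:
            haps[:, j] = v.genotypes
    return haps


def simulate_founder_haplotypes(
    model: FounderModel, n_haplotypes: int, seed: int
) -> tuple[HaplotypePool, GeneticMap]:
    """Founder haplotype pool plus a uniform genetic map.

    In coalescent mode the haplotypes at ``n_snps`` segregating sites
    (sampled uniformly, no MAF filter) are taken directly from the sequence
    simulation, preserving the site-frequency spectrum and LD.  In sfs mode
    per-SNP frequencies come from the calibrated Beta distribution (or a
    point mass) and alleles are drawn independently per site.
    """
    rng = np.random.default_rng(seed)
    if model.mode == "coalescent":
        haps = _coalescent_haplotypes(model, n_haplotypes, model.n_snps, rng)
    else:
        if model.sfs_point_frequency is not None:
            freqs = np.full(model.n_snps, model.sfs_point_frequency)
        else:
            b = model.sfs_beta_shape
            freqs = rng.beta(b, b, size=model.n_snps)
            # keep targets attainable in a finite pool
            freqs = np.clip(
                freqs, 1.0 / (2 * n_haplotypes), 1 - 1.0 / (2 * n_haplotypes)
            )
        haps = (rng.random((n_haplotypes, model.n_snps)) < freqs).astype(np.int8)
        # Re-draw any SNP fixed in the finite pool so every SNP segregates.
        for _ in range(1000):
            colsum = haps.sum(axis=0)
            bad = np.flatnonzero((colsum == 0) | (colsum == n_haplotypes))
            if bad.size == 0:
                break
            haps[:, bad] = rng.random((n_haplotypes, bad.size)) < freqs[bad]
        else:  # pragma: no cover - pathological frequencies only
            raise RuntimeError("could not obtain segregating SNPs in the pool")

    positions = np.sort(rng.uniform(0.0, model.chromosome_length_cM, model.n_snps))
    width = max(4, len(str(model.n_snps)))
    gmap = GeneticMap(
        [f"snp{i:0{width}d}" for i in range(model.n_snps)],
        positions,
        model.chromosome_length_cM,
    )
    return HaplotypePool(haps), gmap


# ---------------------------------------------------------------------------
# gene dropping


def _meiosis(
    rng: np.random.Generator,
    gametes: np.ndarray,  # (2, n_snps) parental gametes
    positions: np.ndarray,
    length_cM: float,
) -> tuple[np.ndarray, int, np.ndarray]:
    """One transmitted gamete under Haldane's model (Poisson crossovers).

    Returns (gamete, start_strand, crossover_positions).
    """
    n_x = rng.poisson(length_cM / 100.0)
    xpos = np.sort(rng.uniform(0.0, length_cM, n_x))
    start = int(rng.integers(2))
    # strand at a SNP flips at every crossover to its left
    strand = (start + np.searchsorted(xpos, positions)) % 2
    return gametes[strand, np.arange(positions.size)], start, xpos


def gene_drop(
    ped: Pedigree, pool: HaplotypePool, gmap: GeneticMap, seed: int
) -> TrueGenotypes:
    """Drop founder haplotypes through the pedigree with recombination.

    Founders receive two pool haplotypes (without replacement while the pool
    lasts, then with replacement); every non-founder receives one
    recombinant gamete per parent.  An unknown parent contributes a fresh
    pool haplotype (a draw from the base population).
    """
    if len(gmap) == 0:
        raise ValueError("empty genetic map")
    if len(gmap) != pool.n_snps:
        raise ValueError("map and haplotype pool disagree on SNP count")
    rng = np.random.default_rng(seed)
    n = len(ped)
    m = pool.n_snps
    positions = gmap.positions_cM
    length = gmap.chromosome_length_cM

    perm = list(rng.permutation(pool.n_haplotypes))

    def draw_pool_haplotype() -> np.ndarray:
        if perm:
            return pool.haplotypes[perm.pop()]
        return pool.haplotypes[rng.integers(pool.n_haplotypes)]

    gametes = np.zeros((n, 2, m), dtype=np.int8)
    crossovers: dict[tuple[str, int], tuple[int, np.ndarray]] = {}
    sire_pos, dam_pos = ped.parent_positions()
    for k, ind in enumerate(ped.individuals):
        for side, parent in ((0, sire_pos[k]), (1, dam_pos[k])):
            if parent < 0:
                gametes[k, side] = draw_pool_haplotype()
            else:
                gam, start, xpos = _meiosis(rng, gametes[parent], positions, length)
                gametes[k, side] = gam
                crossovers[(ind.id, side)] = (start, xpos)
    return TrueGenotypes(
        ids=ped.ids,
        codes=gametes.sum(axis=1),
        gametes=gametes,
        crossovers=crossovers,
    )


# ---------------------------------------------------------------------------
# scenario masking


def apply_scenario(true_g: GenotypeMatrix, spec: ScenarioSpec) -> GenotypeMatrix:
    """Mask everyone outside the scenario's genotyped set to missing."""
    unknown = (spec.genotyped_ids | spec.test_ids) - set(true_g.ids)
    if unknown:
        raise ValueError(f"scenario ids not in genotype matrix: {sorted(unknown)[:5]}")
    obs = true_g.codes.copy()
    keep = np.zeros(len(true_g.ids), dtype=bool)
    if spec.genotyped_ids:
        keep[true_g.positions(sorted(spec.genotyped_ids))] = True
    obs[~keep] = MISSING
    return GenotypeMatrix(list(true_g.ids), obs)
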