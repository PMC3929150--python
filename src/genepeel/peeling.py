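"""Single-locus segregation-analysis imputation (iterative peeling).

Every ungenotyped individual receives, per SNP, a genotype probability
triplet computed from pedigree transmission and the observed genotypes of
relatives only — no linkage, LD or haplotype information.  The algorithm is
anterior/posterior message passing on the pedigree's mating graph:

* the *anterior* carries ancestral information down to an individual,
* the *posterior* of one mating carries descendant information back up to a
  parent, always excluding that mating's own contribution,
* founders (and unknown parents, materialized as phantom founders) start
  from a Hardy-Weinberg prior at the reference allele frequency,
* the penetrance is an indicator of the observed genotype (uninformative if
  missing).

All quantities are iterated to a fixpoint, which is exact on loop-free
pedigrees and the standard approximation on looped ones.  A deterministic
Mendelian rule pass (homozygous parents and offspring force alleles) runs
first, both as a fast fill-in and as a consistency check on the observed
data.

Dosage = p1 + 2*p2 is the expected gene content of the triplet and is the
quantity scored by the accuracy metrics; hard genotype calls are made only
when the top probability reaches the calling threshold, otherwise the
genotype is reported as not imputed (code 9) while the dosage is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pedigree import Pedigree
from .simulate import MISSING, GenotypeMatrix

__all__ = [
    "PeelingOptions",
    "GenotypeProbabilities",
    "ImputationResult",
    "MendelianConflictError",
    "PeelingWarning",
    "TRANSMISSION",
    "transmission_probability",
    "estimate_allele_frequency",
    "mendelian_rules_fill",
    "peel_locus",
    "peel_all",
    "impute_all",
]


class MendelianConflictError(ValueError):
    """Observed genotypes are impossible under Mendelian inheritance."""


class PeelingWarning(UserWarning):
    """Non-fatal peeling diagnostics (e.g. non-convergence)."""


def _transmission_tensor() -> np.ndarray:
    """T[gs, gd, go] = P(offspring go | sire gs, dam gd), single locus."""
    t = np.array([0.0, 0.5, 1.0])  # P(parent transmits allele 1 | genotype)
    T = np.zeros((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            ps, pd = t[gs], t[gd]
            T[gs, gd, 0] = (1 - ps) * (1 - pd)
            T[gs, gd, 1] = ps * (1 - pd) + (1 - ps) * pd
            T[gs, gd, 2] = ps * pd
    return T


TRANSMISSION = _transmission_tensor()
TRANSMISSION.setflags(write=False)


def transmission_probability(g_off: int, g_sire: int, g_dam: int) -> float:
    """Mendelian single-locus transmission probability P(g_off | g_sire, g_dam)."""
    for g in (g_off, g_sire, g_dam):
        if g not in (0, 1, 2):
            raise ValueError(f"genotype codes must be 0, 1 or 2 (got {g})")
    return float(TRANSMISSION[g_sire, g_dam, g_off])


@dataclass(frozen=True)
class PeelingOptions:
    """Tunable knobs of the peeling run.

    call_threshold
        Minimum posterior probability for a hard genotype call; below it the
        genotype is reported as not imputed (the dosage is always kept).
    max_rounds / tolerance
        Fixpoint iteration control; tolerance is the maximum absolute change
        of any stored probability between rounds.
    frequency_clamp
        Minimum allele frequency for the founder prior; ``None`` means
        1/(2*n_reference + 2), so a SNP fixed in a finite reference never
        zeroes out genotypes elsewhere.
    """

    call_threshold: float = 0.98
    max_rounds: int = 30
    tolerance: float = 1e-6
    frequency_clamp: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1.0 / 3.0 < self.call_threshold <= 1.0):
            raise ValueError("call_threshold must be in (1/3, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class GenotypeProbabilities:
    """Per individual x SNP probability triplets (p0, p1, p2)."""

    ids: list[str]
    probs: np.ndarray  # (n, n_snps, 3)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self._pos = {i: k for k, i in enumerate(self.ids)}

    @property
    def dosages(self) -> np.ndarray:
        """Expected gene content in [0, 2]: p1 + 2*p2, per individual x SNP."""
        return self.probs[..., 1] + 2.0 * self.probs[..., 2]

    def row(self, ind_id: str) -> np.ndarray:
        return self.probs[self._pos[ind_id]]

    def dosage_row(self, ind_id: str) -> np.ndarray:
        p = self.row(ind_id)
        return p[:, 1] + 2.0 * p[:, 2]

    def write_dosages(self, path: str | Path) -> None:
        dos = self.dosages
        with open(path, "w") as fh:
            for ind_id, row in zip(self.ids, dos):
                fh.write(ind_id + " " + " ".join(f"{d:.4f}" for d in row) + "\n")


@dataclass
class ImputationResult:
    """Peeling output: probabilities, hard calls (9 = not imputed), frequencies."""

    probabilities: GenotypeProbabilities
    called: GenotypeMatrix
    frequencies: np.ndarray


# ---------------------------------------------------------------------------
# allele frequency


def estimate_allele_frequency(
    obs: GenotypeMatrix,
    reference: Sequence[str],
    clamp: Optional[float] = None,
) -> np.ndarray:
    """Per-SNP frequency of allele 1 from the reference rows, clamped.

    Frequency = mean observed code / 2 over reference individuals with an
    observed genotype at the SNP; clamped into [clamp, 1 - clamp] with the
    default clamp 1/(2*n_reference + 2).
    """
    reference = list(reference)
    if not reference:
        raise ValueError("reference set is empty")
    rows = obs.codes[obs.positions(reference)]
    known = rows != MISSING
    counts = known.sum(axis=0)
    if np.any(counts == 0):
        j = int(np.argmax(counts == 0))
        raise ValueError(f"no observed reference genotype at SNP index {j}")
    freq = (rows * known).sum(axis=0) / (2.0 * counts)
    if clamp is None:
        clamp = 1.0 / (2.0 * len(reference) + 2.0)
    return np.clip(freq, clamp, 1.0 - clamp)


# ---------------------------------------------------------------------------
# deterministic Mendelian rules


def _aligned_codes(ped: Pedigree, obs: GenotypeMatrix) -> np.ndarray:
    """Observed codes reindexed to pedigree order (absent rows all-missing)."""
    codes = np.full((len(ped), obs.n_snps), MISSING, dtype=np.int8)
    for k, ind_id in enumerate(ped.ids):
        if ind_id in obs._pos:
            codes[k] = obs.row(ind_id)
    return codes


def mendelian_rules_fill(ped: Pedigree, obs: GenotypeMatrix) -> GenotypeMatrix:
    """Fixpoint of the deterministic fill-in rules, in pedigree order.

    Rules: a homozygous parent forces one allele in each offspring (both
    homozygous parents force the genotype); an offspring homozygous for an
    allele forces one copy of it in each parent.  A genotype is written only
    when both alleles are forced.  Inconsistent observations raise
    :class:`MendelianConflictError` naming a trio involved.
    """
    n = len(ped)
    m = obs.n_snps
    codes = _aligned_codes(ped, obs)
    known = codes != MISSING

    # Bounds on the number of copies of allele 1; virtual row n = unknown parent.
    lo = np.zeros((n + 1, m), dtype=np.int8)
    hi = np.full((n + 1, m), 2, dtype=np.int8)
    lo[:n][known] = codes[known]
    hi[:n][known] = codes[known]

    sire_pos, dam_pos = ped.parent_positions()
    sidx = np.array([s if s >= 0 else n for s in sire_pos])
    didx = np.array([d if d >= 0 else n for d in dam_pos])

    def conflict_check() -> None:
        bad = np.flatnonzero((lo[:n] > hi[:n]).any(axis=1))
        if not bad.size:
            return
        k = int(bad[0])
        j = int(np.argmax(lo[k] > hi[k]))
        ind = ped.individuals[k]
        if sire_pos[k] < 0 and dam_pos[k] < 0:
            # the violated bound came from offspring: name a trio below
            for c in range(n):
                if sire_pos[c] == k or dam_pos[c] == k:
                    ind = ped.individuals[c]
                    break
        raise MendelianConflictError(
            f"Mendelian conflict at SNP index {j} in trio "
            f"(individual {ind.id!r}, sire {ind.sire_id!r}, "
            f"dam {ind.dam_id!r})"
        )

    while True:
        lo_prev = lo.copy()
        hi_prev = hi.copy()
        # parents -> offspring
        np.maximum(lo[:n], (lo[sidx] == 2).astype(np.int8) + (lo[didx] == 2), out=lo[:n])
        np.minimum(hi[:n], 2 - (hi[sidx] == 0).astype(np.int8) - (hi[didx] == 0), out=hi[:n])
        # offspring -> parents: a homozygous offspring forces one allele
        has1 = np.zeros((n + 1, m), dtype=np.int8)
        has0 = np.zeros((n + 1, m), dtype=np.int8)
        child_hom1 = (lo[:n] == 2).astype(np.int8)
        child_hom0 = (hi[:n] == 0).astype(np.int8)
        for idx in (sidx, didx):
            np.maximum.at(has1, idx, child_hom1)
            np.maximum.at(has0, idx, child_hom0)
        np.maximum(lo[:n], has1[:n], out=lo[:n])
        np.minimum(hi[:n], 2 - has0[:n], out=hi[:n])
        lo[n] = 0
        hi[n] = 2
        conflict_check()
        if np.array_equal(lo, lo_prev) and np.array_equal(hi, hi_prev):
            break

    filled = np.where(lo[:n] == hi[:n], lo[:n], MISSING).astype(np.int8)
    return GenotypeMatrix(ped.ids, filled)


# ---------------------------------------------------------------------------
# iterative peeling


class _PeelGraph:
    """Pedigree restructured as matings, with phantom founders for unknown
    parents of individuals that have one recorded parent."""

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.n_real = len(ped)
        sire_pos, dam_pos = ped.parent_positions()
        sire = list(sire_pos)
        dam = list(dam_pos)
        n = self.n_real
        # Phantom founders: unknown parents of individuals with one recorded
        # parent get their own (unrelated) phantom.
        for k in range(self.n_real):
            if sire[k] < 0 and dam[k] >= 0:
                sire[k] = n
                n += 1
            elif dam[k] < 0 and sire[k] >= 0:
                dam[k] = n
                n += 1
        self.n_total = n
        self.sire = sire
        self.dam = dam

        mating_index: dict[tuple[int, int], int] = {}
        self.mating_sire: list[int] = []
        self.mating_dam: list[int] = []
        self.mating_offspring: list[list[int]] = []
        self.child_mating = np.full(self.n_total, -1, dtype=int)
        self.parent_matings: list[list[tuple[int, int]]] = [
            [] for _ in range(self.n_total)
        ]
        for k in range(self.n_real):
            s, d = sire[k], dam[k]
            if s < 0 and d < 0:
                continue  # founder
            key = (s, d)
            m = mating_index.get(key)
            if m is None:
                m = len(self.mating_sire)
                mating_index[key] = m
                self.mating_sire.append(s)
                self.mating_dam.append(d)
                self.mating_offspring.append([])
                self.parent_matings[s].append((m, 0))
                self.parent_matings[d].append((m, 1))
            self.mating_offspring[m].append(k)
            self.child_mating[k] = m
        self.n_matings = len(self.mating_sire)
        # Topological order: by first offspring position (parents precede
        # offspring in pedigree order, so parents' anteriors are ready).
        self.order = sorted(
            range(self.n_matings), key=lambda m: min(self.mating_offspring[m])
        )


def _log_nz(x: np.ndarray) -> np.ndarray:
    return np.log(np.where(x > 0, x, 1.0))


def _exp_norm(logv: np.ndarray, zeros: np.ndarray) -> np.ndarray:
    """exp(logv) zeroed where zeros>0, scaled to unit sum over the last axis."""
    live = zeros == 0
    lv = np.where(live, logv, -np.inf)
    mx = lv.max(axis=-1, keepdims=True)
    out = np.exp(lv - np.where(np.isfinite(mx), mx, 0.0))
    out[~live] = 0.0
    total = out.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise MendelianConflictError(
            "all genotype states excluded during peeling: observed genotypes "
            "are inconsistent with the pedigree"
        )
    return out / total


def _hwe_prior(freq: np.ndarray) -> np.ndarray:
    p = np.asarray(freq, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def peel_all(
    ped: Pedigree,
    obs_codes: np.ndarray,
    freq: np.ndarray,
    opts: PeelingOptions = PeelingOptions(),
) -> np.ndarray:
    """Iterative peeling for all SNP columns at once.

    Parameters
    ----------
    obs_codes : (n_individuals, n_snps) int codes in pedigree order
    freq : (n_snps,) reference allele-1 frequency, strictly inside (0, 1)

    Returns
    -------
    (n_individuals, n_snps, 3) genotype probability triplets.
    """
    freq = np.atleast_1d(np.asarray(freq, dtype=float))
    if np.any((freq <= 0) | (freq >= 1)):
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    graph = _PeelGraph(ped)
    n, N = graph.n_real, graph.n_total
    m = obs_codes.shape[1]
    K = graph.n_matings
    T = TRANSMISSION

    pen = np.ones((N, m, 3))
    codes = np.asarray(obs_codes)
    observed = codes != MISSING
    kk, jj = np.nonzero(observed)
    pen[kk, jj, :] = 0.0
    pen[kk, jj, codes[kk, jj]] = 1.0

    prior = _hwe_prior(freq)  # (m, 3)
    ant = np.broadcast_to(prior, (N, m, 3)).copy()
    post = np.full((K, 2, m, 3), 1.0 / 3.0)

    if K == 0:
        prod = ant[:n] * pen[:n]
        return _exp_norm(_log_nz(prod), (prod == 0).astype(np.int16))

    def posts_logsum() -> tuple[np.ndarray, np.ndarray]:
        """Per individual: log penetrance + sum of log posterior factors."""
        s = _log_nz(pen).copy()
        z = (pen == 0).astype(np.int16)
        for i in range(N):
            for mm, side in graph.parent_matings[i]:
                p = post[mm, side]
                s[i] += _log_nz(p)
                z[i] += p == 0
        return s, z

    delta = np.inf
    for _round in range(opts.max_rounds):
        delta = 0.0
        # Log-sums are rebuilt each round and maintained incrementally when a
        # posterior is replaced, so exclusions stay exact within a sweep.
        s, z = posts_logsum()

        def child_term(j: int) -> np.ndarray:
            """W_j[gs, gd]: offspring j's evidence given the parent pair."""
            R_j = _exp_norm(s[j], z[j])
            return np.einsum("sdg,mg->msd", T, R_j)

        def parent_dist(i: int, mm: int, side: int) -> np.ndarray:
            """ant x pen x posterior product excluding mating mm's posterior."""
            p = post[mm, side]
            s_i = s[i] - _log_nz(p) + _log_nz(ant[i])
            z_i = z[i] - (p == 0) + (ant[i] == 0)
            return _exp_norm(s_i, z_i)

        # downward: anteriors, parents before offspring
        for mm in graph.order:
            sp, dp = graph.mating_sire[mm], graph.mating_dam[mm]
            A_s = parent_dist(sp, mm, 0)
            A_d = parent_dist(dp, mm, 1)
            offspring = graph.mating_offspring[mm]
            W = [child_term(j) for j in offspring]
            base = A_s[:, :, None] * A_d[:, None, :]
            for idx, i in enumerate(offspring):
                P = base.copy()
                for jdx, Wj in enumerate(W):
                    if jdx != idx:
                        P *= Wj
                new = np.einsum("sdg,msd->mg", T, P)
                total = new.sum(axis=-1, keepdims=True)
                if np.any(total == 0):
                    raise MendelianConflictError(
                        "zero anterior during peeling: inconsistent genotypes"
                    )
                new /= total
                delta = max(delta, float(np.abs(new - ant[i]).max()))
                ant[i] = new
        # upward: posteriors, offspring matings before ancestral ones
        for mm in reversed(graph.order):
            sp, dp = graph.mating_sire[mm], graph.mating_dam[mm]
            A_s = parent_dist(sp, mm, 0)
            A_d = parent_dist(dp, mm, 1)
            prodW = np.ones((m, 3, 3))
            for j in graph.mating_offspring[mm]:
                prodW *= child_term(j)
            for side, parent, A_other in ((0, sp, A_d), (1, dp, A_s)):
                new = (
                    (A_other[:, None, :] * prodW).sum(axis=2)
                    if side == 0
                    else (A_other[:, :, None] * prodW).sum(axis=1)
                )
                total = new.sum(axis=-1, keepdims=True)
                if np.any(total == 0):
                    raise MendelianConflictError(
                        "zero posterior during peeling: inconsistent genotypes"
                    )
                new /= total
                old = post[mm, side]
                delta = max(delta, float(np.abs(new - old).max()))
                # keep the parent's log-sum consistent with the new factor
                s[parent] += _log_nz(new) - _log_nz(old)
                z[parent] += (new == 0).astype(np.int16) - (old == 0)
                post[mm, side] = new
        if delta < opts.tolerance:
            break
    else:
        warnings.warn(
            f"peeling did not converge in {opts.max_rounds} rounds "
            f"(last max change {delta:.2e})",
            PeelingWarning,
            stacklevel=2,
        )

    s, z = posts_logsum()
    s += _log_nz(ant)
    z += (ant == 0).astype(np.int16)
    return _exp_norm(s, z)[:n]


def peel_locus(
    ped: Pedigree,
    column: Sequence[int],
    freq: float,
    opts: PeelingOptions = PeelingOptions(),
) -> np.ndarray:
    """Peel a single SNP: per-individual probability triplets, shape (n, 3)."""
    column = np.asarray(column, dtype=np.int8).reshape(-1, 1)
    if column.shape[0] != len(ped):
        raise ValueError("column length does not match pedigree size")
    return peel_all(ped, column, np.array([freq]), opts)[:, 0, :]


# ---------------------------------------------------------------------------
# full imputation


def impute_all(
    ped: Pedigree,
    obs: GenotypeMatrix,
    opts: PeelingOptions = PeelingOptions(),
    reference: Optional[Sequence[str]] = None,
) -> ImputationResult:
    """Mendelian fill, then per-SNP peeling, then thresholded calling.

    ``reference`` defaults to every individual with at least one observed
    genotype; it is used only for the allele-frequency estimate feeding the
    founder priors.
    """
    if reference is None:
        any_obs = (obs.codes != MISSING).any(axis=1)
        reference = [i for i, keep in zip(obs.ids, any_obs) if keep]
    freq = estimate_allele_frequency(obs, reference, opts.frequency_clamp)
    filled = mendelian_rules_fill(ped, obs)
    probs = peel_all(ped, filled.codes, freq, opts)

    top = probs.max(axis=-1)
    arg = probs.argmax(axis=-1).astype(np.int8)
    # ties are never callable: a tied maximum is at most 1/2 < threshold
    runner_up = np.partition(probs, 1, axis=-1)[..., 1]
    callable_ = (top >= opts.call_threshold) & (top > runner_up)
    called = np.where(callable_, arg, MISSING).astype(np.int8)

    return ImputationResult(
        probabilities=GenotypeProbabilities(ped.ids, probs),
        called=GenotypeMatrix(ped.ids, called),
        frequencies=freq,
    )
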