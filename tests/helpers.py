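"""Independent oracles and generators shared by the test modules.

Everything here is deliberately written by a different route than the
package code it checks: the relationship matrix uses the tabular method
instead of recursive kinship, and genotype marginals come from explicit
enumeration of all genotype configurations instead of message passing.
"""

import itertools

import numpy as np

from genepeel.pedigree import UNKNOWN, Individual, Pedigree
from genepeel.peeling import MISSING, TRANSMISSION


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method."""
    n = len(ped)
    sire, dam = ped.parent_positions()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


def brute_force_marginals(ped: Pedigree, column, freq: float) -> np.ndarray:
    """Exact genotype marginals by enumerating all 3^n configurations.

    Joint probability = founder Hardy-Weinberg priors x Mendelian
    transmissions x observation indicators; individuals with one unknown
    parent marginalize over an implicit unrelated founder.
    """
    n = len(ped)
    sire, dam = ped.parent_positions()
    p = freq
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    half = np.zeros((3, 3))  # P(child | one known parent), other ~ HWE
    for gp in range(3):
        for g in range(3):
            half[gp, g] = sum(
                hwe[u] * TRANSMISSION[gp, u, g] for u in range(3)
            )
    marg = np.zeros((n, 3))
    for cfg in itertools.product(range(3), repeat=n):
        pr = 1.0
        for k in range(n):
            g = cfg[k]
            if column[k] != MISSING and column[k] != g:
                pr = 0.0
                break
            s, d = sire[k], dam[k]
            if s < 0 and d < 0:
                pr *= hwe[g]
            elif s >= 0 and d >= 0:
                pr *= TRANSMISSION[cfg[s], cfg[d], g]
            else:
                pr *= half[cfg[s] if s >= 0 else cfg[d], g]
        if pr:
            for k in range(n):
                marg[k, cfg[k]] += pr
    total = marg.sum(axis=1, keepdims=True)
    return marg / total


def random_tree_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random pedigree whose mating graph is loop-free.

    New individuals take parents from different connected components (or
    unknown), so no marriage-graph cycle can arise; re-using an existing
    couple (full sibs) keeps the graph a tree and is allowed implicitly when
    the dam is unknown.
    """
    inds: list[Individual] = []
    component: dict[str, int] = {}
    next_label = itertools.count()
    for k in range(n):
        iid = f"i{k}"
        ids = [i.id for i in inds]
        if not ids or rng.random() < 0.35:
            inds.append(Individual(iid))
            component[iid] = next(next_label)
            continue
        s = ids[rng.integers(len(ids))]
        others = [c for c in ids if component[c] != component[s]]
        d = others[rng.integers(len(others))] if others and rng.random() < 0.8 else UNKNOWN
        inds.append(Individual(iid, s, d))
        label = component[s]
        if d != UNKNOWN:
            old = component[d]
            for key, val in component.items():
                if val == old:
                    component[key] = label
        component[iid] = label
    return Pedigree(inds)


def sample_single_locus(
    rng: np.random.Generator, ped: Pedigree, p: float
) -> np.ndarray:
    """Consistent genotypes for one locus by Mendelian sampling."""
    sire, dam = ped.parent_positions()
    g = np.zeros(len(ped), dtype=np.int8)

    def gamete(parent: int) -> int:
        if parent < 0:
            return int(rng.random() < p)
        gp = g[parent]
        if gp == 1:
            return int(rng.random() < 0.5)
        return int(gp == 2)

    for k in range(len(ped)):
        g[k] = gamete(sire[k]) + gamete(dam[k])
    return g
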