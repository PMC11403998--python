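"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from numt_atlas.config import ScoringScheme
from numt_atlas.synthio import SpeciesTreeSpec, default_tree


def brute_force_affine_sw(a: str, b: str, sc: ScoringScheme) -> int:
    """Independent affine-gap local alignment oracle (plain Gotoh, lists).

    Deliberately a separate implementation from the package's aligner:
    row-by-row python lists, no numba, gap of length k costs open + k*ext.
    """
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    open_cost = sc.gap_open + sc.gap_extend
    H_prev = [0] * (m + 1)
    F_prev = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        H_cur = [0] * (m + 1)
        F_cur = [NEG] * (m + 1)
        E = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            E = max(E - sc.gap_extend, H_cur[j - 1] - open_cost)
            F_cur[j] = max(F_prev[j] - sc.gap_extend, H_prev[j] - open_cost)
            sub = sc.match if ai == b[j - 1] else -sc.mismatch
            h = max(0, H_prev[j - 1] + sub, E, F_cur[j])
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, F_prev = H_cur, F_cur
    return best


def plant_guarded(rng: np.random.Generator, mt: str, qs: int, qe: int,
                  flank: int = 300, guard: int = 25) -> str:
    """Embed mt[qs:qe] in random flanks that cannot extend the alignment.

    The ``guard`` flank positions adjacent to the copy are forced to
    mismatch the continuation of the mtDNA on the extension diagonal, so
    the optimal local alignment is exactly the planted copy.
    """
    left = list(random_dna(rng, flank))
    right = list(random_dna(rng, flank))
    for k in range(1, min(guard, qs, flank) + 1):
        bad = mt[qs - k]
        if left[-k] == bad:
            left[-k] = "ACGT"[("ACGT".index(bad) + 1) % 4]
    for k in range(min(guard, len(mt) - qe, flank)):
        bad = mt[qe + k]
        if right[k] == bad:
            right[k] = "ACGT"[("ACGT".index(bad) + 1) % 4]
    return "".join(left) + mt[qs:qe] + "".join(right)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("AGCT"[i] for i in rng.choice(4, size=length, p=probs))


@pytest.fixture
def scoring() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture
def tree() -> SpeciesTreeSpec:
    return default_tree()


@pytest.fixture
def two_species_tree():
    def make(T: float, mito_rate: float = 2e-8, kappa: float = 4.0,
             mt_length: int = 16_600) -> SpeciesTreeSpec:
        return SpeciesTreeSpec(
            newick_topology="(A,B)root;",
            divergence_times={"root": T},
            mito_rate=mito_rate,
            kappa=kappa,
            mt_length=mt_length,
        )
    return make


@pytest.fixture(scope="session")
def outgroup_tree():
    """Five-taxon tree whose root (75 Mya) predates the bovid split."""
    return SpeciesTreeSpec(
        newick_topology=(
            "((((scrofa,cebifrons)sus,warthog)suinae,bovid)suiform,outgroup)"
            "root;"
        ),
        divergence_times={"sus": 3.5, "suinae": 10.0, "suiform": 55.0,
                          "root": 75.0},
        mito_rate=1e-8,
        nuclear_rate=2.2e-9,
    )
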