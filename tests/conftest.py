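"""Shared fixtures: pedigrees, expensive simulations, random generators."""

from __future__ import annotations

import numpy as np
import pytest

import ibd2loc as ib

# Monte-Carlo study conditions used by the stochastic-agreement tests:
# 200 000 replicates, fixed seeds, agreement asserted within 4 binomial SE.
N_DROPS = 200_000


def fixture_pair(name, *params):
    ped, (a, b) = ib.make_fixture(name, *params)
    return ped, a, b


@pytest.fixture(scope="session")
def halfsib():
    return ib.make_fixture("half_sibs")


@pytest.fixture(scope="session")
def halfsib_inbred():
    ped, pair = ib.make_fixture("half_sibs")
    return ib.Fixture(ib.set_founder_inbreeding(ped, "2", 1.0), pair)


@pytest.fixture(scope="session")
def drop_halfsib():
    ped, (a, b) = ib.make_fixture("half_sibs")
    return ped, a, b, ib.gene_drop(ped, a, b, rho=0.2, n=N_DROPS, seed=2026)


@pytest.fixture(scope="session")
def drop_fullsibs():
    ped, (a, b) = ib.make_fixture("full_sibs")
    return ped, a, b, ib.gene_drop(ped, a, b, rho=0.2, n=N_DROPS, seed=2027)


@pytest.fixture(scope="session")
def drop_qhfc():
    ped, (a, b) = ib.make_fixture("quad_half_first_cousins")
    return ped, a, b, ib.gene_drop(ped, a, b, rho=0.2, n=N_DROPS, seed=2028)


@pytest.fixture(scope="session")
def drop_sibmating():
    ped, (a, b) = ib.make_fixture("sib_mating_sibs", 1)
    return ped, a, b, ib.gene_drop(ped, a, b, rho=0.2, n=N_DROPS, seed=2029)


@pytest.fixture(scope="session")
def halfsib_k1_sims():
    """Realized half-sib sharing fractions on a 1-Morgan chromosome."""
    return ib.simulate_halfsib_k1(L=1.0, n=50_000, seed=2030)


def assert_within_se(empirical, exact, n, factor=4.0):
    """Assert |empirical - exact| <= factor * binomial SE, element-wise."""
    empirical = np.asarray(empirical, dtype=float)
    exact = np.asarray(exact, dtype=float)
    se = np.sqrt(exact * (1.0 - exact) / n)
    tol = factor * se + 1e-12  # exact-zero cells must match exactly
    assert np.all(np.abs(empirical - exact) <= tol), (
        f"max deviation {np.abs(empirical - exact).max()} vs tol {tol.max()}"
    )


def random_pedigree(rng: np.random.Generator, max_members: int = 9) -> ib.Pedigree:
    """Small random pedigree: founders first, then children of random pairs
    (selfing allowed occasionally)."""
    n_founders = int(rng.integers(2, 4))
    rows = [(str(i + 1), None, None) for i in range(n_founders)]
    ids = [r[0] for r in rows]
    n_extra = int(rng.integers(1, max_members - n_founders + 1))
    for k in range(n_extra):
        child = str(n_founders + k + 1)
        fa = ids[int(rng.integers(0, len(ids)))]
        mo = ids[int(rng.integers(0, len(ids)))]  # may equal fa: selfing
        rows.append((child, fa, mo))
        ids.append(child)
    return ib.Pedigree(rows)


def random_locus_pattern(rng: np.random.Generator, ped: ib.Pedigree, max_blocks=3):
    """Random single-locus pattern over random members with random labels."""
    members = list(ped.members)
    blocks = []
    used = set()
    for _ in range(int(rng.integers(1, max_blocks + 1))):
        size = int(rng.integers(1, 3))
        block = []
        for _ in range(size):
            ind = members[int(rng.integers(0, len(members)))]
            lab = int(rng.integers(1, 3))
            if (ind, lab) not in used:
                used.add((ind, lab))
                block.append((ind, lab))
        if block:
            blocks.append(block)
    if not blocks:
        blocks = [[(members[0], 1)]]
    return blocks
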