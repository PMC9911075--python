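"""Monte-Carlo gene dropping at two linked loci.

This simulator realizes the probability model under which the coefficients
are defined, with no shared code with the recursion engine: founders receive
unique ancestral alleles (one allele class when completely inbred), each
meiosis picks a parental haplotype at locus 1 uniformly and switches
haplotype at locus 2 with probability rho, and the condensed identity state
of the target pair is tallied at both loci.  It is the package's independent
stochastic oracle.

A second, continuous-genome simulator realizes half-sib IBD sharing along a
chromosome under a Poisson crossover process, for checking realized-
relatedness variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnsupportedFounderInbreedingError
from .pedigree import Pedigree
from .single import C_SETS

# detailed state (1..15) from the restricted-growth code of the partition of
# the ordered alleles (a-paternal, a-maternal, b-paternal, b-maternal)
def _init_state_table() -> np.ndarray:
    patterns = {
        (0, 0, 0, 0): 1, (0, 0, 0, 1): 2, (0, 0, 1, 0): 3, (0, 1, 0, 0): 4,
        (0, 1, 1, 1): 5, (0, 0, 1, 1): 6, (0, 0, 1, 2): 7, (0, 1, 2, 2): 8,
        (0, 1, 0, 1): 9, (0, 1, 0, 2): 10, (0, 1, 2, 1): 11, (0, 1, 1, 0): 12,
        (0, 1, 2, 0): 13, (0, 1, 1, 2): 14, (0, 1, 2, 3): 15,
    }
    table = np.zeros((2, 3, 4), dtype=np.int8)
    for (c0, c1, c2, c3), state in patterns.items():
        table[c1, c2, c3] = state
    return table


_STATE_TABLE = _init_state_table()

_DETAILED_TO_CONDENSED = np.zeros(16, dtype=np.int8)
for _cond, _dets in C_SETS.items():
    for _r in _dets:
        _DETAILED_TO_CONDENSED[_r] = _cond


def _detailed_states(ap, am, bp, bm) -> np.ndarray:
    """Vectorized detailed identity state (1..15) of ordered allele arrays."""
    c1 = (am != ap).astype(np.int8)
    c2 = np.where(bp == ap, 0, np.where(bp == am, c1, c1 + 1)).astype(np.int8)
    c3 = np.where(
        bm == ap, 0, np.where(bm == am, c1, np.where(bm == bp, c2, np.maximum(c1, c2) + 1))
    ).astype(np.int8)
    return _STATE_TABLE[c1, c2, c3]


@dataclass(frozen=True)
class SimResult:
    """Tallies of a two-locus gene-drop run.

    Frequencies are relative; standard errors are binomial,
    sqrt(p (1 - p) / n).
    """

    n: int
    seed: int
    empirical_D: np.ndarray  # 9x9 joint condensed-state frequencies
    empirical_K: np.ndarray | None  # 3x3 joint IBD-count frequencies, noninbred pairs
    empirical_delta: np.ndarray  # (9,) single-locus condensed frequencies (locus 1)
    empirical_detailed: np.ndarray  # (15,) single-locus detailed frequencies (locus 1)

    def se(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return np.sqrt(p * (1.0 - p) / self.n)


def gene_drop(ped: Pedigree, a, b, rho: float, n: int, seed: int) -> SimResult:
    """Simulate ``n`` independent two-locus gene drops and tally the joint
    condensed identity states of the pair ``(a, b)``."""
    if not 0 <= rho <= 0.5:
        raise ValueError(f"recombination fraction must lie in [0, 0.5], got {rho}")
    if n < 1:
        raise ValueError("need at least one replicate")
    for f in ped.founders:
        if 0 < ped.founder_inbreeding(f) < 1:
            raise UnsupportedFounderInbreedingError(
                f"gene dropping supports founder inbreeding 0 or 1 only "
                f"(founder {f!r})"
            )
    a, b = ped._check(a), ped._check(b)
    rng = np.random.default_rng(seed)

    # haplotypes[iid] = (pat_L1, pat_L2, mat_L1, mat_L2), int32 arrays of len n
    haplo: dict[str, tuple[np.ndarray, ...]] = {}
    next_allele = 0
    for iid in ped._topo:
        if ped.is_founder(iid):
            a1 = np.full(n, next_allele, dtype=np.int32)
            if ped.founder_inbreeding(iid) >= 1:
                a2 = a1
                next_allele += 1
            else:
                a2 = np.full(n, next_allele + 1, dtype=np.int32)
                next_allele += 2
            haplo[iid] = (a1, a1, a2, a2)
        else:
            gametes = []
            for parent in (ped.father(iid), ped.mother(iid)):
                p1, p2, m1, m2 = haplo[parent]
                h1 = rng.integers(0, 2, n)
                h2 = h1 ^ (rng.random(n) < rho)
                gametes.append(np.where(h1 == 0, p1, m1))
                gametes.append(np.where(h2 == 0, p2, m2))
            haplo[iid] = (gametes[0], gametes[1], gametes[2], gametes[3])

    ap1, ap2, am1, am2 = haplo[a]
    bp1, bp2, bm1, bm2 = haplo[b]
    det1 = _detailed_states(ap1, am1, bp1, bm1)
    det2 = _detailed_states(ap2, am2, bp2, bm2)
    cond1 = _DETAILED_TO_CONDENSED[det1]
    cond2 = _DETAILED_TO_CONDENSED[det2]

    joint = np.bincount((cond1 - 1) * 9 + (cond2 - 1), minlength=81)
    D = joint.reshape(9, 9) / n
    delta = np.bincount(cond1 - 1, minlength=9) / n
    detailed = np.bincount(det1 - 1, minlength=15) / n

    K = None
    if not D[:6, :].any() and not D[:, :6].any():
        # noninbred pair: states 7, 8, 9 map to IBD counts 2, 1, 0
        sub = D[6:, 6:]
        K = sub[::-1, ::-1].copy()
    return SimResult(
        n=n, seed=seed, empirical_D=D, empirical_K=K,
        empirical_delta=delta, empirical_detailed=detailed,
    )


def simulate_halfsib_k1(L: float, n: int, seed: int) -> np.ndarray:
    """Realized half-sib IBD-sharing proportions on one chromosome.

    The two gametes a half-sib pair receives from the shared parent are two
    independent meioses; their agreement indicator along the chromosome is a
    telegraph process started at fair coin flip and toggled at the union of
    the two Poisson(1/Morgan) crossover processes, i.e. at rate 2.  Returns
    the ``n`` realized agreement fractions, whose mean is kappa1 = 1/2.
    """
    if L <= 0:
        raise ValueError("chromosome length must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(2.0 * L, size=n)
    start_equal = rng.integers(0, 2, size=n).astype(bool)
    out = np.empty(n)
    for i in range(n):
        k = counts[i]
        if k == 0:
            out[i] = L if start_equal[i] else 0.0
            continue
        pts = np.sort(rng.random(k)) * L
        edges = np.concatenate(([0.0], pts, [L]))
        seg = np.diff(edges)
        state = start_equal[i]
        shared = seg[0::2].sum() if state else seg[1::2].sum()
        out[i] = shared
    return out / L
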