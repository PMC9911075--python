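"""Single-locus kinship and identity coefficients.

Pairwise kinship uses the classic recursion (young member replaced by its
parents), which also serves as an independent cross-check of the generalized
pattern engine.  Detailed identity coefficients delta_1..delta_15 are the
generalized kinship coefficients of the fifteen parental-gamete patterns
J_1..J_15, evaluated by the same recursion engine that powers the two-locus
coefficients (with an empty second locus); condensed coefficients Delta_1..
Delta_9 aggregate them.

Founder inbreeding of any value in [0, 1] is honored at a single locus: a
founder's two alleles coincide with probability (1 + f)/2 when sampled with
replacement, and are IBD with probability f.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InbredPairError, PedigreeError
from .pedigree import Pedigree, extend_with_parents
from .twolocus import _get_engine, _to_internal
from .patterns import LocusPattern, TwoLocusPattern

# Parental-gamete IBD patterns of the detailed identity states.  Slot order:
# 0 = paternal gamete of a, 1 = maternal gamete of a, 2 = paternal gamete of
# b, 3 = maternal gamete of b.
J_PATTERNS: dict[int, tuple[tuple[int, ...], ...]] = {
    1: ((0, 1, 2, 3),),
    2: ((0, 1, 2), (3,)),
    3: ((0, 1, 3), (2,)),
    4: ((0, 2, 3), (1,)),
    5: ((0,), (1, 2, 3)),
    6: ((0, 1), (2, 3)),
    7: ((0, 1), (2,), (3,)),
    8: ((0,), (1,), (2, 3)),
    9: ((0, 2), (1, 3)),
    10: ((0, 2), (1,), (3,)),
    11: ((1, 3), (0,), (2,)),
    12: ((0, 3), (1, 2)),
    13: ((0, 3), (1,), (2,)),
    14: ((1, 2), (0,), (3,)),
    15: ((0,), (1,), (2,), (3,)),
}

# Condensed states as index sets over the detailed states.
C_SETS: dict[int, tuple[int, ...]] = {
    1: (1,),
    2: (6,),
    3: (2, 3),
    4: (7,),
    5: (4, 5),
    6: (8,),
    7: (9, 12),
    8: (10, 11, 13, 14),
    9: (15,),
}

# Detailed-state index sets by IBD-allele count, for noninbred pairs.
B_SETS: dict[int, tuple[int, ...]] = {0: (15,), 1: (10, 11, 13, 14), 2: (9, 12)}


class KappaTriple(NamedTuple):
    """Single-locus IBD coefficients (kappa0, kappa1, kappa2) of a noninbred pair."""

    k0: float
    k1: float
    k2: float


@dataclass(frozen=True)
class IdentityVector:
    """Condensed (and optionally detailed) single-locus identity coefficients."""

    delta: np.ndarray  # shape (9,), Delta_1..Delta_9
    detailed: np.ndarray | None = None  # shape (15,), delta_1..delta_15

    def __post_init__(self):
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))
        if self.detailed is not None:
            object.__setattr__(self, "detailed", np.asarray(self.detailed, dtype=float))


# ---------------------------------------------------------------------------
# Kinship


def _inbreeding_of(ped: Pedigree, a) -> float:
    a = ped._check(a)
    if ped.is_founder(a):
        return ped.founder_inbreeding(a)
    return kinship(ped, ped.father(a), ped.mother(a))


def inbreeding(ped: Pedigree, a) -> float:
    """Inbreeding coefficient: the kinship of a's parents (or the founder
    annotation)."""
    return _inbreeding_of(ped, a)


def kinship(ped: Pedigree, a, b) -> float:
    """Single-locus kinship phi(a, b) by the classic pairwise recursion."""
    ia, ib = ped.topo_index(a), ped.topo_index(b)
    return _kin(ped, ia, ib)


def _kin(ped: Pedigree, i: int, j: int) -> float:
    if i > j:
        i, j = j, i
    memo = ped._kinship_memo
    val = memo.get((i, j))
    if val is not None:
        return val
    topo = ped._topo
    if i == j:
        iid = topo[i]
        if ped.is_founder(iid):
            f = ped._founder_inbreeding.get(iid, 0.0)
        else:
            f = _kin(
                ped,
                ped._topo_index[ped._father[iid]],
                ped._topo_index[ped._mother[iid]],
            )
        val = (1 + f) / 2
    else:
        jid = topo[j]
        if ped.is_founder(jid):
            val = 0.0  # a founder relates only to its descendants
        else:
            val = (
                _kin(ped, i, ped._topo_index[ped._father[jid]])
                + _kin(ped, i, ped._topo_index[ped._mother[jid]])
            ) / 2
    memo[(i, j)] = val
    return val


def generalized_kinship(ped: Pedigree, pattern) -> float:
    """Generalized single-locus kinship coefficient Phi(G).

    ``pattern`` is a :class:`LocusPattern` or an iterable of blocks of
    ``(individual, gamete_label)`` slots.
    """
    if not isinstance(pattern, LocusPattern):
        pattern = LocusPattern(pattern)
    two = TwoLocusPattern(pattern, LocusPattern([]))
    l1, l2 = _to_internal(ped, two)
    return _get_engine(ped, 0.0).phi(l1, l2)


# ---------------------------------------------------------------------------
# Identity coefficients


def _parental_slots(ped: Pedigree, a, b):
    """The four parental-gamete slots (fa, ma, gb, nb): the gametes that
    constituted a and b, written with constitutive labels so the recursion
    can reuse them when eliminating a parent.  Valid also under selfing and
    shared parents (the four gametes stay distinct)."""
    return (
        (ped.father(a), ("into", a, "pat")),
        (ped.mother(a), ("into", a, "mat")),
        (ped.father(b), ("into", b, "pat")),
        (ped.mother(b), ("into", b, "mat")),
    )


def _extended_for_identity(ped: Pedigree, a, b):
    """Extend the pedigree so that a and b are nonfounders."""
    for target in (a, b):
        if ped.is_founder(target):
            ped = extend_with_parents(ped, target)
    return ped


def j_locus_pattern(ped: Pedigree, a, b, r: int) -> LocusPattern:
    """The generalized kinship pattern J_r of the detailed state S*_r."""
    slots = _parental_slots(ped, a, b)
    return LocusPattern([[slots[i] for i in blk] for blk in J_PATTERNS[r]])


def detailed_identity(ped: Pedigree, a, b) -> np.ndarray:
    """Detailed identity coefficients delta_1..delta_15 (array of 15)."""
    a, b = ped._check(a), ped._check(b)
    if a == b:
        raise PedigreeError("detailed identity coefficients require two distinct ids")
    ped = _extended_for_identity(ped, a, b)
    out = np.empty(15)
    for r in range(1, 16):
        out[r - 1] = generalized_kinship(ped, j_locus_pattern(ped, a, b, r))
    return out


def condensed_identity(ped: Pedigree, a, b) -> IdentityVector:
    """Condensed identity coefficients Delta_1..Delta_9 (Jacquard order)."""
    a, b = ped._check(a), ped._check(b)
    if a == b:
        f = _inbreeding_of(ped, a)
        delta = np.zeros(9)
        delta[0] = f  # both allele pairs collapse when a is autozygous
        delta[6] = 1 - f
        return IdentityVector(delta=delta)
    det = detailed_identity(ped, a, b)
    delta = np.array([sum(det[r - 1] for r in C_SETS[i]) for i in range(1, 10)])
    return IdentityVector(delta=delta, detailed=det)


def kappa(ped: Pedigree, a, b) -> KappaTriple:
    """IBD coefficients (kappa0, kappa1, kappa2) = (Delta9, Delta8, Delta7).

    Defined only when both individuals are noninbred.
    """
    for x in (a, b):
        if _inbreeding_of(ped, x) > 0:
            raise InbredPairError(
                f"kappa coefficients are undefined: individual {x!r} is inbred"
            )
    if str(a) == str(b):
        return KappaTriple(0.0, 0.0, 1.0)
    iv = condensed_identity(ped, a, b)
    return KappaTriple(iv.delta[8], iv.delta[7], iv.delta[6])


def kappa_from_parental_kinships(ped: Pedigree, a, b) -> KappaTriple:
    """kappa via parental kinships: kappa2 = phi_fm phi_gn + phi_fn phi_gm,
    kappa1 = 4 phi - 2 kappa2 (f, g parents of a; m, n parents of b)."""
    for x in (a, b):
        if _inbreeding_of(ped, x) > 0:
            raise InbredPairError(
                f"kappa coefficients are undefined: individual {x!r} is inbred"
            )
        if ped.is_founder(x):
            raise PedigreeError(
                f"parental-kinship formula needs nonfounders; {x!r} is a founder"
            )
    f, g = ped.father(a), ped.mother(a)
    m, n = ped.father(b), ped.mother(b)
    k2 = kinship(ped, f, m) * kinship(ped, g, n) + kinship(ped, f, n) * kinship(ped, g, m)
    k1 = 4 * kinship(ped, a, b) - 2 * k2
    return KappaTriple(1 - k1 - k2, k1, k2)
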