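"""Two-locus coefficient matrices: K(rho), phased components, and D(rho).

Three routes, dispatched on relationship class:

* unilineal pairs: kappa11 from the balanced pattern
  H* = {[a1,a2,b1,b2]} x {[a1,b1],[a2],[b2]}, whose probability equals
  (rho_bar^2 rho^2 / 16) kappa11 regardless of the cis/trans phase, and then
  the whole 3x3 matrix K from kappa11 via the row/column-sum constraints;
* bilineal pairs: the 7x7 grid of coefficients Phi(J_r x J_s), r, s in
  {9..15}, summed over the index sets B_i; the same grid refines into the
  ten phased components;
* general (possibly inbred) pairs: the full 9x9 identity matrix D from the
  15x15 grid, where row 8 and column 8 -- much the most expensive cells --
  are recovered from the single-locus row/column sums instead of being
  evaluated recursively, leaving 121 of the 225 grid terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InbredPairError, PedigreeError, UnsupportedFounderInbreedingError
from .pedigree import Pedigree, classify
from .patterns import TwoLocusPattern
from .single import (
    B_SETS,
    C_SETS,
    KappaTriple,
    _extended_for_identity,
    _inbreeding_of,
    condensed_identity,
    j_locus_pattern,
    kappa as kappa1,
)
from .twolocus import (
    _check_rho,
    generalized_kinship2,
    require_whole_founder_inbreeding,
)


@dataclass(frozen=True)
class KappaMatrix:
    """3x3 matrix of two-locus IBD coefficients kappa_ij(rho), entry (i, j)
    = P(i alleles IBD at locus 1 and j at locus 2)."""

    k: np.ndarray
    rho: float

    def __post_init__(self):
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))

    @property
    def single_locus(self) -> KappaTriple:
        return KappaTriple(*self.k.sum(axis=1))


class PhasedKappa(NamedTuple):
    """The ten phased components of the two-locus IBD coefficients.

    ``cc``/``ct``/``tc``/``tt`` say whether the IBD alleles lie in cis or in
    trans within a and b respectively; ``h``/``r`` whether the doubly-IBD
    haplotypes are intact or recombined.
    """

    k11cc: float
    k11ct: float
    k11tc: float
    k11tt: float
    k21h: float
    k21r: float
    k12h: float
    k12r: float
    k22h: float
    k22r: float


@dataclass(frozen=True)
class IdentityMatrix:
    """9x9 matrix of two-locus condensed identity coefficients Delta_ij(rho)."""

    d: np.ndarray
    rho: float

    def __post_init__(self):
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))

    @property
    def single_locus(self) -> np.ndarray:
        return self.d.sum(axis=1)


def _require_noninbred(ped: Pedigree, a, b) -> None:
    for x in (a, b):
        if _inbreeding_of(ped, x) > 0:
            raise InbredPairError(
                f"two-locus IBD coefficients are undefined: {x!r} is inbred"
            )


# ---------------------------------------------------------------------------
# Unilineal route (Theorem-1 style)


def kappa11_unilineal(ped: Pedigree, a, b, rho):
    """kappa11(rho) of a unilineal pair from the balanced pattern H*.

    At rho = 0 the pattern degenerates (the identity divides by rho^2) and
    kappa11(0) = kappa1 is returned directly.
    """
    rho = _check_rho(rho)
    require_whole_founder_inbreeding(ped)
    a, b = ped._check(a), ped._check(b)
    rel = classify(ped, a, b)
    if rel.inbred_a or rel.inbred_b or rel.lineality != "unilineal":
        raise PedigreeError(
            "kappa11_unilineal requires a noninbred unilineal pair; "
            f"classification is {rel}"
        )
    if rho == 0:
        return kappa1(ped, a, b).k1
    locus1 = [[(a, 1), (a, 2), (b, 1), (b, 2)]]
    locus2 = [[(a, 1), (b, 1)], [(a, 2)], [(b, 2)]]
    phi_star = generalized_kinship2(ped, (locus1, locus2), rho)
    rbar = 1 - rho
    return 16 * phi_star / (rbar * rbar * rho * rho)


def _unilineal_matrix(k1_single, k11, zero):
    k = [
        [1 - 2 * k1_single + k11, k1_single - k11, zero],
        [k1_single - k11, k11, zero],
        [zero, zero, zero],
    ]
    return k


# ---------------------------------------------------------------------------
# Bilineal / general grid evaluations


class _JGrid:
    """Evaluator of Phi(J_r x J_s) sharing one engine cache; exploits the
    locus-exchange symmetry Phi(J_r x J_s) = Phi(J_s x J_r)."""

    def __init__(self, ped: Pedigree, a, b, rho):
        self.ped = ped
        self.a, self.b = a, b
        self.rho = rho
        self.cache: dict[tuple[int, int], float] = {}

    def phi(self, r: int, s: int):
        if r > s:
            r, s = s, r
        val = self.cache.get((r, s))
        if val is None:
            pat = TwoLocusPattern(
                j_locus_pattern(self.ped, self.a, self.b, r),
                j_locus_pattern(self.ped, self.a, self.b, s),
            )
            val = generalized_kinship2(self.ped, pat, self.rho)
            self.cache[(r, s)] = val
        return val


def _bilineal_matrix(grid: _JGrid):
    k = [[None] * 3 for _ in range(3)]
    for i in range(3):
        for j in range(i, 3):
            v = sum(grid.phi(r, s) for r in B_SETS[i] for s in B_SETS[j])
            k[i][j] = v
            k[j][i] = v
    return k


def two_locus_ibd(ped: Pedigree, a, b, rho, method: str = "auto") -> KappaMatrix:
    """The 3x3 two-locus IBD matrix K(rho) of a noninbred pair.

    ``method`` is ``"auto"`` (classify and dispatch, with closed endpoint
    forms at rho = 0 and rho = 1/2), ``"unilineal"`` (force the H* route) or
    ``"general"`` (force the J-grid route); the forced routes skip the
    endpoint shortcuts and exist mainly for cross-validation.
    """
    rho = _check_rho(rho)
    require_whole_founder_inbreeding(ped)
    a, b = ped._check(a), ped._check(b)
    _require_noninbred(ped, a, b)

    if a == b:
        k = np.zeros((3, 3))
        k[2, 2] = 1.0
        return KappaMatrix(k=k, rho=float(rho))

    if method == "auto":
        ks = kappa1(ped, a, b)
        if rho == 0:
            return KappaMatrix(k=np.diag(ks), rho=0.0)
        if rho == 0.5:
            v = np.asarray(ks, dtype=float)
            return KappaMatrix(k=np.outer(v, v), rho=0.5)
        rel = classify(ped, a, b)
        method = "unilineal" if rel.lineality == "unilineal" else "general"

    if method == "unilineal":
        k11 = kappa11_unilineal(ped, a, b, rho)
        k1s = kappa1(ped, a, b).k1
        k = _unilineal_matrix(k1s, k11, 0 * k11)
    elif method == "general":
        eped = _extended_for_identity(ped, a, b)
        k = _bilineal_matrix(_JGrid(eped, a, b, rho))
    else:
        raise PedigreeError(f"unknown method {method!r}")
    return KappaMatrix(k=np.array(k, dtype=float), rho=float(rho))


def two_locus_ibd_phased(ped: Pedigree, a, b, rho) -> PhasedKappa:
    """The ten phased components of K(rho) for a noninbred pair.

    Components are sums over the J-grid: e.g. k22h = Phi(J9 x J9) +
    Phi(J12 x J12), k11ct = 2 Phi(J10 x J13) + 2 Phi(J11 x J14).  The pair is
    extended to nonfounders when necessary; phases refer to (a, b) in order.
    """
    rho = _check_rho(rho)
    require_whole_founder_inbreeding(ped)
    a, b = ped._check(a), ped._check(b)
    _require_noninbred(ped, a, b)
    eped = _extended_for_identity(ped, a, b)
    g = _JGrid(eped, a, b, rho)
    k11cc = g.phi(10, 10) + g.phi(11, 11) + g.phi(13, 13) + g.phi(14, 14)
    k11ct = 2 * g.phi(10, 13) + 2 * g.phi(11, 14)
    k11tc = 2 * g.phi(10, 14) + 2 * g.phi(11, 13)
    k11tt = 2 * g.phi(10, 11) + 2 * g.phi(13, 14)
    k21h = g.phi(9, 10) + g.phi(9, 11) + g.phi(12, 13) + g.phi(12, 14)
    k21r = g.phi(9, 13) + g.phi(9, 14) + g.phi(12, 10) + g.phi(12, 11)
    k22h = g.phi(9, 9) + g.phi(12, 12)
    k22r = 2 * g.phi(9, 12)
    return PhasedKappa(
        k11cc=k11cc, k11ct=k11ct, k11tc=k11tc, k11tt=k11tt,
        k21h=k21h, k21r=k21r, k12h=k21h, k12r=k21r, k22h=k22h, k22r=k22r,
    )


# ---------------------------------------------------------------------------
# Full identity matrix


def plan_identity_terms() -> frozenset[tuple[int, int]]:
    """Grid cells (r, s) requiring recursive evaluation for the 9x9 matrix D
    when row 8 and column 8 are recovered from single-locus sums."""
    c8 = set(C_SETS[8])
    keep = [r for r in range(1, 16) if r not in c8]
    return frozenset((r, s) for r in keep for s in keep)


def two_locus_identity(ped: Pedigree, a, b, rho) -> IdentityMatrix:
    """The 9x9 two-locus condensed identity matrix D(rho) of any pair.

    Cells outside row/column 8 are sums of Phi(J_r x J_s) over the condensed
    index sets; row and column 8 follow from the single-locus coefficients
    (row sums of D are the Delta_i).  Founder targets are handled by
    extension, which is impossible for a completely inbred founder.
    """
    rho = _check_rho(rho)
    require_whole_founder_inbreeding(ped)
    a, b = ped._check(a), ped._check(b)
    if a == b:
        raise PedigreeError("two_locus_identity requires two distinct individuals")
    for x in (a, b):
        if ped.is_founder(x) and ped.founder_inbreeding(x) >= 1:
            raise UnsupportedFounderInbreedingError(
                f"completely inbred founder {x!r} cannot be an identity target"
            )
    eped = _extended_for_identity(ped, a, b)
    delta = condensed_identity(eped, a, b).delta

    if rho == 0:
        return IdentityMatrix(d=np.diag(delta), rho=0.0)

    grid = _JGrid(eped, a, b, rho)
    d = np.zeros((9, 9))
    for i in range(1, 10):
        if i == 8:
            continue
        for j in range(i, 10):
            if j == 8:
                continue
            v = float(sum(grid.phi(r, s) for r in C_SETS[i] for s in C_SETS[j]))
            d[i - 1, j - 1] = v
            d[j - 1, i - 1] = v
    # row sums give column 8, then column sums give row 8 (including (8, 8))
    for i in range(9):
        if i != 7:
            d[i, 7] = delta[i] - (d[i, :].sum() - d[i, 7])
    for j in range(9):
        d[7, j] = delta[j] - (d[:, j].sum() - d[7, j])
    d[np.abs(d) < 1e-14] = 0.0
    return IdentityMatrix(d=d, rho=float(rho))
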