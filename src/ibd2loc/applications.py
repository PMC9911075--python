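"""Consumers of two-locus IBD coefficients.

* Expected likelihood ratio E[LR] in forensic kinship testing with two
  linked markers carrying equifrequent alleles: a bilinear form in the
  two-locus IBD matrices of the hypothesized and the true relationship.
* Haldane's map function linking genetic distance to recombination fraction.
* Variance of realized relatedness: the genome fraction in IBD state j is
  random around its expectation kappa_j, with variance given by a double
  integral of kappa_jj over locus pairs, reduced here to one dimension and
  evaluated by Gauss-Legendre quadrature.
* A two-locus IBD correlation summary in the allele-sharing-proportion
  convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coefficients import KappaMatrix, two_locus_ibd
from .errors import PedigreeError
from .pedigree import Pedigree
from .single import kappa as kappa1
from .twolocus import RecombinationFraction


@dataclass(frozen=True)
class MarkerSpec:
    """A marker with ``n_alleles`` equally frequent alleles."""

    n_alleles: int

    def __post_init__(self):
        if self.n_alleles < 1:
            raise PedigreeError("a marker needs at least one allele")


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths in Morgan."""

    chromosome_lengths: tuple[float, ...]

    def __post_init__(self):
        lengths = tuple(float(x) for x in self.chromosome_lengths)
        if not lengths or any(x <= 0 for x in lengths):
            raise PedigreeError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosome_lengths", lengths)


def elr_matrix(n: int) -> np.ndarray:
    """Single-marker E[LR] kernel M for a marker with n equifrequent alleles.

    Row/column index is the IBD-allele count (0-indexed): M[0, :] = M[:, 0]
    = 1, M[1, 1] = (n + 3)/4, M[1, 2] = M[2, 1] = (n + 1)/2,
    M[2, 2] = n (n + 1)/2.
    """
    n = MarkerSpec(n).n_alleles
    m = np.ones((3, 3))
    m[1, 1] = (n + 3) / 4
    m[1, 2] = m[2, 1] = (n + 1) / 2
    m[2, 2] = n * (n + 1) / 2
    return m


def _kmat(k) -> np.ndarray:
    if isinstance(k, KappaMatrix):
        k = k.k
    k = np.asarray(k, dtype=float)
    if k.shape != (3, 3):
        raise PedigreeError(f"expected a 3x3 kappa matrix, got shape {k.shape}")
    if not math.isclose(k.sum(), 1.0, abs_tol=1e-8):
        raise PedigreeError("kappa matrix entries must sum to 1")
    return k


def expected_lr(K_hyp, K_true, n1: int, n2: int) -> float:
    """Expected likelihood ratio for two linked markers.

    ``K_hyp`` is the two-locus IBD matrix of the hypothesized relationship,
    ``K_true`` of the true one (evaluate both at the same rho);  ``n1``,
    ``n2`` are the marker allele counts.  E[LR] = sum over i,j,i',j' of
    kappa_ij kappa'_i'j' M1[i, i'] M2[j, j'] and equals 1 when the true
    relationship is "unrelated".
    """
    kh, kt = _kmat(K_hyp), _kmat(K_true)
    m1, m2 = elr_matrix(n1), elr_matrix(n2)
    return float(np.einsum("ij,IJ,iI,jJ->", kh, kt, m1, m2))


def haldane_rho(d: float) -> RecombinationFraction:
    """Recombination fraction at genetic distance ``d`` Morgan under a
    Poisson crossover process: rho = (1 - exp(-2 d)) / 2."""
    if d < 0:
        raise PedigreeError("genetic distance must be nonnegative")
    return RecombinationFraction((1.0 - math.exp(-2.0 * d)) / 2.0)


def var_realized_k(
    ped: Pedigree,
    a,
    b,
    j: int,
    genome,
    n_nodes: int = 64,
) -> float:
    """Variance of the realized genome proportion in IBD state ``j``.

    For one chromosome of length L Morgan,
    Var(k_j) = (2/L^2) Int_0^L (L - d) kappa_jj(rho(d)) dd - kappa_j^2,
    with rho(d) from Haldane's map; the integral is evaluated by fixed-order
    Gauss-Legendre quadrature with kappa_jj cached per rho node.  Several
    chromosomes combine by length-weighted averaging with zero covariance
    across chromosomes (kappa_jj(1/2) = kappa_j^2).

    Only noninbred pairs are supported; the inbred analogue over the nine
    condensed states is a documented extension point.
    """
    if j not in (0, 1, 2):
        raise PedigreeError("IBD state index j must be 0, 1 or 2")
    if isinstance(genome, GenomeSpec):
        lengths = genome.chromosome_lengths
    elif np.isscalar(genome):
        lengths = GenomeSpec((genome,)).chromosome_lengths
    else:
        lengths = GenomeSpec(tuple(genome)).chromosome_lengths
    kj = float(kappa1(ped, a, b)[j])

    cache: dict[float, float] = {}

    def kjj(rho: float) -> float:
        val = cache.get(rho)
        if val is None:
            val = float(two_locus_ibd(ped, a, b, rho).k[j, j])
            cache[rho] = val
        return val

    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    total_len = sum(lengths)
    var = 0.0
    for L in lengths:
        d = 0.5 * L * (nodes + 1.0)
        w = 0.5 * L * weights
        integral = sum(
            wi * (L - di) * kjj(float(haldane_rho(di))) for wi, di in zip(w, d)
        )
        var_c = 2.0 * integral / (L * L) - kj * kj
        var += (L / total_len) ** 2 * var_c
    return max(var, 0.0)


def ibd_correlation(ped: Pedigree, a, b, rho) -> float:
    """Correlation of the allele-sharing proportions at two linked loci.

    With pi = kappa1/2 + kappa2 the expected sharing proportion,
    corr = (sum_ij (i/2)(j/2) kappa_ij - pi^2) / (sum_i (i/2)^2 kappa_i -
    pi^2).  Equals 1 at rho = 0 and 0 at rho = 1/2; undefined for
    relationships with zero single-locus sharing variance (e.g.
    parent-offspring).
    """
    K = two_locus_ibd(ped, a, b, rho)
    ks = np.asarray(kappa1(ped, a, b), dtype=float)
    half_i = np.array([0.0, 0.5, 1.0])
    pi = float(half_i @ ks)
    den = float((half_i**2) @ ks) - pi * pi
    if den <= 1e-14:
        raise PedigreeError(
            "IBD correlation is undefined: the relationship has zero "
            "single-locus sharing variance"
        )
    num = float(half_i @ K.k @ half_i) - pi * pi
    return num / den
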