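"""Exact polynomial recovery of coefficient functions of rho.

Every pedigree coefficient computed here is a polynomial in the
recombination fraction.  Evaluating a coefficient function at rational rho
values in exact arithmetic and interpolating recovers the closed-form
polynomial, with verification at extra nodes guarding against an
underestimated degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

from .errors import PedigreeError


@dataclass(frozen=True)
class RhoPolynomial:
    """A polynomial sum_k c_k rho^k with exact rational coefficients."""

    coefficients: tuple[Fraction, ...]

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, rho):
        acc = 0 * rho if not isinstance(rho, (int, float)) else 0
        for c in reversed(self.coefficients):
            acc = acc * rho + c
        return acc

    def scaled(self, factor) -> tuple:
        return tuple(c * factor for c in self.coefficients)

    def __str__(self) -> str:
        terms = []
        for k, c in enumerate(self.coefficients):
            if c == 0:
                continue
            terms.append(f"({c})*rho^{k}" if k else f"({c})")
        return " + ".join(terms) or "0"


def _default_nodes(degree: int) -> list[Fraction]:
    return [Fraction(k, 2 * (degree + 1)) for k in range(degree + 1)]


def fit_rho_polynomial(
    fn: Callable[[Fraction], Fraction],
    degree: int,
    nodes: Sequence[Fraction] | None = None,
) -> RhoPolynomial:
    """Interpolate ``fn`` (exact-rational-capable) by a degree-``degree``
    polynomial through ``degree + 1`` rational nodes in [0, 1/2], then verify
    the fit exactly at two extra nodes.

    Raises if verification fails, i.e. ``fn`` is not a polynomial of the
    stated degree.
    """
    if degree < 0:
        raise PedigreeError("polynomial degree must be nonnegative")
    if nodes is None:
        nodes = _default_nodes(degree)
    nodes = [Fraction(x) for x in nodes]
    if len(set(nodes)) != degree + 1:
        raise PedigreeError(f"need {degree + 1} distinct nodes, got {nodes}")
    if any(not 0 <= x <= Fraction(1, 2) for x in nodes):
        raise PedigreeError("interpolation nodes must lie in [0, 1/2]")
    values = [Fraction(fn(x)) for x in nodes]

    # Newton's divided differences, exact
    coeffs_newton = list(values)
    for level in range(1, degree + 1):
        for i in range(degree, level - 1, -1):
            coeffs_newton[i] = (coeffs_newton[i] - coeffs_newton[i - 1]) / (
                nodes[i] - nodes[i - level]
            )
    # expand to monomial basis: p = (...((c_d (x - x_{d-1})) + c_{d-1}) ...)
    poly = [coeffs_newton[degree]]
    for k in range(degree - 1, -1, -1):
        new = [Fraction(0)] * (len(poly) + 1)
        for i, c in enumerate(poly):
            new[i + 1] += c
            new[i] -= nodes[k] * c
        new[0] += coeffs_newton[k]
        poly = new
    result = RhoPolynomial(tuple(poly))

    candidates = [Fraction(1, 2), Fraction(3, 7), Fraction(5, 11), Fraction(4, 9)]
    checks = [x for x in candidates if x not in nodes][:2]
    for x in checks:
        expect = Fraction(fn(x))
        got = result(x)
        if got != expect:
            raise PedigreeError(
                f"polynomial verification failed at rho={x}: residual {got - expect}; "
                f"the function is not a degree-{degree} polynomial"
            )
    return result
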