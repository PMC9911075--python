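"""Recursive generalized two-locus kinship coefficients.

The engine computes Phi(G1 x G2): the probability that independently sampled
gametes realize the IBD partition G1 at locus 1 and G2 at locus 2, where the
loci recombine at fraction rho.  The recursion pivots on the youngest
nonfounder present in the pattern and replaces its gametes by parental-origin
gametes:

* a gamete observed at both loci descends from the same parental haplotype at
  both loci with probability (1 - rho)/2 per haplotype, and from different
  haplotypes (a recombinant gamete) with probability rho/2 per ordered choice;
* a gamete observed at a single locus descends from either haplotype with
  probability 1/2;
* distinct gametes of the pivot segregate independently, but all of them draw
  on the *same* two parental gametes -- the pivot's own haplotypes -- marked
  by the semantic labels (pivot, paternal/maternal).  These are two distinct
  gametes even under selfing, and they unify with any constitutive labels
  already referencing the gametes the pivot received from its parents (the
  segregation-index convention needed by direct relationships).

At the founder boundary the same branching resolves each founder gamete into
one of the founder's two haplotypes -- founders recombine like everyone else
-- after which the pattern is a set of constraints on fixed ancestral
alleles: blocks must collapse to a single allele, distinct blocks to distinct
alleles.  A completely inbred founder carries one allele class; partial
founder inbreeding contributes factors f / (1 - f) at a single locus and is
rejected by every two-locus entry point, where it is ill-defined.

Arithmetic is generic: pass ``rho`` as a ``fractions.Fraction`` to evaluate
exactly, or as a float for double precision.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from numbers import Rational

from .errors import PedigreeError, UnsupportedFounderInbreedingError
from .patterns import (
    LocusPattern,
    TwoLocusPattern,
    _canonical,
    _trivial_zero_idx,
    is_constitutive_label,
)
from .pedigree import Pedigree


def _label_sort_key(lab):
    """Deterministic order over mixed int (free) and tuple (semantic) labels."""
    return (1, lab) if isinstance(lab, tuple) else (0, (lab, lab))


def _slot_sort_key(slot):
    ind, lab = slot
    return (ind, _label_sort_key(lab))


class RecombinationFraction:
    """A recombination fraction rho in [0, 1/2].

    Exposes ``rho_bar = 1 - rho`` and the non-recombinant gamete-pair
    probability ``R = rho^2 + rho_bar^2``.
    """

    __slots__ = ("rho",)

    def __init__(self, rho):
        rho = _check_rho(rho)
        self.rho = rho

    @property
    def rho_bar(self):
        return 1 - self.rho

    @property
    def R(self):
        return self.rho**2 + self.rho_bar**2

    def __float__(self) -> float:
        return float(self.rho)

    def __repr__(self) -> str:
        return f"RecombinationFraction({self.rho})"


def _check_rho(rho):
    if isinstance(rho, RecombinationFraction):
        rho = rho.rho
    if not 0 <= rho <= 0.5:
        raise PedigreeError(f"recombination fraction must lie in [0, 0.5], got {rho}")
    return rho


def require_whole_founder_inbreeding(ped: Pedigree) -> None:
    """Two-locus coefficients are defined only for founder inbreeding 0 or 1."""
    if ped.has_partial_founder_inbreeding():
        raise UnsupportedFounderInbreedingError(
            "partial founder inbreeding is unsupported at two loci; "
            "founder inbreeding coefficients must be 0 or 1"
        )


class _Engine:
    """Memoized evaluator of generalized kinship patterns in one pedigree at
    one fixed rho.  Patterns are internal: per-locus tuples of blocks of
    (topological index, integer label) slots."""

    def __init__(self, ped: Pedigree, rho):
        self.ped = ped
        self.rho = rho
        one = Fraction(1) if isinstance(rho, Rational) and not isinstance(rho, int) else 1.0
        self.one = one
        self.half = one / 2
        self.w_same = (one - rho) / 2
        self.w_rec = (one * rho) / 2
        topo = ped._topo
        self.father = [
            ped._topo_index[ped._father[i]] if i in ped._father else -1 for i in topo
        ]
        self.mother = [
            ped._topo_index[ped._mother[i]] if i in ped._mother else -1 for i in topo
        ]
        self.is_founder = [f < 0 for f in self.father]
        self.fi = [
            ped._founder_inbreeding.get(i, 0.0) if ped._father.get(i) is None else 0.0
            for i in topo
        ]
        self.anc = ped._anc
        self.memo: dict = {}

    # -- main recursion ---------------------------------------------------

    def phi(self, l1, l2):
        if _trivial_zero_idx(l1, self.anc, self.is_founder) or _trivial_zero_idx(
            l2, self.anc, self.is_founder
        ):
            return 0 * self.one
        key = _canonical(l1, l2)
        val = self.memo.get(key)
        if val is None:
            present = {ind for blocks in (l1, l2) for b in blocks for ind, _ in b}
            pivots = [i for i in present if not self.is_founder[i]]
            if pivots:
                val = self._pivot(l1, l2, max(pivots))
            else:
                val = self._boundary(l1, l2)
            self.memo[key] = val
        return val

    def _labels_of(self, l1, l2, x):
        """Labels of individual x with (at locus 1, at locus 2) occurrence."""
        occ: dict = {}
        for locus_no, blocks in ((0, l1), (1, l2)):
            for b in blocks:
                for ind, lab in b:
                    if ind == x:
                        flags = occ.setdefault(lab, [False, False])
                        flags[locus_no] = True
        return occ

    def _substitute(self, blocks, mapping):
        """Apply slot substitutions; returns None if the same gamete would
        land in two blocks (same allele required both IBD and non-IBD)."""
        out = []
        seen = set()
        for b in blocks:
            nb = frozenset(mapping.get(slot, slot) for slot in b)
            if seen & nb:
                return None
            seen |= nb
            out.append(tuple(sorted(nb, key=_slot_sort_key)))
        return tuple(out)

    def _pivot(self, l1, l2, x):
        occ = self._labels_of(l1, l2, x)
        labels = sorted(occ, key=_label_sort_key)
        # The transmitted parental gametes are x's own haplotypes: label them
        # semantically as (x, side) so that existing references to "the gamete
        # x received from its father/mother" (constitutive labels, as in the
        # parental patterns J_r for direct relationships) unify with them.
        F, M = self.father[x], self.mother[x]
        parent_slot = {0: (F, (x, 0)), 1: (M, (x, 1))}

        choice_sets = []
        for lab in labels:
            at1, at2 = occ[lab]
            if at1 and at2:
                choice_sets.append(
                    [(0, 0, self.w_same), (1, 1, self.w_same),
                     (0, 1, self.w_rec), (1, 0, self.w_rec)]
                )
            elif at1:
                choice_sets.append([(0, None, self.half), (1, None, self.half)])
            else:
                choice_sets.append([(None, 0, self.half), (None, 1, self.half)])

        total = 0 * self.one
        for combo in itertools.product(*choice_sets):
            w = self.one
            map1, map2 = {}, {}
            for lab, (side1, side2, wt) in zip(labels, combo):
                if wt == 0:
                    w = 0
                    break
                w = w * wt
                if side1 is not None:
                    map1[(x, lab)] = parent_slot[side1]
                if side2 is not None:
                    map2[(x, lab)] = parent_slot[side2]
            if w == 0:
                continue
            n1 = self._substitute(l1, map1)
            if n1 is None:
                continue
            n2 = self._substitute(l2, map2)
            if n2 is None:
                continue
            total = total + w * self.phi(n1, n2)
        return total

    # -- founder boundary -------------------------------------------------

    def _boundary(self, l1, l2):
        """All-founder pattern.  Since the trivial-zero screen has removed
        every block spanning two distinct founders, the constraints couple
        gametes only through their shared founder, and the probability
        factorizes as a product of per-founder terms."""
        two_locus = bool(l1) and bool(l2)
        per_founder: dict[int, list] = {}
        for locus_no, blocks in ((0, l1), (1, l2)):
            for b in blocks:
                fnd = b[0][0]
                per_founder.setdefault(fnd, ([], []))[locus_no].append(b)
        total = self.one
        for fnd in sorted(per_founder):
            total = total * self._founder_factor(fnd, *per_founder[fnd], two_locus)
            if total == 0:
                break
        return total

    def _founder_factor(self, fnd, blocks1, blocks2, two_locus):
        """Probability that one founder's sampled gametes satisfy its blocks.

        Each gamete picks one of the founder's two haplotypes per locus with
        the usual recombination weights.  Atoms are the founder's (haplotype,
        locus) alleles, with a completely inbred founder's haplotypes
        collapsed into one class; a block must collapse to a single atom, and
        distinct blocks at one locus must hold distinct atoms.  A partially
        inbred founder's cross-haplotype constraints contribute f (forced
        IBD) or 1 - f (forced non-IBD), which is well-defined only at a
        single locus.
        """
        occ: dict = {}
        for locus_no, blocks in ((0, blocks1), (1, blocks2)):
            for b in blocks:
                for slot in b:
                    occ.setdefault(slot, [False, False])[locus_no] = True
        gametes = sorted(occ, key=_slot_sort_key)
        choice_sets = []
        for g in gametes:
            at1, at2 = occ[g]
            if at1 and at2:
                choice_sets.append(
                    [(0, 0, self.w_same), (1, 1, self.w_same),
                     (0, 1, self.w_rec), (1, 0, self.w_rec)]
                )
            else:
                which = 0 if at1 else 1
                opts = []
                for h in (0, 1):
                    opts.append((h, None, self.half) if which == 0 else (None, h, self.half))
                choice_sets.append(opts)

        f = self.fi[fnd]
        inbred = f == 1
        total = 0 * self.one
        for combo in itertools.product(*choice_sets):
            w = self.one
            hap = {}
            for g, (h1, h2, wt) in zip(gametes, combo):
                if wt == 0:
                    w = 0
                    break
                w = w * wt
                hap[g] = (h1, h2)
            if w == 0:
                continue
            need_ibd = need_distinct = False
            ok = True
            for locus_no, blocks in ((0, blocks1), (1, blocks2)):
                owner: dict = {}
                for bno, b in enumerate(blocks):
                    atoms = {0 if inbred else hap[slot][locus_no] for slot in b}
                    if len(atoms) > 1:  # both haplotypes in one block
                        if f == 0:
                            ok = False
                            break
                        need_ibd = True
                    for atom in atoms:
                        prev = owner.get(atom)
                        if prev is not None and prev != bno:
                            ok = False  # same allele in two non-IBD blocks
                            break
                        owner[atom] = bno
                    if not ok:
                        break
                if not ok:
                    break
                if len({b for b in owner.values()}) > 1 and len(owner) > 1:
                    # distinct blocks hold the two haplotypes: must not be IBD
                    if inbred:
                        ok = False
                        break
                    if f > 0:
                        need_distinct = True
            if not ok:
                continue
            if need_ibd and need_distinct:
                continue
            factor = self.one
            if need_ibd and not inbred:
                if two_locus:
                    raise UnsupportedFounderInbreedingError(
                        "partial founder inbreeding encountered in a two-locus pattern"
                    )
                factor = factor * f
            if need_distinct:
                if two_locus:
                    raise UnsupportedFounderInbreedingError(
                        "partial founder inbreeding encountered in a two-locus pattern"
                    )
                factor = factor * (1 - f)
            total = total + w * factor
        return total


# ---------------------------------------------------------------------------
# Engine cache and pattern conversion


def _get_engine(ped: Pedigree, rho) -> _Engine:
    exact = isinstance(rho, Rational) and not isinstance(rho, int)
    key = (float(rho), exact)
    eng = ped._engines.get(key)
    if eng is None:
        eng = _Engine(ped, Fraction(rho) if exact else float(rho))
        ped._engines[key] = eng
    return eng


def _to_internal(ped: Pedigree, pattern: TwoLocusPattern):
    """Convert public id/label slots to (topo index, internal label) slots.

    Opaque labels are namespaced per individual and mapped to integers in
    first-occurrence order, scanning locus 1 then locus 2.  Constitutive
    labels ``("into", child, "pat"|"mat")`` map to the semantic internal
    label ``(child index, side)``, after checking that the slot's individual
    really is the corresponding parent of ``child``.
    """
    label_map: dict = {}

    def conv(locus: LocusPattern):
        out = []
        for b in locus.blocks:
            nb = []
            for s in b:
                idx = ped.topo_index(s.individual)
                lab = s.gamete_label
                if is_constitutive_label(lab):
                    child, side = str(lab[1]), 0 if lab[2] == "pat" else 1
                    parent = ped.father(child) if side == 0 else ped.mother(child)
                    if parent != s.individual:
                        raise PedigreeError(
                            f"constitutive label {lab!r} on {s.individual!r}, "
                            f"which is not the {lab[2]} parent of {child!r}"
                        )
                    nb.append((idx, (ped.topo_index(child), side)))
                else:
                    key = (idx, lab)
                    if key not in label_map:
                        label_map[key] = len(label_map) + 1
                    nb.append((idx, label_map[key]))
            out.append(tuple(sorted(set(nb), key=_slot_sort_key)))
        return tuple(out)

    return conv(pattern.locus1), conv(pattern.locus2)


def _as_two_locus(pattern) -> TwoLocusPattern:
    if isinstance(pattern, TwoLocusPattern):
        return pattern
    if isinstance(pattern, LocusPattern):
        return TwoLocusPattern(pattern, LocusPattern([]))
    locus1, locus2 = pattern
    if not isinstance(locus1, LocusPattern):
        locus1 = LocusPattern(locus1)
    if not isinstance(locus2, LocusPattern):
        locus2 = LocusPattern(locus2)
    return TwoLocusPattern(locus1, locus2)


# ---------------------------------------------------------------------------
# Public operations


def generalized_kinship2(ped: Pedigree, pattern, rho):
    """Generalized two-locus kinship coefficient Phi(G1 x G2) at ``rho``.

    ``pattern`` is a :class:`TwoLocusPattern` or a pair of block collections
    whose slots are ``(individual, gamete_label)`` tuples.  Pass ``rho`` as a
    :class:`fractions.Fraction` for exact rational evaluation.
    """
    rho = _check_rho(rho)
    require_whole_founder_inbreeding(ped)
    pattern = _as_two_locus(pattern)
    l1, l2 = _to_internal(ped, pattern)
    return _get_engine(ped, rho).phi(l1, l2)


def two_locus_kinship(ped: Pedigree, a, b, rho):
    """Two-locus kinship phi11: the probability that a random gamete from
    ``a`` and a random gamete from ``b`` carry IBD alleles at both loci.

    Satisfies phi11(0) = phi and phi11(1/2) = phi^2.
    """
    rho = _check_rho(rho)
    require_whole_founder_inbreeding(ped)
    a, b = ped._check(a), ped._check(b)
    blocks = [[(a, "g1"), (b, "g2")]]  # distinct labels: independent gametes
    return generalized_kinship2(ped, (blocks, blocks), rho)
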