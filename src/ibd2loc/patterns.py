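"""Algebra of generalized two-locus kinship patterns.

A *locus pattern* is a collection of disjoint blocks of allele slots; each
slot names an individual and a *gamete label*.  The pattern event is: sample
one gamete per (individual, label); the alleles within each block are all
IBD, alleles in different blocks are not.  Gamete labels are opaque tokens
whose scope is the individual: equal labels on slots of the same individual
-- including across the two loci -- mean "the same emitted gamete", which is
what couples the loci under recombination.

Canonicalization maps every pattern to a hashable key invariant under block
order, within-block order and consistent relabeling of gamete labels.  It is
the memoization key of the recursion engine.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from typing import Iterable, NamedTuple

from .errors import PedigreeError
from .pedigree import Pedigree


class AlleleSlot(NamedTuple):
    """One sampled allele: a gamete of ``individual`` tagged ``gamete_label``."""

    individual: str
    gamete_label: object


class LocusPattern:
    """Blocks of allele slots at one locus.

    Each slot occurs in at most one block (a gamete carries a single allele
    per locus), and blocks are non-empty.
    """

    __slots__ = ("blocks",)

    def __init__(self, blocks: Iterable[Iterable]):
        out = []
        seen = set()
        for b in blocks:
            fb = frozenset(AlleleSlot(str(i), lab) for i, lab in b)
            if not fb:
                raise PedigreeError("empty block in locus pattern")
            if seen & fb:
                raise PedigreeError("slot occurs in two blocks of one locus pattern")
            seen |= fb
            out.append(fb)
        self.blocks = tuple(out)

    def individuals(self) -> set[str]:
        return {s.individual for b in self.blocks for s in b}

    def __iter__(self):
        return iter(self.blocks)

    def __repr__(self) -> str:
        inner = ",".join(
            "[" + ",".join(f"{s.individual}:{s.gamete_label}" for s in sorted(b)) + "]"
            for b in self.blocks
        )
        return "{" + inner + "}"


class TwoLocusPattern(NamedTuple):
    """A pair of locus patterns sharing the gamete-label namespace."""

    locus1: LocusPattern
    locus2: LocusPattern

    def __repr__(self) -> str:
        return f"{self.locus1!r} x {self.locus2!r}"


# ---------------------------------------------------------------------------
# Canonical form
#
# Two kinds of gamete labels coexist.  *Free* labels denote anonymous,
# independently sampled meioses; they may be renamed at will (per
# individual), so the canonical form minimizes over consistent renamings.
# *Constitutive* labels denote the specific gamete that became a named
# member's paternal or maternal haplotype -- the segregation-index device
# that lets a pattern refer to "the gamete x received from its father", and
# that the recursion must reuse when it later eliminates x.  Their identity
# is meaningful, so they are kept verbatim in the key.
#
# For free labels: compute an isomorphism-invariant signature for every
# (individual, label) gamete from its slot contexts; order each individual's
# free labels by signature; enumerate the (usually trivial) permutations
# within signature ties; encode and take the lexicographic minimum.  The
# minimum over the signature-respecting orbit is identical for isomorphic
# patterns and distinct otherwise.


def _is_fixed_label(lab) -> bool:
    return isinstance(lab, tuple)


def _canonical(l1, l2):
    """Canonical key for an internal pattern (two block tuples) of
    ``(ind, label)`` slots, where ``ind`` is any totally ordered type and
    tuple labels are constitutive (kept fixed)."""
    descs = defaultdict(list)
    for locus_no, blocks in ((0, l1), (1, l2)):
        for b in blocks:
            profile = tuple(sorted(ind for ind, _ in b))
            for ind, lab in b:
                if not _is_fixed_label(lab):
                    descs[(ind, lab)].append((locus_no, len(b), profile))
    sig = {k: tuple(sorted(v)) for k, v in descs.items()}

    by_ind = defaultdict(list)
    for ind, lab in sig:
        by_ind[ind].append(lab)

    per_ind_orderings = []
    for ind in sorted(by_ind):
        groups = defaultdict(list)
        for lab in by_ind[ind]:
            groups[sig[(ind, lab)]].append(lab)
        tie_groups = [groups[s] for s in sorted(groups)]
        perms = [list(itertools.permutations(g)) for g in tie_groups]
        orderings = [
            list(itertools.chain.from_iterable(combo))
            for combo in itertools.product(*perms)
        ]
        per_ind_orderings.append((ind, orderings))

    def encode(ren):
        return tuple(
            tuple(
                sorted(
                    tuple(
                        sorted(
                            (ind, ("F",) + lab)
                            if _is_fixed_label(lab)
                            else (ind, ("N", ren[(ind, lab)]))
                            for ind, lab in b
                        )
                    )
                    for b in blocks
                )
            )
            for blocks in (l1, l2)
        )

    best = None
    for combo in itertools.product(*(o for _, o in per_ind_orderings)):
        ren = {}
        for (ind, _), ordering in zip(per_ind_orderings, combo):
            for rank, lab in enumerate(ordering):
                ren[(ind, lab)] = rank
        enc = encode(ren)
        if best is None or enc < best:
            best = enc
    return best


def is_constitutive_label(lab) -> bool:
    """Public constitutive labels are ``("into", child_id, "pat"|"mat")``:
    the gamete that became ``child``'s paternal/maternal haplotype."""
    return (
        isinstance(lab, tuple)
        and len(lab) == 3
        and lab[0] == "into"
        and lab[2] in ("pat", "mat")
    )


def canonical_key(pattern: TwoLocusPattern | LocusPattern):
    """Hashable key, equal exactly for semantically equal patterns.

    Opaque gamete labels are canonically renumbered per individual;
    constitutive ``("into", child, side)`` labels are kept verbatim.
    """
    if isinstance(pattern, LocusPattern):
        pattern = TwoLocusPattern(pattern, LocusPattern([]))
    ren: dict = {}

    def conv(lab):
        if is_constitutive_label(lab):
            return ("into", str(lab[1]), lab[2])
        if lab not in ren:
            ren[lab] = len(ren)
        return ren[lab]

    l1 = tuple(
        tuple((s.individual, conv(s.gamete_label)) for s in b) for b in pattern.locus1
    )
    l2 = tuple(
        tuple((s.individual, conv(s.gamete_label)) for s in b) for b in pattern.locus2
    )
    return _canonical(l1, l2)


# ---------------------------------------------------------------------------
# Trivial zeros


def _trivial_zero_idx(blocks, ped_anc, founder_mask) -> bool:
    """Zero test on an internal (topo-index) locus pattern.

    True if a block contains two distinct founders, or a provably unrelated
    pair (disjoint ancestor closures), or some individual occurs in more than
    two blocks.  Distinct founders are never IBD even when completely inbred,
    so founder inbreeding needs no special case here: only *one* founder's
    two alleles can coincide.
    """
    count = defaultdict(int)
    for b in blocks:
        inds = {ind for ind, _ in b}
        for ind in inds:
            count[ind] += 1
            if count[ind] > 2:
                return True
        if len(inds) > 1:
            founders_here = [i for i in inds if founder_mask[i]]
            if len(founders_here) > 1:
                return True
            for i, j in itertools.combinations(inds, 2):
                if not ped_anc[i] & ped_anc[j]:
                    return True
    return False


def trivial_zero(pattern: LocusPattern, ped: Pedigree) -> bool:
    """Cheap structural test implying Phi(pattern) = 0.

    Returning False is *not* a claim that the coefficient is positive.
    """
    idx_blocks = []
    for b in pattern.blocks:
        idx_blocks.append(tuple((ped.topo_index(s.individual), s.gamete_label) for s in b))
    founder_mask = [ped.is_founder(i) for i in ped._topo]
    return _trivial_zero_idx(idx_blocks, ped._anc, founder_mask)
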