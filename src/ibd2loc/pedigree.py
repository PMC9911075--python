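"""Pedigree data model, validation, text I/O and fixture relationships.

A :class:`Pedigree` is a directed acyclic parent--child structure over string
identifiers.  Every member has either both parents or none (a *founder*).
Selfing is allowed (father may equal mother), and founders may carry an
inbreeding coefficient in [0, 1].  Sex is stored when provided but never used
in any computation: recombination is assumed sex-symmetric throughout.

The text format is PLINK-style whitespace-delimited rows

    id  father  mother  [sex]

with ``0`` or ``*`` denoting a missing parent.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .errors import PedigreeError, UnsupportedFounderInbreedingError

MISSING = {"0", "*", "", None}

_SEX_CODES = {
    "1": "male", "2": "female", "0": "unknown",
    "male": "male", "female": "female", "unknown": "unknown",
    "M": "male", "F": "female", "m": "male", "f": "female",
}


class Pedigree:
    """Immutable pedigree over string ids.

    Parameters
    ----------
    trios:
        Iterable of ``(id, father, mother)`` or ``(id, father, mother, sex)``
        tuples.  Parents are either both present or both missing
        (``None``/``"0"``/``"*"``).
    founder_inbreeding:
        Optional mapping founder id -> inbreeding coefficient in [0, 1].
    """

    def __init__(
        self,
        trios: Iterable[Sequence],
        founder_inbreeding: Mapping[str, float] | None = None,
    ):
        father: dict[str, str] = {}
        mother: dict[str, str] = {}
        sex: dict[str, str] = {}
        order: list[str] = []
        for row in trios:
            if len(row) not in (3, 4):
                raise PedigreeError(f"expected 3 or 4 columns, got {row!r}")
            iid = str(row[0])
            if iid in MISSING:
                raise PedigreeError(f"invalid individual id {row[0]!r}")
            if iid in father or iid in sex or iid in order:
                raise PedigreeError(f"duplicate id {iid!r}")
            fa = None if row[1] in MISSING or str(row[1]) in MISSING else str(row[1])
            mo = None if row[2] in MISSING or str(row[2]) in MISSING else str(row[2])
            if (fa is None) != (mo is None):
                raise PedigreeError(
                    f"individual {iid!r} has exactly one parent; "
                    "either both or neither must be given"
                )
            order.append(iid)
            if fa is not None:
                father[iid] = fa
                mother[iid] = mo
            if len(row) == 4 and row[3] not in MISSING:
                code = str(row[3])
                sex[iid] = _SEX_CODES.get(code, "unknown")

        members = set(order)
        for iid in order:
            for par in (father.get(iid), mother.get(iid)):
                if par is not None and par not in members:
                    raise PedigreeError(f"unknown parent {par!r} of {iid!r}")

        self._father = father
        self._mother = mother
        self._sex = sex
        self._declared_order = tuple(order)
        self._topo = self._toposort(order)
        self._topo_index = {iid: k for k, iid in enumerate(self._topo)}

        self._founder_inbreeding: dict[str, float] = {}
        for iid, f in (founder_inbreeding or {}).items():
            iid = str(iid)
            if iid not in members:
                raise PedigreeError(f"unknown id {iid!r} in founder_inbreeding")
            if iid in father:
                raise PedigreeError(f"{iid!r} is not a founder")
            if not 0 <= f <= 1:
                raise PedigreeError(f"founder inbreeding must lie in [0, 1], got {f}")
            if f:
                self._founder_inbreeding[iid] = f

        # ancestor closures (including self) as bitsets over topo indices
        anc: list[int] = []
        for k, iid in enumerate(self._topo):
            bits = 1 << k
            if iid in father:
                bits |= anc[self._topo_index[father[iid]]]
                bits |= anc[self._topo_index[mother[iid]]]
            anc.append(bits)
        self._anc = anc

        # per-object caches, filled lazily by the coefficient engines
        self._kinship_memo: dict[tuple[int, int], float] = {}
        self._engines: dict = {}

    def _toposort(self, order: Sequence[str]) -> tuple[str, ...]:
        """Linear extension with parents before children; raises on cycles."""
        state: dict[str, int] = {}
        out: list[str] = []

        for start in order:
            stack = [start]
            while stack:
                iid = stack[-1]
                if state.get(iid) == 2:
                    stack.pop()
                    continue
                parents = [p for p in (self._father.get(iid), self._mother.get(iid)) if p]
                if state.get(iid) == 1:
                    state[iid] = 2
                    out.append(iid)
                    stack.pop()
                    continue
                state[iid] = 1
                for p in parents:
                    if state.get(p) == 1:
                        raise PedigreeError(f"pedigree cycle involving {p!r}")
                    if state.get(p) is None:
                        stack.append(p)
        return tuple(out)

    # -- basic queries ----------------------------------------------------

    @property
    def members(self) -> tuple[str, ...]:
        """All ids, in declaration order."""
        return self._declared_order

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(i for i in self._declared_order if i not in self._father)

    @property
    def nonfounders(self) -> tuple[str, ...]:
        return tuple(i for i in self._declared_order if i in self._father)

    def __contains__(self, iid) -> bool:
        return str(iid) in self._topo_index

    def __len__(self) -> int:
        return len(self._declared_order)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return (
            set(self.members) == set(other.members)
            and self._father == other._father
            and self._mother == other._mother
            and self._sex == other._sex
            and self._founder_inbreeding == other._founder_inbreeding
        )

    def __repr__(self) -> str:
        return f"<Pedigree with {len(self)} members ({len(self.founders)} founders)>"

    def father(self, iid) -> str | None:
        return self._father.get(self._check(iid))

    def mother(self, iid) -> str | None:
        return self._mother.get(self._check(iid))

    def sex(self, iid) -> str:
        return self._sex.get(self._check(iid), "unknown")

    def is_founder(self, iid) -> bool:
        return self._check(iid) not in self._father

    def founder_inbreeding(self, iid) -> float:
        iid = self._check(iid)
        if iid in self._father:
            raise PedigreeError(f"{iid!r} is not a founder")
        return self._founder_inbreeding.get(iid, 0.0)

    def has_partial_founder_inbreeding(self) -> bool:
        return any(0 < f < 1 for f in self._founder_inbreeding.values())

    def _check(self, iid) -> str:
        iid = str(iid)
        if iid not in self._topo_index:
            raise PedigreeError(f"unknown individual {iid!r}")
        return iid

    def topo_index(self, iid) -> int:
        return self._topo_index[self._check(iid)]

    def is_ancestor(self, anc, desc) -> bool:
        """True if ``anc`` is an ancestor of ``desc`` (strict)."""
        ia, id_ = self.topo_index(anc), self.topo_index(desc)
        return ia != id_ and bool(self._anc[id_] >> ia & 1)

    def related(self, a, b) -> bool:
        """True if a and b have any common ancestor (including themselves)."""
        return bool(self._anc[self.topo_index(a)] & self._anc[self.topo_index(b)])

    def connected_pair(self, a, b) -> bool:
        """Whether a path exists between a and b in the pedigree graph."""
        comp = {self._check(a)}
        frontier = [self._check(a)]
        children: dict[str, list[str]] = {}
        for c in self.nonfounders:
            children.setdefault(self._father[c], []).append(c)
            children.setdefault(self._mother[c], []).append(c)
        while frontier:
            x = frontier.pop()
            nbrs = [p for p in (self._father.get(x), self._mother.get(x)) if p]
            nbrs += children.get(x, [])
            for y in nbrs:
                if y not in comp:
                    comp.add(y)
                    frontier.append(y)
        return self._check(b) in comp

    # -- functional updates ------------------------------------------------

    def _rows(self) -> list[tuple]:
        rows = []
        for iid in self._declared_order:
            rows.append(
                (iid, self._father.get(iid), self._mother.get(iid), self._sex.get(iid))
            )
        return rows


class RelationshipClass(NamedTuple):
    """Classification of a pairwise relationship.

    ``lineality`` is ``"unilineal"`` (kappa2 = 0), ``"bilineal"`` (kappa2 > 0)
    or ``"not-applicable"`` when either individual is inbred.
    """

    inbred_a: bool
    inbred_b: bool
    lineality: str
    direct: bool


# ---------------------------------------------------------------------------
# I/O


def load_pedigree(source) -> Pedigree:
    """Read a PLINK-style whitespace-delimited pedigree.

    ``source`` may be a path, a file object, or a string containing the table
    itself (detected by the presence of a newline).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if not s.strip():
            raise PedigreeError("empty pedigree file")
        if "\n" in s or (len(s.split()) in (3, 4) and " " in s):
            text = s
        else:
            with open(s, "rt") as fh:
                text = fh.read()
    rows = []
    fi = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if len(fields) == 3 and fields[0] == "founder-inbreeding":
                fi[fields[1]] = float(fields[2])
            continue
        fields = line.split()
        if len(fields) not in (3, 4):
            raise PedigreeError(f"expected 3 or 4 columns, got {line!r}")
        rows.append(tuple(fields))
    if not rows:
        raise PedigreeError("empty pedigree file")
    return Pedigree(rows, founder_inbreeding=fi)


def write_pedigree(ped: Pedigree, target=None) -> str:
    """Write ``ped`` in the same format accepted by :func:`load_pedigree`.

    Returns the text; if ``target`` (path or file object) is given, also
    writes it there.  Round-trips through :func:`load_pedigree` to an equal
    pedigree.  Founder inbreeding is emitted as comments for human readers
    (it is an annotation, not part of the PLINK columns).
    """
    has_sex = any(ped.sex(i) != "unknown" for i in ped.members)
    lines = []
    for f in sorted(ped._founder_inbreeding):
        lines.append(f"# founder-inbreeding {f} {ped._founder_inbreeding[f]}")
    sexcode = {"male": "1", "female": "2", "unknown": "0"}
    for iid in ped.members:
        cols = [iid, ped.father(iid) or "0", ped.mother(iid) or "0"]
        if has_sex:
            cols.append(sexcode[ped.sex(iid)])
        lines.append(" ".join(cols))
    text = "\n".join(lines) + "\n"
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "wt") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Annotation and extension


def set_founder_inbreeding(ped: Pedigree, iid, f) -> Pedigree:
    """Return a copy of ``ped`` with founder ``iid`` assigned inbreeding ``f``.

    Any f in [0, 1] is accepted here; single-locus operations support partial
    values, while two-locus operations reject 0 < f < 1 at call time.
    """
    iid = ped._check(iid)
    if not ped.is_founder(iid):
        raise PedigreeError(f"{iid!r} is not a founder")
    if not 0 <= f <= 1:
        raise PedigreeError(f"founder inbreeding must lie in [0, 1], got {f}")
    fi = dict(ped._founder_inbreeding)
    fi.pop(iid, None)
    if f:
        fi[iid] = f
    return Pedigree(ped._rows(), founder_inbreeding=fi)


def extend_with_parents(ped: Pedigree, iid) -> Pedigree:
    """Attach two fresh unrelated founders as parents of founder ``iid``.

    This leaves every coefficient of pre-existing pairs unchanged, and is the
    standard device for applying identity-coefficient formulas (which address
    the four parental gametes) to founder individuals.  A completely inbred
    founder cannot be extended: no pair of parents reproduces f = 1.
    """
    iid = ped._check(iid)
    if not ped.is_founder(iid):
        raise PedigreeError(f"cannot extend at {iid!r}: not a founder")
    f = ped.founder_inbreeding(iid)
    if f >= 1:
        raise UnsupportedFounderInbreedingError(
            f"cannot extend at completely inbred founder {iid!r}"
        )
    names = []
    for tag in ("f", "m"):
        name = f"{iid}_{tag}"
        while name in ped or name in names:
            name += "_"
        names.append(name)
    rows = [(names[0], None, None, None), (names[1], None, None, None)]
    for row in ped._rows():
        if row[0] == iid:
            row = (iid, names[0], names[1], row[3])
        rows.append(row)
    fi = dict(ped._founder_inbreeding)
    fi.pop(iid, None)
    if f:
        # preserve partial founder inbreeding by pushing it onto the new
        # parents' kinship: not representable; instead keep annotation illegal.
        raise UnsupportedFounderInbreedingError(
            f"cannot extend founder {iid!r} with partial inbreeding f={f}"
        )
    return Pedigree(rows, founder_inbreeding=fi)


def classify(ped: Pedigree, a, b) -> RelationshipClass:
    """Classify the relationship between ``a`` and ``b``.

    Inbreeding is read off the parents' kinship (or the founder annotation);
    lineality is decided by kappa2, computed from parental kinships when both
    individuals are nonfounders and by descent logic otherwise: a bilineal
    pair is necessarily collateral with both members nonfounders.
    """
    from .single import _inbreeding_of, kinship

    a, b = ped._check(a), ped._check(b)
    fa_, fb_ = _inbreeding_of(ped, a), _inbreeding_of(ped, b)
    direct = a != b and (ped.is_ancestor(a, b) or ped.is_ancestor(b, a))
    if fa_ > 0 or fb_ > 0:
        lineality = "not-applicable"
    elif a == b:
        lineality = "bilineal"  # kappa2 = 1 for a noninbred self-pair
    elif ped.is_founder(a) or ped.is_founder(b) or direct:
        lineality = "unilineal"
    else:
        f, g = ped.father(a), ped.mother(a)
        m, n = ped.father(b), ped.mother(b)
        k2 = kinship(ped, f, m) * kinship(ped, g, n) + kinship(ped, f, n) * kinship(
            ped, g, m
        )
        lineality = "bilineal" if k2 > 0 else "unilineal"
    return RelationshipClass(fa_ > 0, fb_ > 0, lineality, direct)


# ---------------------------------------------------------------------------
# Fixture relationships


class Fixture(NamedTuple):
    pedigree: Pedigree
    pair: tuple[str, str]


def _ped(trios, fi=None):
    return Pedigree([(str(a), b and str(b), c and str(c)) for a, b, c in trios], fi)


def _fx_parent_offspring() -> Fixture:
    """Parent and child; pair = (parent, child)."""
    return Fixture(_ped([(1, 0, 0), (2, 0, 0), (3, 1, 2)]), ("1", "3"))


def _fx_grandparent() -> Fixture:
    """Grandparent and grandchild."""
    p = _ped([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 0, 0), (5, 3, 4)])
    return Fixture(p, ("1", "5"))


def _fx_half_sibs() -> Fixture:
    """Half siblings 4, 5 with shared parent 2 (founders 1, 2, 3)."""
    p = _ped([(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 1, 2), (5, 3, 2)])
    return Fixture(p, ("4", "5"))


def _fx_full_sibs() -> Fixture:
    """Full siblings."""
    p = _ped([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2)])
    return Fixture(p, ("3", "4"))


def _fx_cousins(p: int = 1, q: int = 1, half: bool = False) -> Fixture:
    """Cousin-type relationships.

    Two siblings (half siblings if ``half``) head two descending lines of
    lengths ``p`` and ``q``; the pair are the line ends.  (1, 1) gives first
    cousins, (0, 1) uncle--nephew, (0, 2) great-uncle, (2, 2) second cousins.
    """
    if p < 0 or q < 0:
        raise PedigreeError("cousin line lengths must be nonnegative")
    trios = [(1, 0, 0), (2, 0, 0), (3, 1, 2)]
    nxt = 4
    if half:
        trios += [(4, 0, 0), (5, 1, 4)]
        top_b = 5
        nxt = 6
    else:
        trios += [(4, 1, 2)]
        top_b = 4
        nxt = 5
    ends = []
    for top, length in ((3, p), (top_b, q)):
        cur = top
        for _ in range(length):
            spouse, child = nxt, nxt + 1
            trios += [(spouse, 0, 0), (child, cur, spouse)]
            cur = child
            nxt += 2
        ends.append(str(cur))
    return Fixture(_ped(trios), (ends[0], ends[1]))


def _fx_sibs_of_halfsib_parents() -> Fixture:
    """Full siblings whose parents are half siblings (7 members)."""
    p = _ped(
        [(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 1, 2), (5, 3, 2), (6, 4, 5), (7, 4, 5)]
    )
    return Fixture(p, ("6", "7"))


def _fx_sib_mating_sibs(generations: int = 1) -> Fixture:
    """Siblings after ``generations`` rounds of brother-sister mating."""
    if generations < 1:
        raise PedigreeError("generations must be >= 1")
    trios = [(1, 0, 0), (2, 0, 0)]
    pa, ma = 1, 2
    nxt = 3
    for _ in range(generations + 1):
        c1, c2 = nxt, nxt + 1
        trios += [(c1, pa, ma), (c2, pa, ma)]
        pa, ma = c1, c2
        nxt += 2
    return Fixture(_ped(trios), (str(pa), str(ma)))


def _fx_quad_half_first_cousins() -> Fixture:
    """Quadruple half first cousins: four half-sib links among the parents."""
    p = _ped(
        [
            (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0),
            (5, 1, 2), (6, 3, 4), (7, 1, 4), (8, 3, 2),
            (9, 5, 6), (10, 7, 8),
        ]
    )
    return Fixture(p, ("9", "10"))


def _fx_hs_plus_half_second_cousins() -> Fixture:
    """Simultaneous half siblings and half second cousins.

    11 and 12 share parent 10, and their other parents (7, 9) are half first
    cousins through the shared grandparent 1.
    """
    p = _ped(
        [
            (1, 0, 0), (2, 0, 0), (3, 0, 0),
            (4, 1, 2), (5, 1, 3),
            (6, 0, 0), (7, 4, 6),
            (8, 0, 0), (9, 5, 8),
            (10, 0, 0), (11, 7, 10), (12, 9, 10),
        ]
    )
    return Fixture(p, ("11", "12"))


def _fx_double_second_cousins_A() -> Fixture:
    """Double second cousins (type A): fathers are first cousins, and so are
    the mothers, through two unrelated ancestral families."""
    p = _ped(
        [
            (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0),
            (5, 1, 2), (6, 1, 2), (7, 3, 4), (8, 3, 4),
            (9, 0, 0), (10, 0, 0), (11, 0, 0), (12, 0, 0),
            (13, 5, 9), (14, 6, 10), (15, 7, 11), (16, 8, 12),
            (17, 13, 15), (18, 14, 16),
        ]
    )
    return Fixture(p, ("17", "18"))


def _fx_first_plus_second_cousins() -> Fixture:
    """Simultaneous first cousins (through the fathers, who are siblings) and
    second cousins (through the mothers, who are first cousins)."""
    p = _ped(
        [
            (1, 0, 0), (2, 0, 0),
            (5, 1, 2), (6, 1, 2),
            (3, 0, 0), (4, 0, 0),
            (7, 3, 4), (8, 3, 4),
            (9, 0, 0), (10, 0, 0),
            (11, 7, 9), (12, 8, 10),
            (13, 5, 11), (14, 6, 12),
        ]
    )
    return Fixture(p, ("13", "14"))


FIXTURES = {
    "parent_offspring": _fx_parent_offspring,
    "grandparent": _fx_grandparent,
    "half_sibs": _fx_half_sibs,
    "full_sibs": _fx_full_sibs,
    "cousins": _fx_cousins,
    "sibs_of_halfsib_parents": _fx_sibs_of_halfsib_parents,
    "sib_mating_sibs": _fx_sib_mating_sibs,
    "quad_half_first_cousins": _fx_quad_half_first_cousins,
    "hs_plus_half_second_cousins": _fx_hs_plus_half_second_cousins,
    "double_second_cousins_A": _fx_double_second_cousins_A,
    "first_plus_second_cousins": _fx_first_plus_second_cousins,
}


def make_fixture(name: str, *params) -> Fixture:
    """Build a named fixture relationship; returns (pedigree, target pair)."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise PedigreeError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None
    return builder(*params)
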