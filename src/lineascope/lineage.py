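"""Sulston-style lineage names and the invariant division tree.

Embryonic C. elegans cells are named by their division history: a founder
prefix (AB, MS, E, C, D, P0-P4, EMS, Z2, Z3) followed by one letter per
division encoding the daughter's position along the embryo's axes --
a(nterior)/p(osterior), l(eft)/r(ight), d(orsal)/v(entral).  The name
therefore uniquely determines the full ancestor chain, which makes tree
navigation a matter of string manipulation plus a small fixed table for
the early (founder) divisions.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

SUFFIX_LETTERS = frozenset("aplrdv")

#: Fixed parent relationships among the founder cells.
FOUNDER_PARENT = {
    "AB": "P0", "P1": "P0",
    "EMS": "P1", "P2": "P1",
    "MS": "EMS", "E": "EMS",
    "C": "P2", "P3": "P2",
    "D": "P3", "P4": "P3",
    "Z2": "P4", "Z3": "P4",
}

#: Founder daughter pairs, ordered (anterior-like, posterior-like).
FOUNDER_DAUGHTERS = {
    "P0": ("AB", "P1"),
    "P1": ("EMS", "P2"),
    "EMS": ("MS", "E"),
    "P2": ("C", "P3"),
    "P3": ("D", "P4"),
    "P4": ("Z2", "Z3"),
}

FOUNDERS = frozenset(FOUNDER_PARENT) | {"P0"}

# Longest-prefix-first so "EMS" wins over "E" and "P4" over nothing.
_FOUNDERS_BY_LENGTH = sorted(FOUNDERS, key=len, reverse=True)

_SISTER_SWAP = {"a": "p", "p": "a", "l": "r", "r": "l", "d": "v", "v": "d"}


class NamingError(ValueError):
    """An invalid Sulston name or pattern."""


class LookupError_(KeyError):
    """A cell absent from the tree under analysis."""


def split_name(name: str) -> tuple[str, str]:
    """Split a name into (founder, division suffix); raise NamingError if invalid."""
    if not isinstance(name, str) or not name:
        raise NamingError(f"empty or non-string cell name: {name!r}")
    for founder in _FOUNDERS_BY_LENGTH:
        if name.startswith(founder):
            suffix = name[len(founder):]
            if all(c in SUFFIX_LETTERS for c in suffix):
                return founder, suffix
    raise NamingError(f"not a valid Sulston name: {name!r}")


def is_valid_name(name: str) -> bool:
    try:
        split_name(name)
    except NamingError:
        return False
    return True


def parent_name(cell: str) -> str:
    """Name of the mother cell; NamingError on invalid input, on P0 a root error."""
    founder, suffix = split_name(cell)
    if suffix:
        return cell[:-1]
    if founder == "P0":
        raise NamingError("P0 is the zygote and has no parent")
    return FOUNDER_PARENT[founder]


def sister_name(cell: str) -> str | None:
    """Syntactic sister: the other daughter of the same division.

    Founder sisters come from the fixed table (e.g. AB <-> P1); for
    suffix-named cells the last letter is swapped within its axis pair.
    Returns None only for P0.
    """
    founder, suffix = split_name(cell)
    if suffix:
        return cell[:-1] + _SISTER_SWAP[cell[-1]]
    if founder == "P0":
        return None
    mother = FOUNDER_PARENT[founder]
    a, b = FOUNDER_DAUGHTERS[mother]
    return b if cell == a else a


def ancestor_chain(cell: str) -> list[str]:
    """[cell, parent, grandparent, ..., P0]."""
    chain = [cell]
    while chain[-1] != "P0":
        chain.append(parent_name(chain[-1]))
    return chain


def contralateral_name(cell: str) -> str | None:
    """Mirror-image name across the left/right axis.

    Swaps the first l/r letter (the convention for bilaterally symmetric
    sublineages); None for midline names with no l/r letter.  Purely
    syntactic -- anatomical homologs that break the naming mirror are not
    resolved here.
    """
    split_name(cell)
    for i, c in enumerate(cell):
        if c == "l":
            return cell[:i] + "r" + cell[i + 1:]
        if c == "r":
            return cell[:i] + "l" + cell[i + 1:]
    return None


def _wildcard_equal(name: str, pattern_founder: str, pattern_suffix: str) -> bool:
    try:
        founder, suffix = split_name(name)
    except NamingError:
        return False
    if founder != pattern_founder or len(suffix) != len(pattern_suffix):
        return False
    for got, want in zip(suffix, pattern_suffix):
        if want == "x":
            if got not in ("l", "r"):
                return False
        elif got != want:
            return False
    return True


def matches_pattern(cell: str, pattern: str) -> bool:
    """True iff `cell` equals or descends from a cell matching `pattern`.

    A pattern is a Sulston name in which any suffix letter may be "x",
    a wildcard for l or r ("ABpxp" = ABplp plus ABprp sublineages).
    """
    for founder in _FOUNDERS_BY_LENGTH:
        if pattern.startswith(founder):
            psuffix = pattern[len(founder):]
            if all(c in SUFFIX_LETTERS or c == "x" for c in psuffix):
                pfounder = founder
                break
    else:
        raise NamingError(f"not a valid name pattern: {pattern!r}")
    if not is_valid_name(cell):
        raise NamingError(f"not a valid Sulston name: {cell!r}")
    return any(
        _wildcard_equal(anc, pfounder, psuffix) for anc in ancestor_chain(cell)
    )


class LineageTree:
    """The invariant division tree: nodes, parent/daughter edges, death fates.

    Fates are one of ``divides`` (internal, exactly two daughters),
    ``death`` (programmed cell death, a leaf), or ``terminal`` (alive at
    the analysis endpoint, a leaf).
    """

    def __init__(self, fates: dict[str, str]):
        for cell in fates:
            split_name(cell)  # raises on bad names ('x' is reserved)
            if "x" in split_name(cell)[1]:
                raise NamingError(f"'x' is reserved for patterns: {cell!r}")
        self.fates = dict(fates)
        self._children: dict[str, list[str]] = {c: [] for c in fates}
        for cell in fates:
            if cell == "P0":
                continue
            par = parent_name(cell)
            if par in self._children:
                self._children[par].append(cell)
            elif cell not in FOUNDERS:
                raise NamingError(f"orphan cell {cell!r}: parent {par!r} not in tree")
        for kids in self._children.values():
            kids.sort()
        self._validate()

    def _validate(self) -> None:
        for cell, fate in self.fates.items():
            nkids = len(self._children[cell])
            if fate == "divides" and nkids != 2:
                raise ValueError(f"{cell}: fate=divides but {nkids} daughters present")
            if fate in ("death", "terminal") and nkids != 0:
                raise ValueError(f"{cell}: fate={fate} but has daughters")

    # -- navigation ---------------------------------------------------------

    def __contains__(self, cell: str) -> bool:
        return cell in self.fates

    def __len__(self) -> int:
        return len(self.fates)

    def cells(self) -> Iterator[str]:
        return iter(self.fates)

    def children(self, cell: str) -> list[str]:
        if cell not in self.fates:
            raise LookupError_(cell)
        return list(self._children[cell])

    def parent(self, cell: str) -> str | None:
        if cell not in self.fates:
            raise LookupError_(cell)
        try:
            par = parent_name(cell)
        except NamingError:
            return None
        return par if par in self.fates else None

    def sister(self, cell: str) -> str | None:
        """The other daughter of this cell's mother, if inside the tree."""
        if cell not in self.fates:
            raise LookupError_(cell)
        sis = sister_name(cell)
        return sis if sis is not None and sis in self.fates else None

    def descendants(self, cell: str) -> list[str]:
        """All strict descendants of `cell` in the tree (preorder)."""
        if cell not in self.fates:
            raise LookupError_(cell)
        out: list[str] = []
        stack = list(self._children[cell])
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self._children[c])
        return out

    @property
    def leaves(self) -> list[str]:
        return [c for c, f in self.fates.items() if f != "divides"]

    @property
    def deaths(self) -> set[str]:
        return {c for c, f in self.fates.items() if f == "death"}

    @property
    def terminals(self) -> list[str]:
        return [c for c, f in self.fates.items() if f == "terminal"]

    def select(self, pattern: str) -> list[str]:
        """All tree cells matching a wildcard pattern (see matches_pattern)."""
        return [c for c in self.fates if matches_pattern(c, pattern)]

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageTree":
        """Read a (cell, fate, ...) tab-separated template; extra columns ignored."""
        fates = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["cell", "fate"]:
                raise ValueError(f"template must start with columns cell, fate; got {header[:2]}")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                fates[parts[0]] = parts[1]
        return cls(fates)

    @classmethod
    def packaged(cls) -> "LineageTree":
        """The synthetic ~350-leaf template shipped with the package."""
        return cls.from_tsv(packaged_template_path())


@lru_cache(maxsize=1)
def packaged_template_path() -> Path:
    return Path(resources.files("lineascope").joinpath("data/lineage_template.tsv"))


def sister_pairs(cells: Iterable[str]) -> list[tuple[str, str]]:
    """All unordered sister pairs fully contained in `cells` (syntactic sisters)."""
    cellset = set(cells)
    pairs = []
    for c in cellset:
        s = sister_name(c)
        if s is not None and s in cellset and c < s:
            pairs.append((c, s))
    return pairs
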