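"""Reporter expression on the lineage: footprints, overlap, L/R symmetry.

Expression is a boolean on/off interval per cell (intensity thresholding
belongs upstream).  The terminal footprint of a pattern is the set of
terminal cells with any expressing ancestor-or-self; overlap between two
reporters in a cell is ``simultaneous`` when their intervals intersect and
``sequential`` when both express but the intervals are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .lineage import LineageTree, NamingError, contralateral_name, is_valid_name


@dataclass
class ExpressionPattern:
    reporter: str
    calls: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell, (on, off) in self.calls.items():
            if not is_valid_name(cell):
                raise NamingError(f"invalid cell name {cell!r} in pattern")
            if not on < off:
                raise ValueError(f"{cell}: on_time must precede off_time")

    @property
    def cells(self) -> set[str]:
        return set(self.calls)

    def add(self, cell: str, on: float, off: float) -> None:
        """Add an interval, merging with an existing one for the same cell."""
        if cell in self.calls:
            o, f = self.calls[cell]
            on, off = min(on, o), max(off, f)
        self.calls[cell] = (on, off)

    @classmethod
    def from_csv(cls, path: str | Path, reporter: str | None = None,
                 ) -> "ExpressionPattern":
        """Read an expression CSV: reporter, cell, on_time_min, off_time_min."""
        df = pd.read_csv(path)
        need = {"reporter", "cell", "on_time_min", "off_time_min"}
        if not need <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(need)}")
        if reporter is not None:
            df = df[df["reporter"] == reporter]
        else:
            reporters = df["reporter"].unique()
            if len(reporters) != 1:
                raise ValueError(f"{path}: several reporters {list(reporters)}; pick one")
            reporter = reporters[0]
        pat = cls(reporter)
        for _, row in df.iterrows():
            pat.add(row["cell"], float(row["on_time_min"]), float(row["off_time_min"]))
        return pat

    def to_csv(self, path: str | Path) -> None:
        rows = [(self.reporter, c, on, off)
                for c, (on, off) in sorted(self.calls.items())]
        pd.DataFrame(rows, columns=["reporter", "cell", "on_time_min",
                                    "off_time_min"]).to_csv(path, index=False)


def terminal_footprint(pattern: ExpressionPattern, tree: LineageTree) -> set[str]:
    """Terminal cells (leaves) with an expressing ancestor-or-self."""
    for cell in pattern.cells:
        if cell not in tree:
            raise NamingError(f"expressing cell {cell!r} not in tree")
    out: set[str] = set()
    for cell in pattern.cells:
        if tree.fates[cell] != "divides":
            out.add(cell)
        else:
            out.update(d for d in tree.descendants(cell)
                       if tree.fates[d] != "divides")
    return out


def overlap_classify(pattern_a: ExpressionPattern, pattern_b: ExpressionPattern,
                     tree: LineageTree) -> dict[str, str]:
    """Per-cell overlap class: none / a_only / b_only / simultaneous / sequential."""
    out = {}
    for cell in tree.cells():
        in_a, in_b = cell in pattern_a.calls, cell in pattern_b.calls
        if in_a and in_b:
            a_on, a_off = pattern_a.calls[cell]
            b_on, b_off = pattern_b.calls[cell]
            touches = a_on <= b_off and b_on <= a_off
            out[cell] = "simultaneous" if touches else "sequential"
        elif in_a:
            out[cell] = "a_only"
        elif in_b:
            out[cell] = "b_only"
        else:
            out[cell] = "none"
    return out


def lr_symmetry_fraction(pattern: ExpressionPattern, tree: LineageTree | None = None,
                         ) -> float:
    """Fraction of lateral expressing cells whose mirror-image cell also
    expresses.  Midline cells (no l/r letter) are excluded from the
    denominator."""
    if not pattern.cells:
        raise ValueError("pattern is empty")
    lateral = [c for c in pattern.cells if contralateral_name(c) is not None]
    if not lateral:
        return float("nan")
    paired = sum(1 for c in lateral if contralateral_name(c) in pattern.cells)
    return paired / len(lateral)
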