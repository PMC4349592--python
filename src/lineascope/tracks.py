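"""Embryo track records and their on-disk formats.

An :class:`EmbryoRecord` is one embryo's observed 4D history: for every
tracked cell a birth time, an end time, an end fate (``divided``, ``died``,
``tracked_to_end`` or ``lost``) and a position time series in µm.  Times
are minutes on the embryo's own clock (origin at the first observed
timepoint); placement in space is arbitrary until alignment.

Two readers are provided: the canonical tidy CSV (one row per cell per
timepoint) and a directory of per-timepoint ``t<NNN>-nuclei`` files as
written by StarryNite/AceTree-style trackers, linked into tracks via their
predecessor/successor indices.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lineage
from .config import AnalysisConfig
from .errors import FormatError

log = logging.getLogger(__name__)

END_FATES = ("divided", "died", "tracked_to_end", "lost")

CSV_COLUMNS = ["embryo_id", "cell", "time_min", "x_um", "y_um", "z_um", "end_fate"]


@dataclass
class CellTrack:
    birth_time: float
    end_time: float
    end_fate: str
    positions: np.ndarray  # (n, 4) columns: time_min, x_um, y_um, z_um

    def pos_at(self, t: float) -> np.ndarray:
        """Linear interpolation of the track at time `t` (clamped to ends)."""
        p = self.positions
        return np.array([np.interp(t, p[:, 0], p[:, 1 + i]) for i in range(3)])

    @property
    def times(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def xyz(self) -> np.ndarray:
        return self.positions[:, 1:4]


@dataclass
class EmbryoRecord:
    embryo_id: str
    genotype: str
    cells: dict[str, CellTrack]
    sampling_min: float = 1.5
    meta: dict = field(default_factory=dict)

    def __contains__(self, cell: str) -> bool:
        return cell in self.cells

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def divided_cells(self) -> list[str]:
        return [c for c, t in self.cells.items() if t.end_fate == "divided"]

    def copy(self) -> "EmbryoRecord":
        return EmbryoRecord(
            embryo_id=self.embryo_id,
            genotype=self.genotype,
            cells={
                c: CellTrack(t.birth_time, t.end_time, t.end_fate, t.positions.copy())
                for c, t in self.cells.items()
            },
            sampling_min=self.sampling_min,
            meta=dict(self.meta),
        )


def validate_embryo(embryo: EmbryoRecord, tree: lineage.LineageTree | None = None) -> None:
    """Raise FormatError on any structural violation; no partial acceptance.

    Checks per-cell time ordering, daughter presence and birth continuity
    for divided cells, and (when a tree is given) name membership.
    """
    problems: list[str] = []
    tol = embryo.sampling_min + 1e-6
    for cell, tr in embryo.cells.items():
        if not lineage.is_valid_name(cell):
            problems.append(f"{cell}: invalid Sulston name")
            continue
        if tr.end_fate not in END_FATES:
            problems.append(f"{cell}: unknown end_fate {tr.end_fate!r}")
        if tr.positions.shape[0] == 0:
            problems.append(f"{cell}: empty position track")
            continue
        t = tr.positions[:, 0]
        if np.any(np.diff(t) <= 0):
            problems.append(f"{cell}: non-monotone position times")
        if t[0] < tr.birth_time - tol or t[-1] > tr.end_time + tol:
            problems.append(f"{cell}: positions outside [birth, end]")
        if tr.birth_time > tr.end_time:
            problems.append(f"{cell}: birth_time > end_time")
        if tree is not None and cell not in tree:
            problems.append(f"{cell}: not in lineage template")
        # orphan check: parent must be present unless the cell starts the record
        try:
            par = lineage.parent_name(cell)
        except lineage.NamingError:
            par = None
        if par is not None and par not in embryo.cells:
            grand_ok = cell in lineage.FOUNDERS
            starts_record = tr.birth_time <= min(
                c.birth_time for c in embryo.cells.values()
            ) + tol
            if not (grand_ok or starts_record):
                problems.append(f"{cell}: orphan (parent {par} absent)")
        if par is not None and par in embryo.cells:
            ptr = embryo.cells[par]
            if ptr.end_fate != "divided":
                problems.append(f"{cell}: parent {par} present but end_fate != divided")
            elif abs(tr.birth_time - ptr.end_time) > tol:
                problems.append(
                    f"{cell}: birth {tr.birth_time:.2f} != parent end {ptr.end_time:.2f}"
                )
    for cell, tr in embryo.cells.items():
        if tr.end_fate == "divided":
            kids = [k for k in embryo.cells if lineage.is_valid_name(k)
                    and k != cell and _is_child(k, cell)]
            if len(kids) != 2:
                problems.append(f"{cell}: end_fate=divided but {len(kids)} daughters tracked")
    if problems:
        raise FormatError(
            f"embryo {embryo.embryo_id}: {len(problems)} validation problems:\n  "
            + "\n  ".join(problems[:25])
        )


def _is_child(child: str, parent: str) -> bool:
    try:
        return lineage.parent_name(child) == parent
    except lineage.NamingError:
        return False


# ---------------------------------------------------------------------------
# canonical tidy CSV
# ---------------------------------------------------------------------------

def write_embryo_csv(embryo: EmbryoRecord, path: str | Path) -> None:
    """Write the canonical tidy CSV (one row per cell per timepoint)."""
    rows = []
    for cell in sorted(embryo.cells):
        tr = embryo.cells[cell]
        n = tr.positions.shape[0]
        for i in range(n):
            t, x, y, z = tr.positions[i]
            rows.append((
                embryo.embryo_id, cell, round(t, 3),
                round(x, 3), round(y, 3), round(z, 3),
                tr.end_fate if i == n - 1 else "",
            ))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.attrs["genotype"] = embryo.genotype
    with open(path, "w") as fh:
        fh.write(f"# genotype={embryo.genotype} sampling_min={embryo.sampling_min}\n")
        df.to_csv(fh, index=False)


def read_embryo_csv(path: str | Path,
                    tree: lineage.LineageTree | None = None) -> EmbryoRecord:
    """Read the canonical tidy CSV into a validated EmbryoRecord."""
    path = Path(path)
    genotype, sampling = "unknown", 1.5
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"genotype=(\S+)", first)
            if m:
                genotype = m.group(1)
            m = re.search(r"sampling_min=([\d.]+)", first)
            if m:
                sampling = float(m.group(1))
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path}: no rows")
    cells: dict[str, CellTrack] = {}
    eid = str(df["embryo_id"].iloc[0])
    for cell, grp in df.groupby("cell", sort=True):
        grp = grp.sort_values("time_min")
        pos = grp[["time_min", "x_um", "y_um", "z_um"]].to_numpy(float)
        fates = [f for f in grp["end_fate"].tolist() if isinstance(f, str) and f]
        if not fates:
            raise FormatError(f"{path}: cell {cell} has no end_fate on its final row")
        cells[str(cell)] = CellTrack(
            birth_time=float(pos[0, 0]),
            end_time=float(pos[-1, 0]),
            end_fate=fates[-1],
            positions=pos,
        )
    embryo = EmbryoRecord(eid, genotype, cells, sampling_min=sampling)
    validate_embryo(embryo, tree)
    return embryo


# ---------------------------------------------------------------------------
# per-timepoint nuclei files (StarryNite/AceTree-style)
# ---------------------------------------------------------------------------

_NUCLEI_RE = re.compile(r"t(\d+)-nuclei$")


def read_nuclei_dir(path: str | Path,
                    config: AnalysisConfig | None = None,
                    tree: lineage.LineageTree | None = None,
                    embryo_id: str | None = None,
                    genotype: str = "unknown") -> EmbryoRecord:
    """Link per-timepoint nuclei files into an EmbryoRecord.

    Each file ``t<NNN>-nuclei`` holds comma-separated rows:
    index, valid-flag, predecessor-index, successor1-index,
    successor2-index, x, y, z, diameter, cell-name.  Rows are linked
    across consecutive timepoints through the index fields; a row with two
    successors is a division; a named track that terminates and carries a
    death annotation in the template is a death.  Pixel x/y and plane z
    are converted to µm with the configured scale factors.
    """
    config = config or AnalysisConfig()
    path = Path(path)
    files: list[tuple[int, Path]] = []
    for f in path.iterdir():
        m = _NUCLEI_RE.search(f.name)
        if m:
            files.append((int(m.group(1)), f))
    if not files:
        raise FormatError(f"{path}: no t<NNN>-nuclei files found")
    files.sort()
    frames: dict[int, dict[int, tuple]] = {}
    for tp, f in files:
        rows: dict[int, tuple] = {}
        seen_names: set[str] = set()
        for ln, line in enumerate(f.read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 10:
                raise FormatError(f"{f.name}:{ln}: expected 10 fields, got {len(parts)}")
            idx, valid, pred, s1, s2 = (int(parts[i]) for i in range(5))
            if valid == 0:
                continue
            x, y, z = float(parts[5]), float(parts[6]), float(parts[7])
            name = parts[9]
            if name and name in seen_names:
                raise FormatError(f"{f.name}:{ln}: duplicated name {name!r}")
            if name:
                seen_names.add(name)
            rows[idx] = (pred, s1, s2, x, y, z, name)
        frames[tp] = rows
    tps = sorted(frames)
    # timepoint numbers are frame indices; convert to minutes via the cadence
    sampling = config.sampling_min

    cells: dict[str, CellTrack] = {}
    visited: set[tuple[int, int]] = set()

    def walk(tp_i: int, idx: int) -> None:
        """Follow successor links from (timepoint, index) to build one track."""
        samples = []
        cur_tp, cur_idx = tp_i, idx
        name = ""
        while True:
            if (cur_tp, cur_idx) in visited:
                raise FormatError(f"broken links: revisited t{tps[cur_tp]} index {cur_idx}")
            visited.add((cur_tp, cur_idx))
            row = frames[tps[cur_tp]].get(cur_idx)
            if row is None:
                raise FormatError(f"broken link into t{tps[cur_tp]} index {cur_idx}")
            pred, s1, s2, x, y, z, nm = row
            if nm:
                name = nm
            samples.append((
                (tps[cur_tp] - tps[0]) * sampling,
                x * config.xy_um_per_px,
                y * config.xy_um_per_px,
                z * config.z_um_per_plane,
            ))
            two = s1 > 0 and s2 > 0
            if two or cur_tp + 1 >= len(tps) or s1 <= 0:
                fate = "divided" if two else (
                    "tracked_to_end" if cur_tp + 1 >= len(tps) else "terminated")
                _finish(name, samples, fate, (cur_tp, s1, s2) if two else None)
                return
            cur_tp, cur_idx = cur_tp + 1, s1

    division_follow: list[tuple[int, int]] = []

    def _finish(name: str, samples: list, fate: str, div) -> None:
        if not name or name.startswith("Nuc"):
            log.warning("dropping unnamed/artifact track (%d samples)", len(samples))
        else:
            pos = np.asarray(samples, float)
            if fate == "terminated":
                fate = ("died" if tree is not None and name in tree.deaths
                        else "lost")
            cells[name] = CellTrack(pos[0, 0], pos[-1, 0], fate, pos)
        if div is not None:
            tp_i, s1, s2 = div
            division_follow.extend([(tp_i + 1, s1), (tp_i + 1, s2)])

    # roots: rows of the first timepoint plus unvisited successors
    for idx in sorted(frames[tps[0]]):
        walk(0, idx)
    while division_follow:
        tp_i, idx = division_follow.pop(0)
        if (tp_i, idx) not in visited:
            walk(tp_i, idx)

    eid = embryo_id or path.name
    embryo = EmbryoRecord(eid, genotype, cells, sampling_min=sampling)
    validate_embryo(embryo, tree)
    return embryo
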