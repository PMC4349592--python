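"""Per-cell defect calling against the wild-type reference.

Calling rules:

* cell-cycle defects: a division is deviant only when its cycle length
  differs from the wild-type mean by more than ``cycle_sd_mult`` standard
  deviations AND by at least ``cycle_min_delta`` minutes (default 3 SD and
  5 min), called as ``cycle_early`` or ``cycle_late``; a cell that should
  divide but has not, well past its expected division time, is a
  ``missed_division``; a division of a cell the reference holds terminal
  is an ``extra_division``.
* death defects: a programmed death that survives well past its expected
  death time is a ``missed_death``; if the survivor divides it is
  additionally an ``extra_division``.
* position defects: a cell is mispositioned only when its mean OR maximum
  deviation from the expected (aligned, canonical) position exceeds the
  wild-type baseline by more than ``pos_sd_mult`` standard deviations AND
  its neighbor-distance score is equally deviant.  The neighbor-distance
  score -- the mean distance to the identities of the cell's nearest
  wild-type neighbors, measured in the mutant -- detects displacement
  relative to local context, which suppresses spurious calls when a whole
  neighborhood moves rigidly.

Cells descending from a missed/extra division have no unambiguous
reference identity and are excluded from position calling ("shadowed").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .errors import StateError
from .lineage import parent_name, NamingError
from .reference import ReferenceModel, RigidTransform, TemporalMap
from .tracks import EmbryoRecord

log = logging.getLogger(__name__)

CATEGORIES = ("cycle_early", "cycle_late", "missed_division", "extra_division",
              "missed_death", "position")

TIMING_CATEGORIES = ("cycle_early", "cycle_late")


@dataclass
class DefectCall:
    embryo_id: str
    cell: str
    category: str
    delta_minutes: float = float("nan")
    z_cycle: float = float("nan")
    mean_dev_um: float = float("nan")
    max_dev_um: float = float("nan")
    z_pos: float = float("nan")
    z_neighbor: float = float("nan")
    config: AnalysisConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown defect category {self.category!r}")
        cfg = self.config or AnalysisConfig()
        if self.category in TIMING_CATEGORIES:
            assert abs(self.delta_minutes) >= cfg.cycle_min_delta, self
            assert abs(self.z_cycle) > cfg.cycle_sd_mult, self
        if self.category == "position":
            assert self.z_pos > cfg.pos_sd_mult, self
            assert self.z_neighbor > cfg.pos_sd_mult, self


def calls_to_frame(calls: list[DefectCall]) -> pd.DataFrame:
    cols = ["embryo_id", "cell", "category", "delta_minutes", "z_cycle",
            "mean_dev_um", "max_dev_um", "z_pos", "z_neighbor"]
    return pd.DataFrame(
        [[getattr(c, k) for k in cols] for c in calls], columns=cols)


def _require_aligned(tmap, transform=None) -> None:
    if tmap is None or (transform is not None and not isinstance(
            transform, RigidTransform)):
        raise StateError("embryo must be aligned (temporal map / transform) first")


# ---------------------------------------------------------------------------
# cycle and death defects
# ---------------------------------------------------------------------------

def shadowed_cells(embryo: EmbryoRecord, reference: ReferenceModel,
                   tmap: TemporalMap, config: AnalysisConfig | None = None,
                   ) -> set[str]:
    """Cells whose reference identity is ambiguous: descendants of cells
    with a missed or extra division, plus cells absent from the reference."""
    config = config or AnalysisConfig()
    bad_roots: set[str] = set()
    for cell, tr in embryo.cells.items():
        if cell not in reference.cells:
            bad_roots.add(cell)
            continue
        r = reference.cells[cell]
        if tr.end_fate == "divided" and r.fate != "divides":
            bad_roots.add(cell)
        if r.fate == "divides" and tr.end_fate != "divided":
            grace = config.cycle_min_delta + config.cycle_sd_mult * r.cycle_sd
            if tmap(tr.end_time) > r.end_mean + grace:
                bad_roots.add(cell)
    shadowed: set[str] = set()
    for cell in embryo.cells:
        try:
            anc = cell
            while anc:
                anc = parent_name(anc) if anc != "P0" else ""
                if anc in bad_roots:
                    shadowed.add(cell)
                    break
                if not anc or anc == "P0":
                    break
        except NamingError:
            continue
    return shadowed


def call_cycle_defects(embryo: EmbryoRecord, reference: ReferenceModel,
                       tmap: TemporalMap,
                       config: AnalysisConfig | None = None) -> list[DefectCall]:
    """Timing defects: deviant, missed, and (reference-terminal) extra divisions."""
    _require_aligned(tmap)
    config = config or AnalysisConfig()
    calls: list[DefectCall] = []
    endpoint_ref = reference.endpoint_min
    for cell in sorted(embryo.cells):
        tr = embryo.cells[cell]
        r = reference.cells.get(cell)
        if r is None:
            continue
        if tr.end_fate == "divided":
            if r.fate == "divides" and np.isfinite(r.cycle_mean):
                cycle_ref = tmap.rate * (tr.end_time - tr.birth_time)
                delta = cycle_ref - r.cycle_mean
                z = delta / r.cycle_sd
                if abs(delta) >= config.cycle_min_delta and abs(z) > config.cycle_sd_mult:
                    calls.append(DefectCall(
                        embryo.embryo_id, cell,
                        "cycle_late" if delta > 0 else "cycle_early",
                        delta_minutes=float(delta), z_cycle=float(z),
                        config=config))
            elif r.fate == "terminal":
                calls.append(DefectCall(embryo.embryo_id, cell, "extra_division",
                                        config=config))
        elif r.fate == "divides" and np.isfinite(r.cycle_mean):
            grace = config.cycle_min_delta + config.cycle_sd_mult * r.cycle_sd
            observed_until = float(tmap(tr.end_time))
            if (r.end_mean + grace < observed_until - 1e-9
                    and r.end_mean + grace < endpoint_ref):
                delta = observed_until - r.end_mean
                calls.append(DefectCall(
                    embryo.embryo_id, cell, "missed_division",
                    delta_minutes=float(delta),
                    z_cycle=float(delta / r.cycle_sd), config=config))
    return calls


def call_death_defects(embryo: EmbryoRecord, reference: ReferenceModel,
                       tmap: TemporalMap,
                       config: AnalysisConfig | None = None) -> list[DefectCall]:
    """Failed programmed deaths (and divisions of the survivors)."""
    _require_aligned(tmap)
    config = config or AnalysisConfig()
    calls: list[DefectCall] = []
    for cell in sorted(reference.cells):
        r = reference.cells[cell]
        if r.fate != "death" or not np.isfinite(r.death_mean):
            continue
        tr = embryo.cells.get(cell)
        if tr is None:
            continue
        if tr.end_fate == "died":
            continue
        grace = config.cycle_min_delta + config.cycle_sd_mult * r.death_sd
        survived_until = float(tmap(tr.end_time))
        if survived_until > r.death_mean + grace:
            delta = survived_until - r.death_mean
            calls.append(DefectCall(embryo.embryo_id, cell, "missed_death",
                                    delta_minutes=float(delta), config=config))
            if tr.end_fate == "divided":
                calls.append(DefectCall(embryo.embryo_id, cell, "extra_division",
                                        config=config))
    return calls


# ---------------------------------------------------------------------------
# position defects
# ---------------------------------------------------------------------------

def neighbor_distance_score(embryo: EmbryoRecord, reference: ReferenceModel,
                            cell: str, config: AnalysisConfig | None = None,
                            *, tmap: TemporalMap, transform: RigidTransform,
                            ) -> tuple[float, float] | None:
    """(score_um, z_neighbor) for one cell, or None when undefined.

    The score is the mean distance from the cell to the identities of its
    ``n_neighbors`` wild-type-nearest cells, measured in the aligned
    embryo at the reference neighbor time; z standardizes it against the
    wild-type baseline stored in the reference.  Neighbors missing from
    the embryo are dropped; with fewer than ``min_neighbors`` left the
    score is undefined and the cell is exempt from the neighbor criterion.
    """
    _require_aligned(tmap, transform)
    config = config or AnalysisConfig()
    r = reference.cells.get(cell)
    tr = embryo.cells.get(cell)
    if r is None or tr is None or not r.neighbors or not np.isfinite(r.neigh_mean):
        return None
    t_obs = r.neighbor_time / tmap.rate + tmap.offset
    tol = embryo.sampling_min
    if not (tr.birth_time - tol <= t_obs <= tr.end_time + tol):
        return None
    p0 = transform.apply(tr.pos_at(t_obs)[None, :])[0]
    dists = []
    for nb in r.neighbors:
        ntr = embryo.cells.get(nb)
        if ntr is None or not (ntr.birth_time - tol <= t_obs <= ntr.end_time + tol):
            continue
        pn = transform.apply(ntr.pos_at(t_obs)[None, :])[0]
        dists.append(float(np.linalg.norm(pn - p0)))
    if len(dists) < config.min_neighbors:
        log.info("neighbor score undefined for %s (%d/%d neighbors present)",
                 cell, len(dists), len(r.neighbors))
        return None
    score = float(np.mean(dists))
    return score, (score - r.neigh_mean) / r.neigh_sd


def call_position_defects(embryo: EmbryoRecord, reference: ReferenceModel,
                          tmap: TemporalMap, transform: RigidTransform,
                          config: AnalysisConfig | None = None,
                          ) -> list[DefectCall]:
    """Position defects: large mean/max deviation confirmed by the neighbor score."""
    _require_aligned(tmap, transform)
    config = config or AnalysisConfig()
    shadow = shadowed_cells(embryo, reference, tmap, config)
    calls: list[DefectCall] = []
    for cell in sorted(embryo.cells):
        if cell in shadow:
            continue
        tr = embryo.cells[cell]
        r = reference.cells.get(cell)
        if r is None or not np.isfinite(r.pos_dev_mean):
            continue
        t_ref = tmap(tr.times)
        ok = (t_ref >= r.times[0] - 1e-9) & (t_ref <= r.times[-1] + 1e-9)
        if not np.any(ok):
            continue
        xyz = transform.apply(tr.xyz[ok])
        canon = np.column_stack([
            np.interp(t_ref[ok], r.times, r.positions[:, i]) for i in range(3)])
        d = np.linalg.norm(xyz - canon, axis=1)
        mean_dev, max_dev = float(d.mean()), float(d.max())
        z_mean = (mean_dev - r.pos_dev_mean) / r.pos_dev_sd
        z_max = (max_dev - r.posmax_mean) / r.posmax_sd
        z_pos = max(z_mean, z_max)
        if z_pos <= config.pos_sd_mult:
            continue
        nd = neighbor_distance_score(embryo, reference, cell, config,
                                     tmap=tmap, transform=transform)
        if nd is None:
            continue
        _, z_nb = nd
        if z_nb > config.pos_sd_mult:
            calls.append(DefectCall(
                embryo.embryo_id, cell, "position",
                mean_dev_um=mean_dev, max_dev_um=max_dev,
                z_pos=float(z_pos), z_neighbor=float(z_nb), config=config))
    return calls


def call_all_defects(embryo: EmbryoRecord, reference: ReferenceModel,
                     config: AnalysisConfig | None = None,
                     ) -> tuple[pd.DataFrame, TemporalMap, RigidTransform]:
    """Align an embryo and run all three callers; returns the defect table."""
    from .reference import temporal_align, spatial_align
    config = config or AnalysisConfig()
    tmap = temporal_align(embryo, reference)
    tf = spatial_align(embryo, reference, tmap, config)
    calls = (call_cycle_defects(embryo, reference, tmap, config)
             + call_death_defects(embryo, reference, tmap, config)
             + call_position_defects(embryo, reference, tmap, tf, config))
    return calls_to_frame(calls), tmap, tf


# ---------------------------------------------------------------------------
# division orientation (reported, never a calling criterion: no published
# deviation rule exists to implement)
# ---------------------------------------------------------------------------

def division_orientation_report(embryo: EmbryoRecord, reference: ReferenceModel,
                                tmap: TemporalMap, transform: RigidTransform,
                                ) -> pd.DataFrame:
    """Angle (degrees) between each observed division axis and the canonical
    one.

    The division axis is the unit vector between the daughters' lifetime
    mean positions (at birth the separation is below the noise floor, so
    instantaneous axes are ill-defined; the lifetime average is robust).
    Daughters are ordered lexicographically on both sides so the sign
    convention matches.
    """
    _require_aligned(tmap, transform)
    rows = []
    for cell in sorted(embryo.cells):
        tr = embryo.cells[cell]
        if tr.end_fate != "divided":
            continue
        r = reference.cells.get(cell)
        if r is None or r.fate != "divides":
            continue
        kids = sorted(k for k in embryo.cells
                      if k != cell and k.startswith(cell) and len(k) == len(cell) + 1)
        if len(kids) != 2 or not all(k in reference.cells for k in kids):
            continue

        def mean_obs(k):
            return transform.apply(embryo.cells[k].xyz).mean(axis=0)

        obs = mean_obs(kids[1]) - mean_obs(kids[0])
        ref_vec = (reference.cells[kids[1]].positions.mean(axis=0)
                   - reference.cells[kids[0]].positions.mean(axis=0))
        no, nr = np.linalg.norm(obs), np.linalg.norm(ref_vec)
        if no < 1e-9 or nr < 1e-9:
            continue
        cosang = float(np.clip(obs @ ref_vec / (no * nr), -1.0, 1.0))
        rows.append((embryo.embryo_id, cell, float(np.degrees(np.arccos(cosang)))))
    return pd.DataFrame(rows, columns=["embryo_id", "cell", "orientation_deg"])


# ---------------------------------------------------------------------------
# group-mean cycle comparison
# ---------------------------------------------------------------------------

def compare_mean_cycles(mutant_embryos: list[EmbryoRecord],
                        wt_embryos: list[EmbryoRecord],
                        reference: ReferenceModel,
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-cell two-sample t test on cycle lengths with BH correction.

    Cycle lengths are mapped to the reference clock per embryo before
    comparison; cells without >= 2 observations per group are skipped.
    """
    from .reference import temporal_align
    config = config or AnalysisConfig()

    def cycles_by_cell(embryos):
        out: dict[str, list[float]] = {}
        for emb in embryos:
            tmap = temporal_align(emb, reference)
            for cell, tr in emb.cells.items():
                if tr.end_fate == "divided":
                    out.setdefault(cell, []).append(
                        tmap.rate * (tr.end_time - tr.birth_time))
        return out

    mut, wt = cycles_by_cell(mutant_embryos), cycles_by_cell(wt_embryos)
    rows = []
    for cell in sorted(set(mut) & set(wt)):
        a, b = mut[cell], wt[cell]
        if len(a) < 2 or len(b) < 2:
            log.info("compare_mean_cycles: skipping %s (n=%d vs %d)",
                     cell, len(a), len(b))
            continue
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append((cell, float(np.mean(a) - np.mean(b)), float(p)))
    df = pd.DataFrame(rows, columns=["cell", "mean_difference_min", "p_value"])
    if len(df):
        df["fdr_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["fdr_bh"] = []
    return df
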