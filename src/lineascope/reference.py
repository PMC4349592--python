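"""The 4D wild-type reference model and embryo alignment.

The reference compiles, over a set of aligned wild-type embryos, per-cell
division-timing statistics (cycle mean/SD), canonical 3D positions over
time, a positional-deviation baseline, and the identities of each cell's
nearest wild-type neighbors together with the wild-type distribution of
the neighbor-distance score.  Mutant embryos are aligned to it with a
least-squares temporal map (offset + rate on division times) and a rigid
(Kabsch) spatial transform, after which per-cell defects can be scored.

Building is iterative: the model is seeded from the first embryo, every
embryo is aligned to the current model, canonical positions are re-averaged,
and the loop repeats until positions stop moving.  The finished model is
re-expressed in a canonical anatomical frame (principal axes of the cell
cloud, anterior-posterior along +x) so that it does not depend on the
arbitrary placement of any input recording.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AnalysisConfig
from .errors import AlignmentError, QueryError
from .lineage import matches_pattern
from .tracks import CellTrack, EmbryoRecord

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class TemporalMap:
    """Affine map from an embryo's clock to the reference clock:
    t_ref = rate * (t_obs - offset)."""
    offset: float
    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise AlignmentError(f"non-positive temporal rate {self.rate}")
        if not (0.5 < self.rate < 2.0):
            warnings.warn(f"temporal rate {self.rate:.3f} outside (0.5, 2.0)")

    def __call__(self, t):
        return self.rate * (np.asarray(t, float) - self.offset)


@dataclass
class RigidTransform:
    """Proper rigid transform x -> scale * R x + t (µm)."""
    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0
    residual_rms: float = float("nan")

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise AlignmentError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise AlignmentError("rotation must be proper (det = +1)")
        if self.scale <= 0:
            raise AlignmentError("scale must be positive")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(xyz, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0, 0.0)


@dataclass
class CellRef:
    """Per-cell wild-type statistics."""
    fate: str                      # divides | death | terminal (modal observed)
    birth_mean: float
    end_mean: float
    times: np.ndarray              # canonical reference times
    positions: np.ndarray          # (len(times), 3) canonical µm
    cycle_mean: float = float("nan")
    cycle_sd: float = float("nan")
    n_obs: int = 0
    death_mean: float = float("nan")
    death_sd: float = float("nan")
    pos_dev_mean: float = float("nan")
    pos_dev_sd: float = float("nan")
    posmax_mean: float = float("nan")
    posmax_sd: float = float("nan")
    neighbors: list[str] = field(default_factory=list)
    neighbor_time: float = float("nan")
    neigh_mean: float = float("nan")
    neigh_sd: float = float("nan")


class ReferenceModel:
    def __init__(self, cells: dict[str, CellRef], sampling_min: float,
                 n_embryos: int, meta: dict | None = None):
        self.cells = cells
        self.sampling_min = sampling_min
        self.n_embryos = n_embryos
        self.meta = meta or {}

    def __contains__(self, cell: str) -> bool:
        return cell in self.cells

    @property
    def endpoint_min(self) -> float:
        return max(c.end_mean for c in self.cells.values())

    def alive_at(self, cell: str, t_ref: float, tol: float | None = None) -> bool:
        if cell not in self.cells:
            return False
        ref = self.cells[cell]
        tol = self.sampling_min if tol is None else tol
        return ref.birth_mean - tol <= t_ref <= ref.end_mean + tol

    def expected_position(self, cell: str, t_ref: float) -> np.ndarray:
        """Canonical position by linear interpolation between stored times."""
        if cell not in self.cells:
            raise QueryError(f"unknown cell {cell!r}")
        if not self.alive_at(cell, t_ref):
            raise QueryError(f"{cell} not alive at reference time {t_ref:.2f}")
        ref = self.cells[cell]
        return np.array([
            np.interp(t_ref, ref.times, ref.positions[:, i]) for i in range(3)
        ])

    def division_times(self) -> dict[str, float]:
        """Reference clock time at which each dividing cell divides."""
        return {c: r.end_mean for c, r in self.cells.items() if r.fate == "divides"}

    def select(self, pattern: str) -> list[str]:
        return [c for c in self.cells if matches_pattern(c, pattern)]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        obj = {
            "schema_version": SCHEMA_VERSION,
            "sampling_min": self.sampling_min,
            "n_embryos": self.n_embryos,
            "meta": self.meta,
            "cells": {
                c: {
                    "fate": r.fate,
                    "birth_mean": r.birth_mean, "end_mean": r.end_mean,
                    "times": np.round(r.times, 4).tolist(),
                    "positions": np.round(r.positions, 4).tolist(),
                    "cycle_mean": r.cycle_mean, "cycle_sd": r.cycle_sd,
                    "n_obs": r.n_obs,
                    "death_mean": r.death_mean, "death_sd": r.death_sd,
                    "pos_dev_mean": r.pos_dev_mean, "pos_dev_sd": r.pos_dev_sd,
                    "posmax_mean": r.posmax_mean, "posmax_sd": r.posmax_sd,
                    "neighbors": r.neighbors, "neighbor_time": r.neighbor_time,
                    "neigh_mean": r.neigh_mean, "neigh_sd": r.neigh_sd,
                }
                for c, r in self.cells.items()
            },
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        obj = json.loads(Path(path).read_text())
        if obj.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported reference schema {obj.get('schema_version')}")
        cells = {}
        for c, r in obj["cells"].items():
            cells[c] = CellRef(
                fate=r["fate"], birth_mean=r["birth_mean"], end_mean=r["end_mean"],
                times=np.asarray(r["times"], float),
                positions=np.asarray(r["positions"], float),
                cycle_mean=r["cycle_mean"], cycle_sd=r["cycle_sd"],
                n_obs=r["n_obs"], death_mean=r["death_mean"], death_sd=r["death_sd"],
                pos_dev_mean=r["pos_dev_mean"], pos_dev_sd=r["pos_dev_sd"],
                posmax_mean=r["posmax_mean"], posmax_sd=r["posmax_sd"],
                neighbors=list(r["neighbors"]), neighbor_time=r["neighbor_time"],
                neigh_mean=r["neigh_mean"], neigh_sd=r["neigh_sd"],
            )
        return cls(cells, obj["sampling_min"], obj["n_embryos"], obj.get("meta"))


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def temporal_align(embryo: EmbryoRecord, reference: ReferenceModel) -> TemporalMap:
    """Least-squares fit of reference division times against observed ones."""
    ref_div = reference.division_times()
    t_obs, t_ref = [], []
    for cell, tr in embryo.cells.items():
        if tr.end_fate == "divided" and cell in ref_div:
            t_obs.append(tr.end_time)
            t_ref.append(ref_div[cell])
    if len(t_obs) < 10:
        raise AlignmentError(
            f"only {len(t_obs)} shared divisions between embryo and reference (need 10)")
    a, b = np.polyfit(np.asarray(t_obs), np.asarray(t_ref), 1)
    return TemporalMap(offset=-b / a, rate=a)


def _gauge_fix(tmaps: list[TemporalMap]) -> list[TemporalMap]:
    """Renormalize temporal maps so their cohort mean is the identity.

    The joint align-and-average iteration has a free affine gauge on the
    reference clock; without pinning it, small regression biases accumulate
    as a drift of all reference times.  Composing every map with the
    inverse of the cohort-mean map keeps the reference on the embryos'
    common clock.
    """
    a = np.array([m.rate for m in tmaps])
    b = np.array([-m.rate * m.offset for m in tmaps])
    abar, bbar = float(a.mean()), float(b.mean())
    out = []
    for ai, bi in zip(a, b):
        a2, b2 = ai / abar, (bi - bbar) / abar
        out.append(TemporalMap(offset=-b2 / a2, rate=a2))
    return out


def kabsch(obs: np.ndarray, ref: np.ndarray,
           allow_scale: bool = False) -> RigidTransform:
    """Proper rigid (optionally similarity) transform minimizing
    sum ||s R obs_i + t - ref_i||^2."""
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    if obs.shape[0] < 4:
        raise AlignmentError(f"need >= 4 matched points, got {obs.shape[0]}")
    co, cr = obs.mean(axis=0), ref.mean(axis=0)
    X, Y = obs - co, ref - cr
    # degenerate geometry: covariance of the observed cloud must be rank 3
    s_obs = np.linalg.svd(X, compute_uv=False)
    if s_obs[2] < 1e-9 * max(s_obs[0], 1e-30):
        raise AlignmentError("degenerate geometry: matched points are coplanar/collinear")
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d < 0:
        warnings.warn("best alignment is a reflection; forcing a proper rotation")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        scale = float((S * np.diag(D)).sum() / (X ** 2).sum())
    else:
        scale = 1.0
    t = cr - scale * R @ co
    tf = RigidTransform(R, t, scale)
    tf.residual_rms = float(np.sqrt(np.mean(
        np.sum((tf.apply(obs) - ref) ** 2, axis=1))))
    return tf


def _matched_points(embryo: EmbryoRecord, reference: ReferenceModel,
                    tmap: TemporalMap) -> tuple[np.ndarray, np.ndarray]:
    obs_pts, ref_pts = [], []
    for cell, tr in embryo.cells.items():
        if cell not in reference.cells:
            continue
        r = reference.cells[cell]
        t_ref = tmap(tr.times)
        ok = (t_ref >= r.times[0] - 1e-9) & (t_ref <= r.times[-1] + 1e-9)
        if not np.any(ok):
            continue
        canon = np.column_stack([
            np.interp(t_ref[ok], r.times, r.positions[:, i]) for i in range(3)])
        obs_pts.append(tr.xyz[ok])
        ref_pts.append(canon)
    if not obs_pts:
        raise AlignmentError("no matched (cell, time) pairs")
    return np.vstack(obs_pts), np.vstack(ref_pts)


def spatial_align(embryo: EmbryoRecord, reference: ReferenceModel,
                  tmap: TemporalMap,
                  config: AnalysisConfig | None = None) -> RigidTransform:
    """Rigid transform taking observed positions onto canonical positions."""
    config = config or AnalysisConfig()
    obs, ref = _matched_points(embryo, reference, tmap)
    return kabsch(obs, ref, allow_scale=config.allow_scale)


# ---------------------------------------------------------------------------
# reference building
# ---------------------------------------------------------------------------

_FATE_FROM_END = {"divided": "divides", "died": "death",
                  "tracked_to_end": "terminal", "lost": "terminal"}


def _initial_reference(embryo: EmbryoRecord) -> ReferenceModel:
    cells = {}
    for c, tr in embryo.cells.items():
        cells[c] = CellRef(
            fate=_FATE_FROM_END[tr.end_fate],
            birth_mean=tr.birth_time, end_mean=tr.end_time,
            times=tr.times.copy(), positions=tr.xyz.copy(),
        )
    return ReferenceModel(cells, embryo.sampling_min, 1)


def _grid(b: float, e: float, dt: float) -> np.ndarray:
    g = np.arange(np.ceil(b / dt - 1e-9) * dt, e + 1e-9, dt)
    return g if g.size else np.array([b])


def build_reference(embryos: list[EmbryoRecord],
                    config: AnalysisConfig | None = None,
                    max_iter: int = 10,
                    tol_um: float = 0.01) -> ReferenceModel:
    """Iteratively align-and-average wild-type embryos into a reference model."""
    config = config or AnalysisConfig()
    if len(embryos) < 2:
        raise ValueError("need >= 2 embryos to build a reference")
    dt = embryos[0].sampling_min
    ref = _initial_reference(embryos[0])
    aligned: list[tuple[TemporalMap, RigidTransform]] = []
    for it in range(max_iter):
        tmaps = [temporal_align(emb, ref) for emb in embryos]
        tmaps = _gauge_fix(tmaps)
        aligned = []
        for emb, tmap in zip(embryos, tmaps):
            tf = spatial_align(emb, ref, tmap, config)
            aligned.append((tmap, tf))
        new_cells: dict[str, CellRef] = {}
        movement = 0.0
        all_names = sorted({c for emb in embryos for c in emb.cells})
        for cell in all_names:
            births, ends, fates = [], [], []
            tracks: list[tuple[np.ndarray, np.ndarray]] = []
            for emb, (tmap, tf) in zip(embryos, aligned):
                tr = emb.cells.get(cell)
                if tr is None:
                    continue
                births.append(float(tmap(tr.birth_time)))
                ends.append(float(tmap(tr.end_time)))
                fates.append(tr.end_fate)
                tracks.append((tmap(tr.times), tf.apply(tr.xyz)))
            b, e = float(np.mean(births)), float(np.mean(ends))
            grid = _grid(b, e, dt)
            # clamp-interpolate every embryo's track at every grid point so the
            # average varies continuously with the alignment parameters
            # (coverage-set flips at track edges would otherwise oscillate)
            acc = np.zeros((grid.size, 3))
            for tt, xyz in tracks:
                acc += np.column_stack([
                    np.interp(grid, tt, xyz[:, i]) for i in range(3)])
            canon = acc / len(tracks)
            fate_mode = max(set(fates), key=fates.count)
            if cell in ref.cells:
                old = ref.cells[cell]
                interior = (grid >= old.times[0] + dt) & (grid <= old.times[-1] - dt)
                if np.any(interior):
                    old_interp = np.column_stack([
                        np.interp(grid[interior], old.times, old.positions[:, i])
                        for i in range(3)])
                    movement = max(movement, float(np.max(
                        np.linalg.norm(canon[interior] - old_interp, axis=1))))
                else:
                    movement = max(movement, np.inf)
            else:
                movement = max(movement, np.inf)
            new_cells[cell] = CellRef(
                fate=_FATE_FROM_END[fate_mode], birth_mean=b, end_mean=e,
                times=grid, positions=canon,
            )
        ref = ReferenceModel(new_cells, dt, len(embryos))
        if movement < tol_um:
            break
    else:
        log.warning("reference build did not converge after %d iterations", max_iter)

    _finalize_stats(ref, embryos, aligned, config)
    _canonicalize_frame(ref)
    ref.meta = {
        "embryo_order": [e.embryo_id for e in embryos],
        "iterations": it + 1,
        "config": config.to_dict(),
    }
    return ref


def _finalize_stats(ref: ReferenceModel, embryos: list[EmbryoRecord],
                    aligned: list, config: AnalysisConfig) -> None:
    # cycle and death-timing statistics (reference clock)
    for cell, r in ref.cells.items():
        cycles, death_times = [], []
        devs_mean, devs_max = [], []
        for emb, (tmap, tf) in zip(embryos, aligned):
            tr = emb.cells.get(cell)
            if tr is None:
                continue
            if tr.end_fate == "divided":
                cycles.append(tmap.rate * (tr.end_time - tr.birth_time))
            if tr.end_fate == "died":
                death_times.append(float(tmap(tr.end_time)))
            tt, xyz = tmap(tr.times), tf.apply(tr.xyz)
            ok = (tt >= r.times[0] - 1e-9) & (tt <= r.times[-1] + 1e-9)
            if np.any(ok):
                canon = np.column_stack([
                    np.interp(tt[ok], r.times, r.positions[:, i]) for i in range(3)])
                d = np.linalg.norm(xyz[ok] - canon, axis=1)
                devs_mean.append(float(d.mean()))
                devs_max.append(float(d.max()))
        if cycles:
            r.cycle_mean = float(np.mean(cycles))
            r.n_obs = len(cycles)
            r.cycle_sd = (max(float(np.std(cycles, ddof=1)), config.cycle_sd_floor)
                          if len(cycles) >= 2 else config.cycle_sd_floor)
        if death_times:
            r.death_mean = float(np.mean(death_times))
            r.death_sd = (max(float(np.std(death_times, ddof=1)), config.cycle_sd_floor)
                          if len(death_times) >= 2 else config.cycle_sd_floor)
        if devs_mean:
            r.pos_dev_mean = float(np.mean(devs_mean))
            r.pos_dev_sd = (max(float(np.std(devs_mean, ddof=1)), config.pos_sd_floor)
                            if len(devs_mean) >= 2 else config.pos_sd_floor)
            r.posmax_mean = float(np.mean(devs_max))
            r.posmax_sd = (max(float(np.std(devs_max, ddof=1)), config.pos_sd_floor)
                           if len(devs_max) >= 2 else config.pos_sd_floor)

    # neighbor identities at each cell's mid-life, from canonical positions
    names = sorted(ref.cells)
    for cell in names:
        r = ref.cells[cell]
        mid = 0.5 * (r.birth_mean + r.end_mean)
        alive = [c for c in names if c != cell
                 and ref.cells[c].birth_mean <= mid <= ref.cells[c].end_mean]
        if not alive:
            continue
        p0 = ref.expected_position(cell, mid)
        dists = []
        for c in alive:
            rc = ref.cells[c]
            pc = np.array([np.interp(mid, rc.times, rc.positions[:, i])
                           for i in range(3)])
            dists.append((float(np.linalg.norm(pc - p0)), c))
        dists.sort()
        r.neighbors = [c for _, c in dists[:config.n_neighbors]]
        r.neighbor_time = mid

    # wild-type baseline of the neighbor-distance score
    for cell in names:
        r = ref.cells[cell]
        if not r.neighbors:
            continue
        scores = []
        for emb, (tmap, tf) in zip(embryos, aligned):
            s = _embryo_neighbor_score(emb, tmap, tf, ref, cell, config)
            if s is not None:
                scores.append(s)
        if scores:
            r.neigh_mean = float(np.mean(scores))
            r.neigh_sd = (max(float(np.std(scores, ddof=1)), config.pos_sd_floor)
                          if len(scores) >= 2 else config.pos_sd_floor)


def _embryo_neighbor_score(emb: EmbryoRecord, tmap: TemporalMap,
                           tf: RigidTransform, ref: ReferenceModel,
                           cell: str, config: AnalysisConfig) -> float | None:
    """Mean distance from `cell` to its wild-type-nearest neighbor identities,
    measured in this (aligned) embryo at the reference neighbor time."""
    r = ref.cells[cell]
    tr = emb.cells.get(cell)
    if tr is None or not r.neighbors:
        return None
    t_obs = r.neighbor_time / tmap.rate + tmap.offset
    if not (tr.birth_time - emb.sampling_min <= t_obs <= tr.end_time + emb.sampling_min):
        return None
    p0 = tf.apply(tr.pos_at(t_obs)[None, :])[0]
    dists = []
    for nb in r.neighbors:
        ntr = emb.cells.get(nb)
        if ntr is None:
            continue
        if not (ntr.birth_time - emb.sampling_min <= t_obs
                <= ntr.end_time + emb.sampling_min):
            continue
        pn = tf.apply(ntr.pos_at(t_obs)[None, :])[0]
        dists.append(float(np.linalg.norm(pn - p0)))
    if len(dists) < config.min_neighbors:
        return None
    return float(np.mean(dists))


def _canonicalize_frame(ref: ReferenceModel) -> None:
    """Re-express canonical positions in a placement-independent frame.

    Principal axes of the pooled canonical cloud; +x is anterior-posterior
    (AB lineage anterior of C), +z points from the E toward the C lineage,
    y completes a right-handed system.
    """
    pooled = np.vstack([r.positions for r in ref.cells.values()])
    c = pooled.mean(axis=0)
    cov = np.cov((pooled - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    e1, e2, e3 = (evecs[:, i] for i in order)

    def lineage_mean(founder: str) -> np.ndarray:
        from .lineage import split_name
        pts = [r.positions.mean(axis=0) for cell, r in ref.cells.items()
               if split_name(cell)[0] == founder]
        return np.mean(pts, axis=0) - c

    ab, cc, ee = lineage_mean("AB"), lineage_mean("C"), lineage_mean("E")
    if np.dot(ab, e1) > np.dot(cc, e1):
        e1 = -e1
    if np.dot(cc - ee, e3) < 0:
        e3 = -e3
    e2 = np.cross(e3, e1)
    R = np.vstack([e1, e2, e3])
    for r in ref.cells.values():
        r.positions = (r.positions - c) @ R.T
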