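"""Defect calling: thresholds, neighbor score, pipeline closure."""

import numpy as np
import pandas as pd
import pytest

from lineascope.config import AnalysisConfig
from lineascope.defects import (DefectCall, call_all_defects, call_cycle_defects,
                                call_death_defects, call_position_defects,
                                compare_mean_cycles, neighbor_distance_score)
from lineascope.errors import StateError
from lineascope.reference import (CellRef, ReferenceModel, RigidTransform,
                                  TemporalMap, temporal_align)
from lineascope.simulate import (DefectSpec, Injection, SimulationSpec,
                                 generate_wildtype, inject_defects)
from lineascope.tracks import CellTrack, EmbryoRecord


class TestCycleThresholds:
    """The calling rule: beyond 3 SD AND at least 5 minutes."""

    def _one_cell_setup(self, cycle_sd, observed_cycle, cycle_mean=40.0):
        cells = {"ABa": CellRef(fate="divides", birth_mean=0.0,
                                end_mean=cycle_mean,
                                times=np.array([0.0, cycle_mean]),
                                positions=np.zeros((2, 3)),
                                cycle_mean=cycle_mean, cycle_sd=cycle_sd,
                                n_obs=10)}
        ref = ReferenceModel(cells, 1.5, 10)
        t = np.array([[0.0, 0, 0, 0], [observed_cycle, 0, 0, 0]])
        emb = EmbryoRecord("m", "mut", {
            "ABa": CellTrack(0.0, observed_cycle, "divided", t)})
        return emb, ref

    @pytest.mark.parametrize("sd,obs,expected", [
        (1.0, 46.0, "cycle_late"),   # delta 6 > 3 SD and >= 5 min
        (1.0, 44.0, None),           # delta 4 < 5-min floor
        (2.5, 47.0, None),           # delta 7 < 3 x 2.5
        (1.0, 34.0, "cycle_early"),
    ])
    def test_rule(self, sd, obs, expected):
        emb, ref = self._one_cell_setup(sd, obs)
        calls = call_cycle_defects(emb, ref, TemporalMap(0.0, 1.0))
        cats = [c.category for c in calls]
        assert cats == ([expected] if expected else [])

    def test_unaligned_raises_state_error(self, ref10):
        emb = EmbryoRecord("m", "mut", {})
        with pytest.raises(StateError):
            call_cycle_defects(emb, ref10, None)

    def test_call_invariants_enforced_on_construction(self):
        with pytest.raises(AssertionError):
            DefectCall("e", "ABa", "cycle_late", delta_minutes=3.0, z_cycle=10.0)


class TestDeathDefects:
    def test_skipped_death_that_divides_gets_both_calls(self, template, ref10,
                                                        config):
        """A failed programmed death that survives and divides (the MSpaapp
        phenotype) is missed_death + extra_division."""
        emb = generate_wildtype(SimulationSpec(template=template, seed=321), "m")
        mut, _ = inject_defects(
            emb, DefectSpec([Injection("MSpaapp", "extra_division")]), 1, template)
        table, *_ = call_all_defects(mut, ref10, config)
        cats = set(table.loc[table.cell == "MSpaapp", "category"])
        assert cats == {"missed_death", "extra_division"}

    def test_on_schedule_death_not_called(self, template, ref10, config):
        emb = generate_wildtype(SimulationSpec(template=template, seed=322), "m")
        table, *_ = call_all_defects(emb, ref10, config)
        assert "missed_death" not in set(table.category)

    def test_small_death_delay_not_called(self):
        """Dying 2 min late with SD 1.5 is inside the 5-minute floor."""
        cells = {"Caaapp": CellRef(fate="death", birth_mean=0.0, end_mean=20.0,
                                   times=np.array([0.0, 20.0]),
                                   positions=np.zeros((2, 3)),
                                   death_mean=20.0, death_sd=1.5)}
        ref = ReferenceModel(cells, 1.5, 10)
        t = np.array([[0.0, 0, 0, 0], [22.0, 0, 0, 0]])
        emb = EmbryoRecord("m", "mut",
                           {"Caaapp": CellTrack(0.0, 22.0, "died", t)})
        assert call_death_defects(emb, ref, TemporalMap(0.0, 1.0)) == []


def _grid_reference(n_side=4, spacing=1.0, t_end=100.0):
    """A hand-built reference of 12 well-separated concurrent cells on a
    grid, with neighbor identities and baselines computed by brute force."""
    names = [p + s for p in ("ABal", "ABar", "ABpl", "ABpr")
             for s in ("a", "p", "d"[:1])][:12]
    # 12 valid distinct names: ABala ABalp ABald? d invalid at this depth? all letters valid
    names = ["ABala", "ABalp", "ABara", "ABarp", "ABpla", "ABplp",
             "ABpra", "ABprp", "ABald", "ABard", "ABpld", "ABprd"]
    rng = np.random.default_rng(0)
    pos = {}
    for i, name in enumerate(names):
        pos[name] = np.array([(i % 4) * spacing, (i // 4) * spacing, 0.0]) \
            + rng.normal(0, 0.15 * spacing, 3)
    cells = {}
    for name in names:
        d = sorted((float(np.linalg.norm(pos[o] - pos[name])), o)
                   for o in names if o != name)
        neighbors = [o for _, o in d[:10]]
        wt_score = float(np.mean([dist for dist, _ in d[:10]]))
        cells[name] = CellRef(
            fate="terminal", birth_mean=0.0, end_mean=t_end,
            times=np.array([0.0, t_end]),
            positions=np.vstack([pos[name], pos[name]]),
            pos_dev_mean=0.1, pos_dev_sd=0.3, posmax_mean=0.2, posmax_sd=0.3,
            neighbors=neighbors, neighbor_time=t_end / 2,
            neigh_mean=wt_score, neigh_sd=0.3)
    return ReferenceModel(cells, 1.5, 10), pos


def _grid_embryo(pos, displaced=None, offset=np.zeros(3), t_end=100.0):
    cells = {}
    for name, p in pos.items():
        q = p + (offset if displaced and name in displaced else 0.0)
        track = np.array([[0.0, *q], [t_end, *q]])
        cells[name] = CellTrack(0.0, t_end, "tracked_to_end", track)
    return EmbryoRecord("m", "mut", cells)


class TestNeighborScore:
    def test_identity_embryo_scores_zero_z(self):
        ref, pos = _grid_reference()
        emb = _grid_embryo(pos)
        s, z = neighbor_distance_score(emb, ref, "ABala",
                                       tmap=TemporalMap(0.0, 1.0),
                                       transform=RigidTransform.identity())
        assert z == pytest.approx(0.0, abs=1e-9)
        assert s == pytest.approx(ref.cells["ABala"].neigh_mean)

    def test_displacement_raises_score_by_about_the_offset(self):
        """+20 µm on one cell in a well-separated grid adds ~20 µm to the
        brute-force mean neighbor distance."""
        ref, pos = _grid_reference()
        emb = _grid_embryo(pos, displaced={"ABala"},
                           offset=np.array([0.0, 0.0, 20.0]))
        s, z = neighbor_distance_score(emb, ref, "ABala",
                                       tmap=TemporalMap(0.0, 1.0),
                                       transform=RigidTransform.identity())
        brute = np.mean([np.linalg.norm(pos[n] - pos["ABala"]
                                        - np.array([0, 0, 20.0]))
                         for n in ref.cells["ABala"].neighbors])
        assert s == pytest.approx(float(brute), abs=1e-9)
        # displacement >> local spacing, so the score grows by ~the offset
        assert s - ref.cells["ABala"].neigh_mean == pytest.approx(20.0, abs=2.5)

    def test_missing_neighbors_drop_and_renormalize(self):
        ref, pos = _grid_reference()
        keep = dict(pos)
        removed = ref.cells["ABala"].neighbors[:4]
        for r in removed:
            del keep[r]
        emb = _grid_embryo(keep)
        out = neighbor_distance_score(emb, ref, "ABala",
                                      tmap=TemporalMap(0.0, 1.0),
                                      transform=RigidTransform.identity())
        assert out is not None   # 6 >= 5 remain
        brute = np.mean([np.linalg.norm(pos[n] - pos["ABala"])
                         for n in ref.cells["ABala"].neighbors
                         if n not in removed])
        assert out[0] == pytest.approx(float(brute), abs=1e-9)

    def test_under_five_neighbors_undefined(self):
        ref, pos = _grid_reference()
        keep = dict(pos)
        for r in ref.cells["ABala"].neighbors[:6]:
            del keep[r]
        emb = _grid_embryo(keep)
        out = neighbor_distance_score(emb, ref, "ABala",
                                      tmap=TemporalMap(0.0, 1.0),
                                      transform=RigidTransform.identity())
        assert out is None


class TestPositionDefects:
    def test_identity_embryo_no_calls(self):
        ref, pos = _grid_reference()
        emb = _grid_embryo(pos)
        calls = call_position_defects(emb, ref, TemporalMap(0.0, 1.0),
                                      RigidTransform.identity())
        assert calls == []

    def test_displaced_cell_called(self):
        ref, pos = _grid_reference()
        emb = _grid_embryo(pos, displaced={"ABala"},
                           offset=np.array([0.0, 0.0, 15.0]))
        calls = call_position_defects(emb, ref, TemporalMap(0.0, 1.0),
                                      RigidTransform.identity())
        assert [c.cell for c in calls] == ["ABala"]
        assert calls[0].z_pos > 3.5 and calls[0].z_neighbor > 3.5

    def test_comoving_cluster_suppressed(self):
        """A cell displaced together with all its wild-type neighbors keeps
        its local context, so the neighbor criterion suppresses the call."""
        ref, pos = _grid_reference()
        cluster = {"ABala", *ref.cells["ABala"].neighbors}
        emb = _grid_embryo(pos, displaced=cluster,
                           offset=np.array([0.0, 0.0, 15.0]))
        calls = call_position_defects(emb, ref, TemporalMap(0.0, 1.0),
                                      RigidTransform.identity())
        assert "ABala" not in [c.cell for c in calls]

    def test_injected_displacement_called_in_full_pipeline(self, template,
                                                           ref10, config):
        emb = generate_wildtype(SimulationSpec(template=template, seed=808), "m")
        target = "ABalaapapa"
        mut, _ = inject_defects(
            emb, DefectSpec([Injection(target, "displace", 15.0)]), 3, template)
        table, *_ = call_all_defects(mut, ref10, config)
        pos_calls = table[table.category == "position"]
        assert target in set(pos_calls.cell)

    def test_calls_invariant_to_rigid_placement(self, template, ref10, config):
        emb = generate_wildtype(SimulationSpec(template=template, seed=809), "m")
        mut, _ = inject_defects(
            emb, DefectSpec([Injection("ABalaapapa", "displace", 15.0)]), 3,
            template)
        t1, *_ = call_all_defects(mut, ref10, config)
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(5)
        R = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-25, 25, 3)
        moved = mut.copy()
        for tr in moved.cells.values():
            tr.positions[:, 1:4] = tr.positions[:, 1:4] @ R.T + shift
        t2, *_ = call_all_defects(moved, ref10, config)
        key = ["cell", "category"]
        assert sorted(map(tuple, t1[key].values.tolist())) == \
            sorted(map(tuple, t2[key].values.tolist()))


class TestDivisionOrientation:
    def test_reported_small_in_wildtype_and_never_called(self, template, ref10,
                                                         config):
        """Orientation deviation is reported for every scored division but is
        not a defect category."""
        from lineascope.defects import division_orientation_report
        from lineascope.reference import spatial_align
        emb = generate_wildtype(SimulationSpec(template=template, seed=911), "w")
        tmap = temporal_align(emb, ref10)
        tf = spatial_align(emb, ref10, tmap, config)
        report = division_orientation_report(emb, ref10, tmap, tf)
        assert len(report) > 200
        assert report["orientation_deg"].median() < 45.0
        table, *_ = call_all_defects(emb, ref10, config)
        assert "orientation" not in set(table.category)

    def test_zero_for_reference_cohort_member_noiselessly(self, template, config):
        """Two identical noiseless embryos: observed axes equal canonical."""
        from lineascope.defects import division_orientation_report
        from lineascope.reference import build_reference, spatial_align
        quiet = dict(timing_cv=0.0, pos_noise_um=0.0, walk_um=0.0,
                     rigid_placement="fixed")
        embs = [generate_wildtype(SimulationSpec(template=template, seed=s,
                                                 **quiet), f"q{s}")
                for s in (0, 1)]
        ref = build_reference(embs, config)
        tmap = temporal_align(embs[0], ref)
        tf = spatial_align(embs[0], ref, tmap, config)
        report = division_orientation_report(embs[0], ref, tmap, tf)
        assert report["orientation_deg"].max() < 1.0


class TestCompareMeanCycles:
    def test_same_distribution_gives_flat_p(self, template, ref10, wt10):
        a = [generate_wildtype(SimulationSpec(template=template, seed=60 + i),
                               f"a{i}") for i in range(3)]
        df = compare_mean_cycles(a, wt10[:5], ref10)
        assert (df["fdr_bh"] < 0.15).mean() < 0.02
        assert df["p_value"].median() > 0.2

    def test_shifted_cell_detected_with_bh(self, template, ref10, wt10):
        """One cell delayed ~10 SD in every mutant reaches FDR < 0.15."""
        target = "ABplpapa"
        muts = []
        for i in range(4):
            emb = generate_wildtype(
                SimulationSpec(template=template, seed=70 + i), f"m{i}")
            mut, _ = inject_defects(
                emb, DefectSpec([Injection(target, "delay", 12.0)]), i, template)
            muts.append(mut)
        df = compare_mean_cycles(muts, wt10, ref10).set_index("cell")
        assert df.loc[target, "fdr_bh"] < 0.15
        assert df.loc[target, "mean_difference_min"] == pytest.approx(12.0, abs=3.0)

    def test_bh_monotone_in_raw_p_rank(self, template, ref10, wt10):
        a = [generate_wildtype(SimulationSpec(template=template, seed=80 + i),
                               f"a{i}") for i in range(2)]
        df = compare_mean_cycles(a, wt10[:3], ref10).sort_values("p_value")
        assert (np.diff(df["fdr_bh"].to_numpy()) >= -1e-12).all()
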