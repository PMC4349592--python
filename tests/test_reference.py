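"""Temporal/spatial alignment and reference-model construction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lineascope.config import AnalysisConfig
from lineascope.errors import AlignmentError, QueryError
from lineascope.reference import (RigidTransform, build_reference, kabsch,
                                  spatial_align, temporal_align)
from lineascope.simulate import SimulationSpec, generate_wildtype


def quiet_spec(template, seed=0, placement="fixed"):
    return SimulationSpec(template=template, timing_cv=0.0, pos_noise_um=0.0,
                          walk_um=0.0, rigid_placement=placement, seed=seed)


@pytest.fixture(scope="module")
def quiet_ref(template, config):
    embs = [generate_wildtype(quiet_spec(template, s), f"q{s}") for s in (0, 1)]
    return build_reference(embs, config)


class TestTemporalAlign:
    def test_identity(self, template, quiet_ref):
        emb = generate_wildtype(quiet_spec(template, 5), "t")
        tmap = temporal_align(emb, quiet_ref)
        assert tmap.rate == pytest.approx(1.0, abs=1e-6)
        assert tmap.offset == pytest.approx(0.0, abs=1e-4)

    def test_uniform_dilation_recovered(self, template, quiet_ref):
        """All observed times x1.1 -> fitted rate 1/1.1 (closed-form LSQ)."""
        emb = generate_wildtype(quiet_spec(template, 5), "t")
        for tr in emb.cells.values():
            tr.birth_time *= 1.1
            tr.end_time *= 1.1
            tr.positions[:, 0] *= 1.1
        tmap = temporal_align(emb, quiet_ref)
        assert tmap.rate == pytest.approx(1 / 1.1, abs=1e-6)

    def test_shift_recovered(self, template, quiet_ref):
        emb = generate_wildtype(quiet_spec(template, 5), "t")
        for tr in emb.cells.values():
            tr.birth_time += 20.0
            tr.end_time += 20.0
            tr.positions[:, 0] += 20.0
        tmap = temporal_align(emb, quiet_ref)
        assert tmap.rate == pytest.approx(1.0, abs=1e-6)
        assert tmap.offset == pytest.approx(20.0, abs=1e-3)

    def test_too_few_shared_divisions(self, template, quiet_ref):
        emb = generate_wildtype(quiet_spec(template, 5), "t")
        keep = [c for c in list(emb.cells) if len(c) <= 3][:6]
        emb.cells = {c: emb.cells[c] for c in keep}
        with pytest.raises(AlignmentError, match="shared divisions"):
            temporal_align(emb, quiet_ref)


class TestSpatialAlign:
    def test_noiseless_rigid_recovery(self, template, quiet_ref, config):
        """A known random placement is undone to numerical precision."""
        fixed = generate_wildtype(quiet_spec(template, 7, placement="fixed"), "t")
        placed = generate_wildtype(quiet_spec(template, 7, placement="random"), "t")
        tmap = temporal_align(placed, quiet_ref)
        tf = spatial_align(placed, quiet_ref, tmap, config)
        assert tf.residual_rms < 1e-9
        # composing the recovered transform with the placement reproduces the
        # fixed-placement alignment exactly
        tf0 = spatial_align(fixed, quiet_ref, temporal_align(fixed, quiet_ref),
                            config)
        rot = np.asarray(placed.meta["placement_rot"])
        shift = np.asarray(placed.meta["placement_shift"])
        assert np.allclose(tf.rotation @ rot, tf0.rotation, atol=1e-9)
        assert np.allclose(tf.rotation @ shift + tf.translation,
                           tf0.translation, atol=1e-6)

    def test_reflected_embryo_warns_and_stays_proper(self, template, quiet_ref, config):
        emb = generate_wildtype(quiet_spec(template, 7), "t")
        for tr in emb.cells.values():
            tr.positions[:, 1] *= -1.0
        tmap = temporal_align(emb, quiet_ref)
        with pytest.warns(UserWarning, match="reflection"):
            tf = spatial_align(emb, quiet_ref, tmap, config)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)
        assert tf.residual_rms > 1.0

    def test_collinear_points_degenerate(self):
        obs = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(AlignmentError, match="degenerate"):
            kabsch(obs, obs)

    def test_alignment_idempotence(self, template, config, ref10):
        emb = generate_wildtype(SimulationSpec(template=template, seed=55,
                                               rigid_placement="fixed"), "t")
        tmap = temporal_align(emb, ref10)
        tf = spatial_align(emb, ref10, tmap, config)
        for tr in emb.cells.values():
            tr.positions[:, 1:4] = tf.apply(tr.positions[:, 1:4])
        tf2 = spatial_align(emb, ref10, tmap, config)
        assert np.allclose(tf2.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(tf2.translation, 0.0, atol=1e-5)


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(AlignmentError, match="proper"):
            RigidTransform(R, np.zeros(3))

    def test_compose_matches_sequential_application(self):
        rng = np.random.default_rng(4)
        a = RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                           rng.normal(size=3))
        b = RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                           rng.normal(size=3))
        x = rng.normal(size=(10, 3))
        assert np.allclose(a.compose(b).apply(x), a.apply(b.apply(x)))


class TestBuildReference:
    def test_zero_noise_gives_floored_sds(self, quiet_ref, config):
        for cell, r in quiet_ref.cells.items():
            if r.n_obs >= 2:
                assert r.cycle_sd == config.cycle_sd_floor
            if np.isfinite(r.pos_dev_mean):
                assert r.pos_dev_mean < 0.05
                assert r.pos_dev_sd == config.pos_sd_floor

    def test_cycle_sd_recovery_within_30_percent(self, template, ref10):
        """Per-cell timing SD recovered from 10 noisy embryos (cv = 3%)."""
        rel = []
        for c, r in ref10.cells.items():
            if r.n_obs >= 8 and np.isfinite(r.cycle_sd):
                true_sd = 0.03 * template.cycle(c)
                rel.append(abs(r.cycle_sd - true_sd) / true_sd)
        assert np.median(rel) < 0.30

    def test_wildtype_cycle_cv_below_5_percent(self, template, ref10):
        """The synthetic wild type reproduces the <5% cycle-length CV of the
        real lineage."""
        cvs = [r.cycle_sd / r.cycle_mean for r in ref10.cells.values()
               if r.n_obs >= 8 and np.isfinite(r.cycle_mean)]
        assert np.median(cvs) < 0.05

    def test_invariance_to_rigid_placement(self, template, config, wt10, ref10):
        """Re-placing every input embryo leaves canonical positions unchanged."""
        rng = np.random.default_rng(999)
        replaced = []
        for emb in wt10[:5]:
            emb = emb.copy()
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-20, 20, 3)
            for tr in emb.cells.values():
                tr.positions[:, 1:4] = tr.positions[:, 1:4] @ R.T + t
            replaced.append(emb)
        ref_a = build_reference(wt10[:5], config)
        ref_b = build_reference(replaced, config)
        for c in ref_a.cells:
            assert np.allclose(ref_a.cells[c].positions,
                               ref_b.cells[c].positions, atol=1e-6)

    def test_neighbors_alive_concurrently(self, ref10):
        for cell, r in ref10.cells.items():
            for nb in r.neighbors:
                nr = ref10.cells[nb]
                assert nr.birth_mean <= r.neighbor_time <= nr.end_mean
            assert cell not in r.neighbors

    def test_needs_two_embryos(self, template, config):
        emb = generate_wildtype(quiet_spec(template), "solo")
        with pytest.raises(ValueError, match=">= 2"):
            build_reference([emb], config)


class TestExpectedPosition:
    def test_stored_time_exact_and_midpoint_mean(self, quiet_ref):
        cell = "ABplpappa"
        r = quiet_ref.cells[cell]
        assert np.allclose(quiet_ref.expected_position(cell, r.times[0]),
                           r.positions[0])
        mid = 0.5 * (r.times[0] + r.times[1])
        assert np.allclose(quiet_ref.expected_position(cell, mid),
                           0.5 * (r.positions[0] + r.positions[1]))

    def test_query_before_birth_errors(self, quiet_ref):
        with pytest.raises(QueryError):
            quiet_ref.expected_position("ABplpappa", 1.0)

    def test_unknown_cell_errors(self, quiet_ref):
        with pytest.raises(QueryError):
            quiet_ref.expected_position("ABplpapplll", 100.0)


class TestSerialization:
    def test_json_round_trip(self, ref10, tmp_path):
        path = tmp_path / "ref.json"
        ref10.to_json(path)
        from lineascope.reference import ReferenceModel
        back = ReferenceModel.from_json(path)
        assert set(back.cells) == set(ref10.cells)
        r0, r1 = ref10.cells["MSpaapp"], back.cells["MSpaapp"]
        assert r1.fate == r0.fate == "death"
        assert r1.death_mean == pytest.approx(r0.death_mean, abs=1e-3)
        assert r1.neighbors == r0.neighbors
        assert np.allclose(r0.positions, r1.positions, atol=1e-3)
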