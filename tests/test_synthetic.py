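"""Synthetic cohort generator: covariance targets, motion spikes, behavior."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fcgraph as fg
from fcgraph import qc
from fcgraph.synthetic import BEHAVIOR_DEFAULTS, BlockFcSpec

from conftest import make_ts


class TestBlockFcSpec:
    def test_uniform_layout(self):
        spec = BlockFcSpec.uniform(intra_z=0.3, inter_z=0.1)
        z = spec.block_z("I", "1")
        assert np.allclose(np.diag(z.to_numpy()), 0.3)
        assert z.loc["SVN", "DMN"] == 0.1

    def test_planted_effect_is_additive_and_specific(self):
        spec = fg.default_effect_spec(delta_z=0.15)
        base = spec.block_z("NI", "1")
        bumped = spec.block_z("NI", "2")
        assert bumped.loc["SVN", "SVN"] - base.loc["SVN", "SVN"] == pytest.approx(0.15)
        assert bumped.loc["DAN", "DAN"] == base.loc["DAN", "DAN"]
        assert np.allclose(spec.block_z("I", "2"), spec.block_z("I", "1"))

    def test_asymmetric_table_rejected(self):
        spec = BlockFcSpec.uniform()
        bad = spec.base.copy()
        bad.iloc[0, 1] = 0.5  # not mirrored
        with pytest.raises(ValueError, match="symmetric"):
            BlockFcSpec(spec.systems, bad)

    def test_z_magnitude_limit(self):
        spec = BlockFcSpec.uniform()
        with pytest.raises(ValueError):
            BlockFcSpec.uniform(intra_z=3.5)
        with pytest.raises(ValueError):
            spec.with_effect("I", "2", "SVN", "SVN", 2.9)


class TestBlockCovariance:
    def test_zero_spec_gives_identity(self, small_partition):
        spec = BlockFcSpec.uniform(intra_z=0.0, inter_z=0.0)
        res = fg.build_block_covariance(small_partition, spec.base)
        assert not res.repaired
        assert np.allclose(res.cov, np.eye(small_partition.n_rois))

    def test_single_block_tanh_value(self):
        # one intra-block at z = 0.3 on 10 ROIs: off-diagonal tanh(0.3)
        part = fg.NetworkPartition(
            tuple(f"r{i}" for i in range(10)),
            ("A",) * 5 + ("B",) * 5, systems=("A", "B"))
        z = pd.DataFrame([[0.3, 0.0], [0.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        res = fg.build_block_covariance(part, z)
        a = res.cov[:5, :5]
        off = a[~np.eye(5, dtype=bool)]
        assert np.allclose(off, np.tanh(0.3))
        assert np.allclose(off, 0.2913, atol=5e-4)
        assert np.allclose(res.cov[:5, 5:], 0.0)

    def test_infeasible_spec_repaired_to_pd(self):
        # two strongly coherent blocks forced to be uncorrelated with a third
        # system correlated with both: drives the matrix non-PD
        part = fg.NetworkPartition(
            tuple(f"r{i}" for i in range(12)),
            ("A",) * 4 + ("B",) * 4 + ("C",) * 4, systems=("A", "B", "C"))
        z = pd.DataFrame(
            [[2.5, 0.0, 0.9], [0.0, 2.5, 0.9], [0.9, 0.9, 2.5]],
            index=["A", "B", "C"], columns=["A", "B", "C"])
        res = fg.build_block_covariance(part, z)
        assert res.repaired
        eig = np.linalg.eigvalsh(res.cov)
        assert eig[0] > 0
        assert np.allclose(np.diag(res.cov), 1.0)
        # block means survive the repair to within 0.05
        for sa, sb in (("A", "A"), ("B", "B"), ("A", "C")):
            ia, ib = part.indices(sa), part.indices(sb)
            if sa == sb:
                sub = res.cov[np.ix_(ia, ia)]
                got = sub[np.triu_indices(len(ia), k=1)].mean()
            else:
                got = res.cov[np.ix_(ia, ib)].mean()
            assert abs(got - np.tanh(z.loc[sa, sb])) < 0.05

    def test_asymmetric_rejected(self, small_partition):
        z = BlockFcSpec.uniform().base.copy()
        z.iloc[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            fg.build_block_covariance(small_partition, z)


class TestSimulateTimeseries:
    def test_identity_cov_null_correlations(self):
        x = fg.simulate_subject_timeseries(np.eye(6), 10_000, seed=0)
        r = np.corrcoef(x, rowvar=False)
        off = r[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_same_seed_bit_identical(self):
        cov = np.eye(4)
        a = fg.simulate_subject_timeseries(cov, 100, seed=7)
        b = fg.simulate_subject_timeseries(cov, 100, seed=7)
        assert np.array_equal(a, b)

    def test_planted_pair_correlation(self):
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.5
        x = fg.simulate_subject_timeseries(cov, 5000, seed=3)
        r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert 0.45 < r < 0.55

    def test_non_pd_cov_rejected(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            fg.simulate_subject_timeseries(cov, 10, seed=0)


class TestInjectMotion:
    def _clean_ts(self, rng, n=240):
        return make_ts(1000 + 10 * rng.normal(size=(n, 8)),
                       run_lengths=(n // 2, n - n // 2))

    def test_no_spikes_fd_below_threshold(self, rng):
        ts = self._clean_ts(rng)
        _, motion, spikes = fg.inject_motion(ts, 0.0, 1.6, seed=1)
        assert spikes.size == 0
        assert np.all(qc.compute_fd(motion) < 0.8)

    def test_fd_exact_at_planted_frames(self, rng):
        ts = self._clean_ts(rng)
        _, motion, spikes = fg.inject_motion(ts, 0.1, 1.6, seed=2)
        fd = qc.compute_fd(motion)
        assert spikes.size > 0
        assert np.allclose(fd[spikes], 1.6, atol=1e-9)

    def test_dvars_exceeds_threshold_only_at_spikes(self, rng):
        ts = self._clean_ts(rng)
        out, _, spikes = fg.inject_motion(ts, 0.1, 1.6, seed=3)
        dv = qc.compute_dvars(out, divisor=float(out.data.mean()))
        flagged = np.flatnonzero(dv > 0.05)
        assert np.array_equal(flagged, spikes)

    def test_bookkeeping_count(self, rng):
        ts = self._clean_ts(rng)
        _, motion, spikes = fg.inject_motion(ts, 0.1, 1.6, seed=4)
        fd = qc.compute_fd(motion)
        assert np.array_equal(np.flatnonzero(fd > 0.8), spikes)

    def test_guard_window_respected(self, rng):
        ts = self._clean_ts(rng)
        _, _, spikes = fg.inject_motion(ts, 0.3, 1.6, seed=5, guard_frames=6)
        run2_start = ts.run_lengths[0]
        assert np.all((spikes >= 6))
        assert not np.any((spikes >= run2_start) & (spikes < run2_start + 6))


class TestSimulateBehavior:
    def _design(self, n, rng):
        frame = pd.DataFrame({
            "subject": [f"s{i}" for i in range(n)],
            "group": ["I"] * (n // 2) + ["NI"] * (n - n // 2),
            "age": rng.uniform(7, 12, n),
            "scanner": (rng.random(n) < 0.5).astype(float),
        })
        return fg.StudyDesign(frame, behaviors=())

    def test_zero_coupling_null_bound(self, rng):
        n = 2000
        design = self._design(n, rng)
        dfc = rng.normal(size=n)
        out = fg.simulate_behavior(design, dfc, 0.0, seed=1, behavior="b")
        r = np.corrcoef(dfc, out.behavior_delta("b"))[0, 1]
        assert abs(r) < 2 / np.sqrt(n)

    def test_full_coupling_exact(self, rng):
        design = self._design(40, rng)
        dfc = rng.normal(size=40)
        out = fg.simulate_behavior(design, dfc, 1.0, seed=2, behavior="b")
        r = np.corrcoef(dfc, out.behavior_delta("b"))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_moderate_coupling_recovered(self, rng):
        n = 2000
        design = self._design(n, rng)
        dfc = rng.normal(size=n)
        out = fg.simulate_behavior(design, dfc, 0.4, seed=3, behavior="b")
        r = np.corrcoef(dfc, out.behavior_delta("b"))[0, 1]
        assert 0.36 < r < 0.44

    def test_group_offsets_applied(self, rng):
        design = self._design(400, rng)
        dfc = rng.normal(size=400)
        out = fg.simulate_behavior(
            design, dfc, 0.0, seed=4, behavior="b",
            delta_mean={"I": -3.0, "NI": -1.0}, delta_sd=0.5)
        d = out.behavior_delta("b")
        g = out.frame["group"] == "I"
        assert d[g.to_numpy()].mean() == pytest.approx(-3.0, abs=0.15)
        assert d[~g.to_numpy()].mean() == pytest.approx(-1.0, abs=0.15)

    def test_length_mismatch_rejected(self, rng):
        design = self._design(10, rng)
        with pytest.raises(ValueError, match="per subject"):
            fg.simulate_behavior(design, np.zeros(9), 0.2, seed=0)


class TestSimulateCohort:
    def test_study_dimension_bundle_loads(self, tmp_path):
        """Full-size bundle (18+11 subjects, 141 ROIs, 246 frames) round-trips
        through the pipeline reader."""
        cfg = fg.SyntheticConfig(seed=5)
        co = fg.simulate_cohort(cfg)
        assert co.design.n_subjects == 29
        assert co.partition.n_rois == 141
        out = tmp_path / "bundle"
        co.write(out)
        bundle = fg.load_inputs(out, tr_seconds=2.0,
                                run_lengths=cfg.run_lengths())
        assert len(bundle.sessions) == 29
        ts, motion = bundle.sessions["sub-01"]["2"]
        assert ts.n_frames == 246 == motion.shape[0]

    def test_same_seed_identical_ground_truth(self):
        cfg = dict(n_per_group=(3, 2), n_frames=80, roi_count=16, seed=9)
        a = fg.simulate_cohort(fg.SyntheticConfig(**cfg))
        b = fg.simulate_cohort(fg.SyntheticConfig(**cfg))
        assert a.ground_truth == b.ground_truth
        assert np.array_equal(a.timeseries("sub-01", "1").data,
                              b.timeseries("sub-01", "1").data)
        pd.testing.assert_frame_equal(a.design.frame, b.design.frame)

    def test_ground_truth_spikes_match_qc(self, small_cohort):
        co = small_cohort
        for subject in list(co.sessions)[:3]:
            for session in ("1", "2"):
                ts = co.timeseries(subject, session)
                motion = co.motion(subject, session)
                rep = qc.make_qc_report(ts, motion,
                                        dvars_divisor=float(ts.data.mean()))
                flagged = np.flatnonzero(~rep.keep)
                truth = np.array(
                    co.ground_truth["spike_frames"][subject][session], int)
                assert np.array_equal(flagged, truth)

    def test_behavior_columns_present(self, small_cohort):
        for b in BEHAVIOR_DEFAULTS:
            assert f"{b}_t1" in small_cohort.design.frame.columns
            assert f"{b}_t2" in small_cohort.design.frame.columns

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            fg.SyntheticConfig(n_per_group=(1, 5))
        with pytest.raises(ValueError):
            fg.SyntheticConfig(n_frames=10)
        with pytest.raises(ValueError):
            fg.SyntheticConfig(motion_spike_rate=0.6)
        with pytest.raises(ValueError):
            fg.SyntheticConfig(behavior_coupling=1.5)


class TestSpikesAfterDiscard:
    def test_mapping_across_runs(self):
        spikes = np.array([10, 130])
        out = fg.spikes_after_discard(spikes, (123, 123), 5)
        assert np.array_equal(out, [5, 120])

    def test_discarded_spikes_dropped(self):
        out = fg.spikes_after_discard(np.array([2, 10]), (50, 50), 5)
        assert np.array_equal(out, [5])
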