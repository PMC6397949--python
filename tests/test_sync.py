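import numpy as np
import pandas as pd
import pytest

from blinksync import (SyncMap, VoxelSeriesSet, glm_residualize,
                       hrf_regressors, make_block_schedule,
                       paired_sync_contrast, simulate_voxel_pair,
                       split_concat_condition, voxelwise_sync)
from blinksync.design import Block, BlockSchedule


@pytest.fixture
def schedule():
    return make_block_schedule(seed=21)


def make_set(data, tr=1.0, n_runs=1):
    return VoxelSeriesSet.from_array(np.asarray(data, dtype=float), tr, n_runs)


class TestGLMResidualize:
    def test_task_free_input_equals_highpassed_input(self, schedule, rng):
        """With no task signal the GLM only removes drift: projecting the
        residuals again changes nothing (idempotent projection)."""
        data = rng.standard_normal((2040, 4))
        vs = make_set(data, n_runs=4)
        res1 = glm_residualize(vs, schedule)
        res2 = glm_residualize(
            VoxelSeriesSet(data=res1.data, tr=1.0,
                           run_boundaries=res1.run_boundaries,
                           voxel_ids=res1.voxel_ids,
                           volume_times=res1.volume_times),
            schedule, drop_initial=0)
        assert np.allclose(res1.data, res2.data, atol=1e-8)

    def test_pure_task_signal_removed_to_numerical_zero(self, schedule):
        X = hrf_regressors(schedule, 2040, 1.0)
        data = np.column_stack([2.0 * X[:, 0] + 1.0, -3.0 * X[:, 1] + 0.5])
        res = glm_residualize(make_set(data, n_runs=4), schedule)
        assert np.linalg.norm(res.data) / np.linalg.norm(data) < 1e-6

    def test_volume_bookkeeping_matches_design(self, schedule, rng):
        """4 runs x (510 - 10) volumes = 2000 analyzed volumes."""
        vs = make_set(rng.standard_normal((2040, 3)), n_runs=4)
        res = glm_residualize(vs, schedule)
        assert res.data.shape[0] == 2000
        assert res.volumes_per_run == 500
        assert res.volume_times[0] == pytest.approx(10.0)

    def test_run_count_mismatch_rejected(self, schedule, rng):
        vs = make_set(rng.standard_normal((1020, 3)), n_runs=2)
        with pytest.raises(ValueError, match="runs"):
            glm_residualize(vs, schedule)


class TestSplitConcat:
    def test_canonical_live_concatenation_has_640_volumes(self, schedule, rng):
        vs = make_set(rng.standard_normal((2040, 3)), n_runs=4)
        res = glm_residualize(vs, schedule)
        live = split_concat_condition(res, schedule, "LIVE")
        assert live.data.shape[0] == 640
        replay = split_concat_condition(res, schedule, "REPLAY")
        assert replay.data.shape[0] == 640

    def test_single_block_at_tr_one_gives_duration_volumes(self):
        sch = BlockSchedule([Block("LIVE", 5.0, 20.0, 0)], run_length=40.0,
                            n_runs=1)
        vs = make_set(np.arange(40.0)[:, None])
        out = split_concat_condition(vs, sch, "LIVE")
        assert out.data.shape[0] == 20

    def test_half_open_edge_inclusion_by_hand_enumeration(self):
        # volumes at t = 0..9; block [3, 7) holds volumes 3,4,5,6 only
        sch = BlockSchedule([Block("LIVE", 3.0, 4.0, 0)], run_length=10.0,
                            n_runs=1)
        vs = make_set(np.arange(10.0)[:, None])
        out = split_concat_condition(vs, sch, "LIVE")
        assert out.data[:, 0].tolist() == [3.0, 4.0, 5.0, 6.0]

    def test_empty_selection_rejected(self):
        sch = BlockSchedule([Block("LIVE", 3.0, 4.0, 0)], run_length=10.0,
                            n_runs=1)
        vs = make_set(np.arange(10.0)[:, None])
        with pytest.raises(ValueError):
            split_concat_condition(vs, sch, "REPLAY")


class TestVoxelwiseSync:
    def test_identical_inputs_give_r_one(self, rng):
        data = rng.standard_normal((100, 5))
        m = voxelwise_sync(make_set(data), make_set(data.copy()))
        assert np.allclose(m.r, 1.0)
        assert np.all(np.isfinite(m.z))

    def test_null_z_sd_matches_fisher_variance(self, rng):
        """Independent 640-volume series: z ~ Normal(0, 1/sqrt(637))."""
        n = 640
        a = make_set(rng.standard_normal((n, 2000)))
        b = make_set(rng.standard_normal((n, 2000)))
        m = voxelwise_sync(a, b)
        sd = m.z.std()
        assert abs(sd - 1.0 / np.sqrt(n - 3)) / (1.0 / np.sqrt(n - 3)) < 0.10

    def test_latent_rho_recovered_after_residualization(self):
        sch = make_block_schedule(seed=13)
        sim = simulate_voxel_pair(400, 2040, shared_rho=0.5, task_amp=1.0,
                                  schedule=sch, seed=5)
        ra = glm_residualize(make_set(sim.series_a, n_runs=4), sch)
        rb = glm_residualize(make_set(sim.series_b, n_runs=4), sch)
        m = voxelwise_sync(ra, rb)
        assert m.z.mean() == pytest.approx(np.arctanh(0.5), abs=0.03)

    def test_zero_variance_voxel_gets_z_zero(self, rng):
        a = rng.standard_normal((50, 2))
        a[:, 1] = 3.0
        m = voxelwise_sync(make_set(a), make_set(rng.standard_normal((50, 2))))
        assert m.z[1] == 0.0
        assert np.isfinite(m.z[0])

    def test_affine_rescaling_invariance(self, rng):
        a = rng.standard_normal((80, 4))
        b = rng.standard_normal((80, 4))
        base = voxelwise_sync(make_set(a), make_set(b))
        scaled = voxelwise_sync(make_set(3.0 * a - 7.0),
                                make_set(0.5 * b + 2.0))
        assert scaled.r == pytest.approx(base.r, abs=1e-12)

    def test_shape_and_id_mismatches_rejected(self, rng):
        a = make_set(rng.standard_normal((50, 3)))
        b = make_set(rng.standard_normal((40, 3)))
        with pytest.raises(ValueError):
            voxelwise_sync(a, b)


class TestPairedSyncContrast:
    def _map(self, z, cond="LIVE"):
        z = np.asarray(z, dtype=float)
        return SyncMap(voxel_ids=np.arange(len(z)), r=np.tanh(z), z=z,
                       condition=cond, n_volumes=640)

    def test_identical_map_sets_give_zero_t(self, rng):
        maps = [self._map(rng.standard_normal(6)) for _ in range(4)]
        out = paired_sync_contrast(maps, [self._map(m.z, "REPLAY")
                                          for m in maps])
        assert np.allclose(out["t"], 0.0)

    def test_matches_hand_paired_t_on_three_pairs(self):
        za = [np.array([0.5, 0.1]), np.array([0.6, 0.2]),
              np.array([0.4, 0.15])]
        zb = [np.array([0.2, 0.1]), np.array([0.3, 0.25]),
              np.array([0.1, 0.05])]
        out = paired_sync_contrast([self._map(z) for z in za],
                                   [self._map(z, "REPLAY") for z in zb])
        for v in range(2):
            d = np.array([a[v] - b[v] for a, b in zip(za, zb)])
            t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
            assert out.loc[v, "t"] == pytest.approx(t_hand, rel=1e-10)

    def test_planted_live_specific_sync_is_localized(self):
        """Voxels carrying extra latent correlation only during live blocks
        dominate the live-minus-replay contrast."""
        from blinksync import RunConfig, SyncConfig, run_sync

        cfg = SyncConfig(seed=17, n_dyads=6, n_voxels=60, rho_live=0.6,
                         live_voxels=10, task_amp=1.0)
        bundle = run_sync(cfg)
        out = bundle["contrast"]
        top10 = out.nlargest(10, "t")["voxel_id"].to_numpy()
        assert len(np.intersect1d(top10, np.arange(10))) >= 8

    def test_fewer_than_three_pairs_rejected(self, rng):
        maps = [self._map(rng.standard_normal(3)) for _ in range(2)]
        with pytest.raises(ValueError):
            paired_sync_contrast(maps, maps)


def test_fisher_z_equals_atanh_closed_form(rng):
    a = make_set(rng.standard_normal((100, 20)))
    b = make_set(rng.standard_normal((100, 20)))
    m = voxelwise_sync(a, b)
    assert m.z == pytest.approx(np.arctanh(m.r), abs=1e-12)
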