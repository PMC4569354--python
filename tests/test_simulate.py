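import numpy as np
import pytest

from megnet import (CoupledPair, SimulationConfig, get_band, make_cohort,
                    multitaper_csd, simulate_subject)
from megnet.simulate import (exchangeable_networks, exchangeable_strength_maps,
                             narrowband_noise, phase_shift,
                             planted_clump_config)


def _pair_config(grid, coupling=1.0, lag=np.pi / 2, seed=5, n_epochs=20,
                 noise=1e-18, effect=1.0):
    a = int(np.argmin(np.linalg.norm(grid.positions - [0.03, 0.0, 0.03], axis=1)))
    b = int(np.argmin(np.linalg.norm(grid.positions - [-0.03, 0.0, 0.03], axis=1)))
    cfg = SimulationConfig(
        n_subjects_per_group=(2, 2), n_epochs=n_epochs, epoch_length_s=2.0,
        fs=256.0, coupled_pairs=(CoupledPair(a, b, "beta2", lag, coupling),),
        planted_group_effect=effect, sensor_noise_sd=noise, seed=seed)
    return cfg, a, b


class TestCoupledPairValidation:
    def test_self_coupling_rejected(self):
        with pytest.raises(ValueError, match="itself"):
            CoupledPair(3, 3, "alpha", np.pi / 2, 0.5)

    def test_zero_or_pi_lag_rejected(self):
        for lag in (0.0, np.pi):
            with pytest.raises(ValueError, match="lag"):
                CoupledPair(0, 1, "alpha", lag, 0.5)

    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CoupledPair(0, 1, "alpha", np.pi / 2, 1.2)


class TestSourceConstruction:
    def test_narrowband_noise_band_limited(self, rng):
        band = get_band("beta2")
        x = narrowband_noise(rng, band, 8192, 256.0)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(8192, 1 / 256.0)
        inband = spec[(freqs >= band.low) & (freqs <= band.high)].sum()
        assert inband / spec.sum() > 0.95
        assert np.sqrt(np.mean(x**2)) == pytest.approx(1.0, rel=1e-9)

    def test_phase_shift_imposes_lag(self, rng):
        """The shifted trace has the requested phase lead at the band centre."""
        band = get_band("alpha")
        x = narrowband_noise(rng, band, 16384, 256.0)
        y = phase_shift(x, np.pi / 2)
        X = np.fft.rfft(x)
        Y = np.fft.rfft(y)
        freqs = np.fft.rfftfreq(16384, 1 / 256.0)
        sel = (freqs > 9) & (freqs < 11)
        phases = np.angle(X[sel] * np.conj(Y[sel]))
        assert np.abs(np.median(phases) - np.pi / 2) < 0.05

    def test_lagged_pair_source_imaginary_coherence_near_one(self, rng):
        """Strength-1 coupling at 90 degrees: |Im coherency| of the traces ~ 1."""
        band = get_band("beta2")
        n = 30 * 512
        s = narrowband_noise(rng, band, n, 256.0)
        traces = np.stack([s, phase_shift(s, np.pi / 2)])
        data = traces.reshape(2, 30, 512).transpose(1, 0, 2)
        _, csd = multitaper_csd(data, 256.0, band)
        S = csd.matrix
        imcoh = abs((S[0, 1] / np.sqrt(S[0, 0].real * S[1, 1].real)).imag)
        assert imcoh > 0.97


class TestSimulateSubject:
    def test_bit_identical_with_same_seed(self, grid, leadfield, sensors):
        cfg, _, _ = _pair_config(grid)
        r1, _ = simulate_subject(cfg, grid, leadfield, sensors, "control")
        r2, _ = simulate_subject(cfg, grid, leadfield, sensors, "control")
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_group_effect_only_for_patients(self, grid, leadfield, sensors):
        cfg, _, _ = _pair_config(grid, coupling=0.4, effect=2.0)
        _, info_p = simulate_subject(cfg, grid, leadfield, sensors, "patient")
        _, info_c = simulate_subject(cfg, grid, leadfield, sensors, "control")
        assert info_p["coupling_effect"] == 2.0
        assert info_c["coupling_effect"] == 1.0

    def test_effect_above_unity_coupling_rejected(self, grid, leadfield, sensors):
        cfg, _, _ = _pair_config(grid, coupling=0.8, effect=2.0)
        with pytest.raises(ValueError, match="above 1"):
            simulate_subject(cfg, grid, leadfield, sensors, "patient")

    def test_unknown_node_rejected(self, grid, leadfield, sensors):
        cfg = SimulationConfig(
            coupled_pairs=(CoupledPair(0, 10_000, "alpha", np.pi / 2, 0.5),),
            n_epochs=1, epoch_length_s=1.0, fs=256.0)
        with pytest.raises(ValueError, match="outside grid"):
            simulate_subject(cfg, grid, leadfield, sensors, "control")

    def test_zero_coupling_sensor_covariance_additive(self, grid, leadfield,
                                                      sensors):
        """With no coupling the sensor covariance is the sum of the two
        independent source projections plus the isotropic noise floor."""
        from megnet.simulate import _gain_column, _tangential_orientation
        cfg, a, b = _pair_config(grid, coupling=0.0, lag=np.pi / 2, seed=77,
                                 n_epochs=40, noise=5e-15)
        rec, _ = simulate_subject(cfg, grid, leadfield, sensors, "control")
        x = rec.data.transpose(1, 0, 2).reshape(sensors.count, -1)
        emp = x @ x.T / x.shape[1]
        center = grid.positions.mean(axis=0)
        model = np.zeros_like(emp)
        for node in (a, b):
            col = _gain_column(leadfield, node,
                               _tangential_orientation(grid.positions[node],
                                                       center))
            model += np.outer(col, col) * cfg.dipole_moment**2
        model += cfg.sensor_noise_sd**2 * np.eye(sensors.count)
        scale = np.abs(emp).max()
        assert np.abs(emp - model).max() < 0.15 * scale


class TestMakeCohort:
    def test_study_size_cohort(self, grid, leadfield, sensors):
        cfg = SimulationConfig(n_subjects_per_group=(13, 19), n_epochs=1,
                               epoch_length_s=1.0, fs=128.0, seed=0)
        subjects, manifest = make_cohort(cfg, grid, leadfield, sensors)
        assert len(subjects) == 32
        groups = [g for _, g, _ in subjects]
        assert groups.count("patient") == 13 and groups.count("control") == 19
        assert manifest["groups"] == {"patient": 13, "control": 19}

    def test_manifest_planted_nodes(self, grid, leadfield, sensors):
        cfg, a, b = _pair_config(grid)
        cfg = SimulationConfig(**{**cfg.__dict__, "n_epochs": 1,
                                  "epoch_length_s": 1.0})
        _, manifest = make_cohort(cfg, grid, leadfield, sensors)
        assert manifest["planted_nodes"] == sorted({a, b})

    def test_subject_seeds_are_master_plus_ordinal(self, grid, leadfield,
                                                   sensors):
        cfg = SimulationConfig(n_subjects_per_group=(2, 2), n_epochs=1,
                               epoch_length_s=1.0, fs=128.0, seed=100)
        _, manifest = make_cohort(cfg, grid, leadfield, sensors)
        assert [s["seed"] for s in manifest["subjects"]] == [100, 101, 102, 103]

    def test_null_cohort_groups_exchangeable(self, grid, leadfield, sensors):
        """planted_group_effect=1: group labels carry no signal information."""
        cfg, a, b = _pair_config(grid, coupling=0.5, effect=1.0, noise=1e-14,
                                 n_epochs=4)
        p, _ = simulate_subject(cfg, grid, leadfield, sensors, "patient")
        c, _ = simulate_subject(cfg, grid, leadfield, sensors, "control")
        np.testing.assert_array_equal(p.data, c.data)


class TestPlantedClumpConfig:
    def test_clumps_are_contiguous_and_disjoint(self, grid):
        cfg, truth = planted_clump_config(grid, seed=0)
        a, b = set(truth["clump_a"]), set(truth["clump_b"])
        assert len(a) == 5 and len(b) == 5 and not a & b
        adj = grid.adjacency()
        for clump in (truth["clump_a"], truth["clump_b"]):
            sub = adj[np.ix_(clump, clump)]
            from scipy.sparse.csgraph import connected_components
            n_comp, _ = connected_components(sub, directed=False)
            assert n_comp == 1

    def test_pairs_share_signal_group(self, grid):
        cfg, _ = planted_clump_config(grid)
        assert all(p.signal_id == "clump" for p in cfg.coupled_pairs)
        assert cfg.planted_group_effect == 1.5


class TestNullGenerators:
    def test_strength_maps_shapes_and_determinism(self, grid):
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(0)
        a1, b1 = exchangeable_strength_maps(rng1, 13, 19, grid.positions[:20])
        a2, b2 = exchangeable_strength_maps(rng2, 13, 19, grid.positions[:20])
        assert a1.shape == (13, 20) and b1.shape == (19, 20)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)

    def test_networks_valid_adjacency(self):
        rng = np.random.default_rng(1)
        a, b = exchangeable_networks(rng, 4, 5, 8)
        for net in np.concatenate([a, b]):
            np.testing.assert_array_equal(net, net.T)
            assert np.all(np.diag(net) == 0)
            assert net.min() >= 0 and net.max() <= 1
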