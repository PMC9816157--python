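import numpy as np
import pytest

from conftest import random_neutral_config, rocksalt_config
from efgrelax.core import Configuration
from efgrelax.efg import (EwaldParams, SingularityError, efg_direct_sum,
                          efg_ewald, efg_series, radial_distribution,
                          shell_decompose, symmetric_traceless,
                          variance_by_coordination)
from efgrelax.synthetic import TENSOR_BASIS


def frob(t):
    return np.linalg.norm(t)


class TestDirectSum:
    def test_single_charge_closed_form(self):
        """q = +1e at 2 A along z: V_zz = 2q/r^3 = 0.25 e/A^3."""
        cfg = Configuration([[0, 0, 0], [0, 0, 2.0]], [0.0, 1.0], 100.0)
        V = efg_direct_sum(cfg, 0).tensor
        assert V[2, 2] == pytest.approx(0.25, abs=1e-12)
        assert V[0, 0] == pytest.approx(-0.125, abs=1e-12)
        assert V[1, 1] == pytest.approx(-0.125, abs=1e-12)
        assert abs(V[0, 1]) + abs(V[0, 2]) + abs(V[1, 2]) < 1e-12

    def test_superposition_two_charges(self):
        cfg = Configuration([[0, 0, 0], [0, 0, 2.0], [0, 0, -2.0]],
                            [0.0, 1.0, 1.0], 100.0)
        V = efg_direct_sum(cfg, 0).tensor
        assert V[2, 2] == pytest.approx(0.5, abs=1e-12)

    def test_rock_salt_site_symmetry(self):
        """A cubic-symmetric site has zero EFG; the lattice-sum residual
        shrinks with the summation radius."""
        cfg = rocksalt_config()
        coarse = frob(efg_direct_sum(cfg, 0, 4, window="smooth").tensor)
        fine = frob(efg_direct_sum(cfg, 0, 8, window="smooth").tensor)
        assert fine < 1e-8
        assert fine < coarse

    def test_singularity_detection(self):
        cfg = Configuration([[0, 0, 0], [0, 0, 1e-8]], [1.0, 1.0], 10.0)
        with pytest.raises(SingularityError):
            efg_direct_sum(cfg, 0)


class TestEwald:
    def test_rock_salt_zero(self, rocksalt):
        V = efg_ewald(rocksalt, [0], EwaldParams.auto(rocksalt.box_edge))[0]
        assert frob(V.tensor) < 1e-8

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_direct_sum_oracle(self, seed):
        cfg = random_neutral_config(seed)
        ew = efg_ewald(cfg, [0], EwaldParams.auto(cfg.box_edge, 1e-10))[0]
        oracle = efg_direct_sum(cfg, 0, image_shells=8, window="smooth")
        rel = frob(ew.tensor - oracle.tensor) / frob(oracle.tensor)
        assert rel < 1e-6

    def test_alpha_invariance(self, neutral_config):
        cfg = neutral_config
        results = [
            efg_ewald(cfg, [0], EwaldParams.auto(cfg.box_edge, 1e-10,
                                                 alpha=a))[0].tensor
            for a in (0.25, 0.35, 0.45)
        ]
        scale = frob(results[1])
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                assert frob(results[i] - results[j]) / scale < 1e-8

    def test_translation_invariance(self, neutral_config):
        cfg = neutral_config
        params = EwaldParams.auto(cfg.box_edge, 1e-10)
        v0 = efg_ewald(cfg, [0], params)[0].tensor
        shift = np.array([3.17, -1.4, 7.9])
        cfg2 = Configuration(cfg.positions + shift, cfg.charges,
                             cfg.box_edge)
        v1 = efg_ewald(cfg2, [0], params)[0].tensor
        assert frob(v0 - v1) / frob(v0) < 1e-9

    def test_rotation_equivariance(self, neutral_config):
        """A lattice-compatible 90-degree rotation acts as V -> R V R^T."""
        cfg = neutral_config
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        params = EwaldParams.auto(cfg.box_edge, 1e-10)
        v0 = efg_ewald(cfg, [0], params)[0].tensor
        rotated = Configuration(cfg.positions @ R.T, cfg.charges,
                                cfg.box_edge)
        v1 = efg_ewald(rotated, [0], params)[0].tensor
        assert frob(v1 - R @ v0 @ R.T) / frob(v0) < 1e-9

    def test_linearity_in_charges(self, neutral_config):
        cfg = neutral_config
        params = EwaldParams.auto(cfg.box_edge, 1e-10)
        v1 = efg_ewald(cfg, [0], params)[0].tensor
        doubled = Configuration(cfg.positions, 2.0 * cfg.charges,
                                cfg.box_edge)
        v2 = efg_ewald(doubled, [0], params)[0].tensor
        assert np.allclose(v2, 2.0 * v1, rtol=1e-12, atol=1e-15)

    def test_symmetric_traceless_everywhere(self, neutral_config):
        for p in range(4):
            t = efg_ewald(neutral_config, [p],
                          EwaldParams.auto(12.0))[0]
            t.validate(tol=1e-8)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            EwaldParams(alpha=-1.0, r_cut=5.0, n_kmax=4)
        with pytest.raises(ValueError):
            EwaldParams(alpha=0.5, r_cut=5.0, n_kmax=4, accuracy=0.0)


class TestEFGSeries:
    def test_constant_trajectory(self, neutral_config):
        traj = [Configuration(neutral_config.positions,
                              neutral_config.charges,
                              neutral_config.box_edge, time=10.0 * i)
                for i in range(3)]
        series = efg_series(traj, [0, 1])
        assert series.n_frames == 3 and series.n_probes == 2
        assert np.allclose(series.data[0], series.data[1])
        assert np.allclose(series.data[1], series.data[2])
        assert series.variance() > 0

    def test_non_uniform_spacing_rejected(self, neutral_config):
        traj = []
        for t in (0.0, 10.0, 25.0):
            traj.append(Configuration(neutral_config.positions,
                                      neutral_config.charges,
                                      neutral_config.box_edge, time=t))
        with pytest.raises(ValueError, match="non-uniform"):
            efg_series(traj, [0])

    def test_deterministic_recomputation(self, neutral_config):
        traj = [Configuration(neutral_config.positions,
                              neutral_config.charges,
                              neutral_config.box_edge, time=float(i))
                for i in range(2)]
        a = efg_series(traj, [0]).data
        b = efg_series(traj, [0]).data
        assert np.array_equal(a, b)


class TestShellDecomposition:
    def test_single_source_in_first_shell(self):
        cfg = Configuration([[5, 5, 5], [5, 5, 7.0]], [0.0, 1.0], 20.0)
        sd = shell_decompose(cfg, 0, [3.0])
        assert np.allclose(sd.shell_tensors[0], sd.total)
        assert frob(sd.remainder) == 0.0

    def test_additivity_partition(self, neutral_config):
        sd = shell_decompose(neutral_config, 0, [2.5, 4.0, 5.5])
        sd.check_additivity(tol=1e-10)

    def test_radii_validation(self, neutral_config):
        with pytest.raises(ValueError):
            shell_decompose(neutral_config, 0, [7.0])   # >= L/2
        with pytest.raises(ValueError):
            shell_decompose(neutral_config, 0, [3.0, 2.0])

    def test_molecule_grouping_keeps_molecules_whole(self):
        """A 'water' straddling a shell boundary is assigned entirely by
        its oxygen."""
        pos = np.array([[10.0, 10, 10],      # probe
                        [12.9, 10, 10],      # O, inside 3 A shell
                        [13.4, 10, 10]])     # H, outside
        cfg = Configuration(pos, [1.0, -0.8, 0.4], 30.0,
                            species=["Na", "O", "H"])
        sd_mol = shell_decompose(cfg, 0, [3.0], grouping="molecule",
                                 molecule_ids=[0, 1, 1])
        assert frob(sd_mol.remainder) == 0.0
        sd_atom = shell_decompose(cfg, 0, [3.0], grouping="atom")
        assert frob(sd_atom.remainder) > 0.0

    def test_cumulative_variance_approaches_ewald(self):
        """The minimum-image shell sums capture the periodic variance once
        the outermost radius nears L/2 (local screening)."""
        from efgrelax.synthetic import ToySystemSpec, gen_langevin_trajectory
        traj = gen_langevin_trajectory(
            ToySystemSpec(n_steps=3000, sample_every=100, seed=5))
        configs = traj.configurations()
        L = configs[0].box_edge
        radii = np.linspace(2.0, 0.49 * L, 8)
        params = EwaldParams.auto(L, 1e-8)
        probes = [0, 2, 4, 6]
        cum_var = ew_var = 0.0
        for cfg in configs:
            tensors = efg_ewald(cfg, probes, params)
            for p, tw in zip(probes, tensors):
                sd = shell_decompose(cfg, p, radii)
                cum_var += np.sum(sd.shell_tensors.sum(axis=0) ** 2)
                ew_var += np.sum(tw.tensor ** 2)
        assert cum_var / ew_var == pytest.approx(1.0, abs=0.05)


class TestRadialDistribution:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(0)
        configs = [Configuration(rng.uniform(0, 10, (200, 3)),
                                 np.zeros(200), 10.0,
                                 species=["X"] * 200, time=float(i))
                   for i in range(20)]
        rdf = radial_distribution(configs, "X", "X", bin_width=0.25)
        sel = rdf.r > 1.0
        assert np.mean(np.abs(rdf.g[sel] - 1.0)) < 0.1

    def test_two_fixed_particles_single_bin(self):
        cfg = Configuration([[0, 0, 0], [0, 0, 3.0]], [0, 0], 20.0,
                            species=["A", "B"])
        rdf = radial_distribution([cfg], "A", "B", bin_width=0.2)
        occupied = np.flatnonzero(rdf.g > 0)
        assert occupied.size == 1
        assert rdf.r[occupied[0]] == pytest.approx(3.0, abs=0.2)

    def test_empty_selection_raises(self, neutral_config):
        with pytest.raises(ValueError):
            radial_distribution([neutral_config], "Zz", "X")

    def test_first_peak_stable_across_halves(self):
        from efgrelax.synthetic import ToySystemSpec, gen_langevin_trajectory
        traj = gen_langevin_trajectory(
            ToySystemSpec(n_steps=4000, sample_every=50, seed=8))
        configs = traj.configurations()
        half = len(configs) // 2
        bw = 0.2
        g1 = radial_distribution(configs[:half], "Na", "Cl", bin_width=bw)
        g2 = radial_distribution(configs[half:], "Na", "Cl", bin_width=bw)
        p1 = g1.r[np.argmax(g1.g)]
        p2 = g2.r[np.argmax(g2.g)]
        assert abs(p1 - p2) <= bw + 1e-12


class TestVarianceByCoordination:
    @staticmethod
    def _frames_with_coordination(counts, seed=0, radius=3.0):
        """Configurations with a prescribed number of partners inside the
        first shell of particle 0."""
        rng = np.random.default_rng(seed)
        configs = []
        for i, cn in enumerate(counts):
            pos = [[15.0, 15.0, 15.0]]
            for k in range(cn):          # inside
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                pos.append(pos[0] + u * rng.uniform(1.5, radius - 0.2))
            for k in range(6 - cn):      # outside
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                pos.append(pos[0] + u * rng.uniform(radius + 0.5, 6.0))
            configs.append(Configuration(
                np.asarray(pos), np.zeros(7), 30.0,
                species=["Na"] + ["O"] * 6, time=float(i)))
        return configs

    def test_occupancies_sum_to_one(self):
        from efgrelax.efg import EFGSeries
        counts = [4, 5, 5, 6, 6, 6]
        configs = self._frames_with_coordination(counts)
        rng = np.random.default_rng(1)
        data = rng.standard_normal((len(counts), 1, 3, 3))
        data = 0.5 * (data + np.transpose(data, (0, 1, 3, 2)))
        series = EFGSeries(data=data, dt=1.0, probes=[0])
        out = variance_by_coordination(series, configs, "O", 3.0)
        assert sum(v["occupancy"] for v in out.values()) \
            == pytest.approx(1.0, abs=1e-12)
        assert set(out) == {4, 5, 6}

    def test_single_class_recovers_total_variance(self):
        from efgrelax.efg import EFGSeries
        counts = [6] * 5
        configs = self._frames_with_coordination(counts)
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 1, 3, 3))
        series = EFGSeries(data=data, dt=1.0, probes=[0])
        out = variance_by_coordination(series, configs, "O", 3.0)
        assert list(out) == [6]
        assert out[6]["variance"] == pytest.approx(series.variance(),
                                                   rel=1e-12)

    def test_planted_conditional_variance_ratio(self):
        """Classes constructed with variance ratio 0.9 are recovered."""
        from efgrelax.efg import EFGSeries
        n_per = 6000
        counts = [5] * n_per + [6] * n_per
        rng = np.random.default_rng(3)
        var_b = 1.0
        var_a = 0.9 * var_b
        coeffs = np.concatenate([
            np.sqrt(var_a / 5.0) * rng.standard_normal((n_per, 5)),
            np.sqrt(var_b / 5.0) * rng.standard_normal((n_per, 5))])
        data = np.einsum("tm,mab->tab", coeffs, TENSOR_BASIS)[:, None]
        series = EFGSeries(data=data, dt=1.0, probes=[0])
        configs = self._frames_with_coordination(counts, seed=4)
        out = variance_by_coordination(series, configs, "O", 3.0)
        ratio = out[5]["variance"] / out[6]["variance"]
        assert ratio == pytest.approx(0.9, abs=0.02)

    def test_misaligned_series_rejected(self, neutral_config):
        from efgrelax.efg import EFGSeries
        series = EFGSeries(data=np.zeros((3, 1, 3, 3)) + np.eye(3) * 0,
                           dt=1.0, probes=[0])
        with pytest.raises(ValueError, match="misaligned"):
            variance_by_coordination(series, [neutral_config], "X", 3.0)


def test_symmetric_traceless_projection():
    rng = np.random.default_rng(0)
    t = rng.standard_normal((3, 3))
    s = symmetric_traceless(t)
    assert np.allclose(s, s.T)
    assert abs(np.trace(s)) < 1e-14
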