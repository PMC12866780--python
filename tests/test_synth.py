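import numpy as np
import pandas as pd
import pytest

from histomech import (COMPRESSION_PROTOCOL, DomainError, FormatError,
                       StepProtocol, ViscoParams, equilibrium_stress,
                       gen_cell_table, gen_fibers, gen_grouped,
                       gen_indentation, gen_relaxation, gen_stain_raster,
                       orientation_index, scheirer_ray_hare, spring_strain,
                       write_mech_csv)
from histomech.histology import write_raster
from histomech.synth import SyntheticTruth


class TestGenIndentation:
    def test_noiseless_forces_on_sneddon_line(self):
        E, R, nu, H0 = 900.0, 38.1e-6, 0.5, 3e-3
        series, _ = gen_indentation(E_true=E, R=R, nu=nu, H0=H0, seed=0)
        # every hold sample sits exactly on F = E 2R delta/(1-nu^2)
        for i in range(1, 6):
            sel = (series.time > (i - 1) * 60.0) & (series.time < i * 60.0)
            expected = E * 2 * R * (0.01 * i * H0) / (1 - nu ** 2)
            np.testing.assert_allclose(series.force[sel], expected, rtol=1e-12)

    def test_zero_modulus_zero_force(self):
        series, _ = gen_indentation(E_true=0.0, seed=1)
        assert np.all(series.force == 0.0)

    def test_poisson_guard(self):
        with pytest.raises(DomainError):
            gen_indentation(E_true=100.0, nu=1.0)


class TestGenRelaxation:
    def test_equal_viscosities_single_decay_mode(self):
        p = ViscoParams(1200.0, 1.5, 400.0, 900.0, 900.0)
        proto = StepProtocol(2, 0.025, 60.0)
        series, _ = gen_relaxation(p, protocol=proto, seed=0)
        sigma = np.abs(series.force) / (np.pi * series.radius ** 2)
        sel = (series.time >= 0) & (series.time < 60.0)
        expected = equilibrium_stress(0.025, 1200.0, 1.5) + \
            2 * 400.0 * spring_strain(series.time[sel], 0.0, 0.025, 400.0, 900.0)
        np.testing.assert_allclose(sigma[sel], expected, rtol=1e-10)

    def test_degenerate_maxwell_constant_holds(self):
        p = ViscoParams(1200.0, 1.5, 0.0, 900.0, 1800.0)
        series, _ = gen_relaxation(p, seed=0)
        sigma = np.abs(series.force) / (np.pi * series.radius ** 2)
        for i in range(8):
            sel = (series.time >= i * 120.0) & (series.time < (i + 1) * 120.0)
            assert np.ptp(sigma[sel]) < 1e-10

    def test_equilibrium_part_matches_direct_evaluation(self, visco_truth):
        # subtracting the independently evaluated Maxwell terms leaves the
        # printed equilibrium stress at every step end
        series, _ = gen_relaxation(visco_truth, seed=2)
        sigma = np.abs(series.force) / (np.pi * series.radius ** 2)
        eps = 0.025 * np.arange(9)
        prev = np.zeros(2)
        for i in range(8):
            eps_hat = eps[i + 1] - eps[i] + prev
            t0, t1 = i * 120.0, (i + 1) * 120.0
            t_end = series.time[(series.time >= t0) & (series.time < t1)][-1]
            maxwell = sum(visco_truth.c_m * spring_strain(
                t_end, t0, eps_hat[j], visco_truth.c_m, visco_truth.etas[j])
                for j in range(2))
            k = int(np.where(series.time == t_end)[0][0])
            assert sigma[k] - maxwell == pytest.approx(
                equilibrium_stress(eps[i + 1], visco_truth.c_a,
                                   visco_truth.c_b), rel=1e-9)
            prev = np.array([spring_strain(t1, t0, eps_hat[j],
                                           visco_truth.c_m,
                                           visco_truth.etas[j])
                             for j in range(2)])

    def test_radial_kinematics_exact(self, visco_truth):
        series, _ = gen_relaxation(visco_truth, nu_true=0.3, seed=5)
        eps_zz = series.height / series.H0 - 1.0
        eps_rr = series.radius / series.R0 - 1.0
        np.testing.assert_allclose(eps_rr, -0.3 * eps_zz, rtol=1e-12)

    def test_total_deformation_guard(self, visco_truth):
        with pytest.raises(FormatError, match="100%"):
            gen_relaxation(visco_truth, protocol=StepProtocol(10, 0.1, 10.0))


class TestGenStainRaster:
    def test_fraction_sum_guard(self):
        with pytest.raises(Exception, match="sum"):
            gen_stain_raster("PSR", {"red": 0.7, "green": 0.5})

    def test_exact_class_counts(self):
        raster, truth = gen_stain_raster(
            "PSR", {"red": 0.25, "orange": 0.25, "yellow": 0.25, "green": 0.25},
            size=128, seed=9)
        label = truth.extras["label_map"]
        counts = np.bincount(label[label >= 0].ravel())
        np.testing.assert_allclose(counts / counts.sum(), 0.25, atol=1e-4)


class TestGenFibers:
    def test_aligned_limit(self):
        fibers, _ = gen_fibers(n=500, mean_angle=37.0, kappa=1e6, seed=0)
        oi, _ = orientation_index(fibers["angle_deg"].to_numpy())
        assert oi > 0.999
        assert np.allclose(fibers["angle_deg"], 37.0, atol=1.0)

    def test_uniform_grid_exact_zero(self):
        fibers, _ = gen_fibers(n=180, kappa=0.0, grid=True, seed=0)
        oi, _ = orientation_index(fibers["angle_deg"].to_numpy(), axial=True)
        assert oi == pytest.approx(0.0, abs=1e-12)

    def test_mean_length_converges(self):
        mean, sd, n = 30.0, 10.0, 100_000
        fibers, _ = gen_fibers(n=n, kappa=1.0, length_dist=(mean, sd), seed=4)
        se = sd / np.sqrt(n)
        assert abs(fibers["length_um"].mean() - mean) < 3 * se + 0.05

    def test_angles_in_axial_domain(self):
        fibers, _ = gen_fibers(n=2000, mean_angle=170.0, kappa=3.0, seed=8)
        a = fibers["angle_deg"]
        assert (a >= 0).all() and (a < 180).all()
        assert (fibers["length_um"] > 0).all() and (fibers["width_um"] > 0).all()


class TestGenCellTable:
    def test_null_effects_nominal_rejection(self):
        # all-ones group effects: the four groups are exchangeable, so the
        # two-factor rank test on cell area rejects at ~ the nominal rate
        effects = {g: (1.0, 1.0, 1.0, 1.0)
                   for g in ("AO-normal", "AO-cancer", "EO-normal", "EO-cancer")}
        rej = np.zeros(3)
        n_rep = 300
        for rep in range(n_rep):
            table, _ = gen_cell_table(n_per_group=10, group_effects=effects,
                                      seed=20_000 + rep)
            onset = table["group"].str.split("-").str[0]
            tissue = table["group"].str.split("-").str[1]
            df = table[["area"]].rename(columns={"area": "value"})
            df["factor_a"], df["factor_b"] = onset, tissue
            res = scheirer_ray_hare(df)
            rej += [e.p < 0.05 for e in res.effects]
        rates = rej / n_rep
        assert np.all(rates > 0.01) and np.all(rates < 0.10)

    def test_default_effects_shift_groups_as_configured(self):
        table, _ = gen_cell_table(n_per_group=2000, seed=3)
        med = table.groupby("group")["area"].median()
        assert med["EO-normal"] < med["AO-normal"]   # EO cells smaller
        assert med["AO-cancer"] > med["AO-normal"]   # cancer cells larger
        pk = table.groupby("group")["panck"].mean()
        assert pk["EO-cancer"] < pk["AO-cancer"]     # PanCK lower in EO

    def test_minimum_group_size(self):
        with pytest.raises(FormatError):
            gen_cell_table(n_per_group=5)


class TestDeterminism:
    """Every stochastic path reproduces byte-identical outputs for a seed."""

    def test_mech_series_bytes(self, tmp_path, visco_truth):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_mech_csv(gen_indentation(1000.0, noise_sd=1e-4, seed=3)[0], p1)
        write_mech_csv(gen_indentation(1000.0, noise_sd=1e-4, seed=3)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()
        write_mech_csv(gen_relaxation(visco_truth, noise_sd=1.0, seed=3)[0], p1)
        write_mech_csv(gen_relaxation(visco_truth, noise_sd=1.0, seed=3)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_raster_bytes(self, tmp_path):
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        write_raster(gen_stain_raster("PSR", {"red": 0.5, "green": 0.3},
                                      size=64, seed=6)[0], p1)
        write_raster(gen_stain_raster("PSR", {"red": 0.5, "green": 0.3},
                                      size=64, seed=6)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tables_identical(self):
        f1, _ = gen_fibers(n=100, kappa=2.0, seed=11)
        f2, _ = gen_fibers(n=100, kappa=2.0, seed=11)
        pd.testing.assert_frame_equal(f1, f2)
        c1, _ = gen_cell_table(n_per_group=20, seed=11)
        c2, _ = gen_cell_table(n_per_group=20, seed=11)
        pd.testing.assert_frame_equal(c1, c2)
        g1, _ = gen_grouped(n=10, seed=11)
        g2, _ = gen_grouped(n=10, seed=11)
        pd.testing.assert_frame_equal(g1, g2)

    def test_different_seeds_differ(self):
        f1, _ = gen_fibers(n=100, kappa=2.0, seed=1)
        f2, _ = gen_fibers(n=100, kappa=2.0, seed=2)
        assert not np.allclose(f1["angle_deg"], f2["angle_deg"])


class TestTruthSidecar:
    def test_round_trip(self, tmp_path):
        _, truth = gen_fibers(n=50, kappa=1.5, seed=21)
        p = tmp_path / "truth.yaml"
        truth.to_yaml(p)
        back = SyntheticTruth.from_yaml(p)
        assert back.generator == truth.generator
        assert back.seed == truth.seed
        assert back.parameters == truth.parameters

    def test_truth_regenerates_identical_data(self, tmp_path):
        fibers, truth = gen_fibers(n=50, kappa=1.5, seed=21)
        p = tmp_path / "truth.yaml"
        truth.to_yaml(p)
        back = SyntheticTruth.from_yaml(p)
        params = dict(back.parameters)
        params["length_dist"] = tuple(params["length_dist"])
        params["width_dist"] = tuple(params["width_dist"])
        params["intensity_dist"] = tuple(params["intensity_dist"])
        again, _ = gen_fibers(seed=back.seed, **params)
        pd.testing.assert_frame_equal(fibers, again)


class TestGenGrouped:
    def test_two_factor_layout(self):
        table, _ = gen_grouped(n=5, seed=0)
        assert set(table["factor_a"]) == {"AO", "EO"}
        assert set(table["factor_b"]) == {"normal", "cancer"}
        assert len(table) == 20

    def test_location_shift_applied(self):
        table, _ = gen_grouped(
            n=200, location_shifts={"a": 0.0, "b": 10.0}, noise=1.0, seed=1)
        means = table.groupby("factor_a")["value"].mean()
        assert means["b"] - means["a"] == pytest.approx(10.0, abs=0.5)
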