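"""Size control: growth law, optimal radius, emulsion evolution, sweeps."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from actodrop.chem_cycle import KineticParams
from actodrop.size_control import (
    DropletFieldParams,
    Emulsion,
    droplet_radius_rate,
    efflux,
    evolve_emulsion,
    extinction_k_deact,
    fit_relaxation,
    influx,
    integrate_radius,
    optimal_radius,
    perturb_emulsion,
    radii_to_volumes,
    run_to_steady,
    sweep,
)


@pytest.fixture(scope="module")
def fld():
    return DropletFieldParams()


class TestGrowthLaw:
    def test_rate_vanishes_at_optimal_radius(self, fld):
        c_A = 0.05
        R_star = optimal_radius(c_A, fld)
        assert droplet_radius_rate(R_star, c_A, fld) == pytest.approx(0.0, abs=1e-15)

    def test_small_grow_large_shrink(self, fld):
        c_A = 0.05
        R_star = optimal_radius(c_A, fld)
        assert droplet_radius_rate(0.5 * R_star, c_A, fld) > 0
        assert droplet_radius_rate(2.0 * R_star, c_A, fld) < 0

    def test_flux_scaling_laws(self, fld):
        # influx/R² and efflux/R³ are constants in R
        c_A = 0.04
        ratios_in = [influx(R, c_A, fld) / R ** 2 for R in (0.3, 0.9, 2.7)]
        ratios_out = [efflux(R, fld) / R ** 3 for R in (0.3, 0.9, 2.7)]
        assert np.ptp(ratios_in) < 1e-12 * ratios_in[0]
        assert np.ptp(ratios_out) < 1e-12 * ratios_out[0]

    def test_single_positive_root_and_stability(self, fld):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c_A = rng.uniform(0.005, 0.5)
            R_star = optimal_radius(c_A, fld)
            # derivative of dR/dt at the root is negative: stable fixed point
            eps = 1e-6
            slope = (droplet_radius_rate(R_star + eps, c_A, fld)
                     - droplet_radius_rate(R_star - eps, c_A, fld)) / (2 * eps)
            assert slope < 0

    def test_closed_form_matches_bisection(self):
        # oracle: bracketed root of the growth law itself
        rng = np.random.default_rng(42)
        for _ in range(100):
            chem = KineticParams(k_deact=rng.uniform(0.001, 0.1),
                                 c_den=rng.uniform(100.0, 1000.0))
            p = DropletFieldParams(chem=chem, k_up=rng.uniform(1.0, 100.0))
            c_A = rng.uniform(0.001, 0.5)
            R_star = optimal_radius(c_A, p)
            root = brentq(lambda R: droplet_radius_rate(R, c_A, p),
                          1e-9, 10.0 * R_star, xtol=1e-14)
            assert root == pytest.approx(R_star, abs=1e-10)

    def test_integrated_slope_matches_rate(self, fld):
        # numerical-differentiation oracle on the integrated radius
        c_A = 0.05
        traj = integrate_radius(0.3, c_A, fld, t_end=200.0, n_out=2001)
        t, R = traj["t"].to_numpy(), traj["R"].to_numpy()
        mid = 1000
        slope = (R[mid + 1] - R[mid - 1]) / (t[mid + 1] - t[mid - 1])
        assert slope == pytest.approx(droplet_radius_rate(R[mid], c_A, fld), abs=1e-6)

    def test_zero_concentration_gives_zero_radius(self, fld):
        assert optimal_radius(0.0, fld) == 0.0

    def test_passive_limit_has_no_optimal_radius(self):
        chem = KineticParams(k_deact=0.0)
        p = DropletFieldParams(chem=chem)
        with pytest.raises(ValueError, match="passive"):
            optimal_radius(0.05, p)

    def test_negative_radius_rejected(self, fld):
        with pytest.raises(ValueError):
            droplet_radius_rate(-0.1, 0.05, fld)


class TestEmulsionEvolution:
    def test_active_mode_converges_to_optimal_radius(self, bulk_steady, bulk_ref):
        fld, _, _ = bulk_ref
        R_star = optimal_radius(bulk_steady.c_A_pool, fld)
        assert bulk_steady.n_droplets > 10
        assert np.all(np.abs(bulk_steady.radii / R_star - 1.0) < 0.02)
        pdi = bulk_steady.radii.std() / bulk_steady.radii.mean()
        assert pdi < 0.05

    def test_material_conserved_at_every_step(self, bulk_ref):
        fld, c_total, volume = bulk_ref
        em0 = Emulsion(radii=np.empty(0), c_A_pool=0.0, c_P_pool=c_total, volume=volume)
        hist = evolve_emulsion(em0, fld, 600.0, seed=3, n_out=40)
        for h in hist:
            assert h.total_material(fld.chem.c_den) == pytest.approx(c_total, rel=1e-6)

    def test_identical_seed_identical_trajectory(self, bulk_ref):
        fld, c_total, volume = bulk_ref
        em0 = Emulsion(radii=np.empty(0), c_A_pool=0.0, c_P_pool=c_total, volume=volume)
        a = evolve_emulsion(em0, fld, 300.0, seed=11, n_out=10)
        b = evolve_emulsion(em0, fld, 300.0, seed=11, n_out=10)
        assert all(np.array_equal(x.radii, y.radii) for x, y in zip(a, b))

    def test_passive_two_droplets_ripen(self):
        # the larger grows at the expense of the smaller, which vanishes
        chem = KineticParams(c_fuel_oil=0.0)
        p = DropletFieldParams(chem=chem, mode="passive", gibbs_thomson_length=0.1)
        em = Emulsion(radii=[0.8, 1.0], c_A_pool=chem.c_sat * 1.1,
                      c_P_pool=0.0, volume=1e4)
        hist = evolve_emulsion(em, p, 6000.0, seed=0, n_out=30)
        final = hist[-1]
        assert final.n_droplets == 1
        assert final.radii[0] > 1.0

    def test_passive_coarsening_signature(self):
        # mean radius up, count down, PDI not narrowing: opposite of active
        chem = KineticParams(c_fuel_oil=0.0)
        p = DropletFieldParams(chem=chem, mode="passive", gibbs_thomson_length=0.1)
        rng = np.random.default_rng(5)
        em = Emulsion(radii=rng.uniform(0.9, 1.1, size=30),
                      c_A_pool=chem.c_sat * 1.05, c_P_pool=0.0, volume=3e4)
        hist = evolve_emulsion(em, p, 8000.0, seed=0, n_out=5)
        means = [h.radii.mean() for h in hist]
        counts = [h.n_droplets for h in hist]
        assert means[-1] > means[0]
        assert np.all(np.diff(counts) <= 0)
        assert counts[-1] < counts[0]


class TestPerturbation:
    def test_zero_spread_is_identity(self, bulk_steady):
        out = perturb_emulsion(bulk_steady, 0.0, seed=1)
        assert np.array_equal(out.radii, bulk_steady.radii)

    def test_total_volume_conserved_exactly(self, bulk_steady):
        out = perturb_emulsion(bulk_steady, 0.5, seed=1)
        assert out.total_droplet_volume == pytest.approx(
            bulk_steady.total_droplet_volume, rel=1e-12)

    def test_negative_spread_rejected(self, bulk_steady):
        with pytest.raises(ValueError):
            perturb_emulsion(bulk_steady, -0.1)

    def test_relaxation_back_to_optimal_radius(self, bulk_steady, bulk_ref):
        fld, _, _ = bulk_ref
        pert = perturb_emulsion(bulk_steady, 0.4, seed=2)
        R_star = optimal_radius(pert.c_A_pool, fld)
        rates = droplet_radius_rate(pert.radii, pert.c_A_pool, fld)
        assert np.all(rates[pert.radii > R_star * 1.001] < 0)
        assert np.all(rates[pert.radii < R_star * 0.999] > 0)
        relaxed = evolve_emulsion(pert, fld, 1500.0, seed=3, n_out=30)[-1]
        R_star_end = optimal_radius(relaxed.c_A_pool, fld)
        assert np.all(np.abs(relaxed.radii / R_star_end - 1.0) < 0.02)


class TestSweeps:
    def test_fuel_sweep_trends(self, bulk_ref):
        fld, c_total, volume = bulk_ref
        tab = sweep("fuel", [4.0, 7.0, 10.0], fld, c_total=c_total, volume=volume,
                    t_end=3000.0, seed=0)
        assert np.all(np.diff(tab["number_density"]) > 0)
        r = tab["R_star"].to_numpy()
        assert np.nanmax(r) / np.nanmin(r) < 1.1

    def test_peptide_sweep_trends(self, bulk_ref):
        fld, c_total, volume = bulk_ref
        tab = sweep("peptide", [10.0, 14.0, 18.0], fld, c_total=c_total,
                    volume=volume, t_end=3000.0, seed=0)
        assert np.all(np.diff(tab["R_star"].to_numpy()) > 0)

    def test_k_deact_sweep_shrinks_then_extinguishes(self, bulk_ref):
        fld, c_total, volume = bulk_ref
        k_ext = extinction_k_deact(fld, c_total=c_total)
        values = [0.25 * k_ext, 0.5 * k_ext, 0.9 * k_ext, 1.5 * k_ext]
        tab = sweep("k_deact", values, fld, c_total=c_total, volume=volume,
                    t_end=3000.0, seed=0)
        alive = tab["R_star"].notna()
        assert alive[:3].all() and not alive.iloc[3]
        assert np.all(np.diff(tab["R_star"].dropna()) < 0)

    def test_unsorted_values_rejected(self, bulk_ref):
        fld, c_total, volume = bulk_ref
        with pytest.raises(ValueError):
            sweep("fuel", [10.0, 4.0], fld, c_total=c_total, volume=volume)


class TestParameterRecovery:
    def test_least_squares_recovers_generating_constants(self, fld, rng):
        # noisy single-droplet relaxation at SNR 20, recovery within 5%
        c_A = 0.05
        traj = integrate_radius(0.2, c_A, fld, t_end=1500.0, n_out=400)
        R = traj["R"].to_numpy()
        noisy = R + rng.normal(0.0, np.ptp(R) / 20.0, size=R.size)
        fit = fit_relaxation(traj["t"].to_numpy(), noisy, c_A)
        assert fit.k_deact == pytest.approx(fld.chem.k_deact, rel=0.05)
        assert fit.k_up_over_c_den == pytest.approx(fld.k_up / fld.chem.c_den, rel=0.05)
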