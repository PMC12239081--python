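"""Solubility-diffusion integral, its invariants and error propagation."""
import math

import numpy as np
import pytest

from scperm.constants import thermal_energy
from scperm.diffusion import DiffusionProfile
from scperm.errors import ConvergenceError, PermeabilityError
from scperm.permeability import (
    compare_permeability,
    isd_permeability,
    permeability_draws,
    permeability_uncertainty,
)
from scperm.pmf import FreeEnergyProfile

RT = thermal_energy(303.15)


def profiles(z, dg, d, dg_err=None, d_err=None, converged=None):
    dg_err = np.zeros_like(z) if dg_err is None else dg_err
    d_err = np.zeros_like(z) if d_err is None else d_err
    converged = np.ones(len(z), dtype=bool) if converged is None else converged
    fe = FreeEnergyProfile(z=z, dG=dg - dg[0], dG_error=dg_err, anchored_at=z[0])
    dp = DiffusionProfile(z=z, D=d, D_error=d_err, converged_mask=converged)
    return fe, dp


def flat_profiles(n=91, span=9.0, d=0.002, **kw):
    z = np.linspace(-span / 2, span / 2, n)
    return profiles(z, np.zeros(n), np.full(n, d), **kw)


class TestIsdPermeability:
    def test_flat_limit_is_d_over_l_exactly(self):
        """dG = 0, D = 0.002 nm^2/ps over 9 nm: P = D/L = 22.22 cm/s."""
        fe, dp = flat_profiles()
        res = isd_permeability(fe, dp, 303.15)
        assert res.P == pytest.approx(1e5 * 0.002 / 9.0, rel=1e-12)
        assert res.P == pytest.approx(22.222, rel=1e-4)

    def test_uniform_rt_ln2_offset_halves_p_exactly(self):
        fe, dp = flat_profiles()
        p0 = isd_permeability(fe, dp, 303.15).P
        p1 = isd_permeability(fe, dp, 303.15, dG_offset=RT * math.log(2.0)).P
        assert p1 == pytest.approx(p0 / 2.0, rel=1e-12)

    def test_gauss_barrier_grid_matches_fine_quadrature(self, presets):
        """Window-grid trapezoid within 0.5% of a 1e4-point quadrature."""
        lnd = presets["gauss_barrier"]
        z = np.arange(-4.45, 4.4501, 0.1)
        fe, dp = profiles(z, lnd.free_energy(z), lnd.diffusion(z))
        res = isd_permeability(fe, dp, 303.15)
        zf = np.linspace(z[0], z[-1], 10_001)
        p_ref = 1e5 / np.trapezoid(lnd.resistance(zf), zf)
        assert res.P == pytest.approx(p_ref, rel=0.005)

    def test_inverse_p_equals_trapezoid_of_resistance(self, presets):
        lnd = presets["sc_like"]
        z = np.arange(-4.45, 4.4501, 0.1)
        fe, dp = profiles(z, lnd.free_energy(z), lnd.diffusion(z))
        res = isd_permeability(fe, dp, 303.15)
        assert 1.0 / res.P == pytest.approx(
            float(np.trapezoid(res.resistance, res.z)), rel=1e-12
        )

    def test_resistance_additivity_at_any_interior_point(self):
        rng = np.random.default_rng(3)
        z = np.arange(-2.0, 2.001, 0.1)
        fe, dp = profiles(z, rng.normal(size=len(z)) * 3,
                          rng.uniform(0.001, 0.003, len(z)))
        a, c = z[0], z[-1]
        for b in (-1.0, 0.3, 1.5):
            p_ac = isd_permeability(fe, dp, bounds=(a, c)).P
            p_ab = isd_permeability(fe, dp, bounds=(a, b)).P
            p_bc = isd_permeability(fe, dp, bounds=(b, c)).P
            assert 1 / p_ac == pytest.approx(1 / p_ab + 1 / p_bc, rel=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_monotonicity_in_dg_and_d(self, trial):
        rng = np.random.default_rng(100 + trial)
        z = np.arange(-2.0, 2.001, 0.1)
        dg = rng.normal(size=len(z)) * 2
        d = rng.uniform(0.001, 0.003, len(z))
        fe, dp = profiles(z, dg, d)
        p0 = isd_permeability(fe, dp).P
        bump = np.zeros(len(z))
        bump[rng.integers(1, len(z) - 1)] = rng.uniform(0.5, 3.0)
        fe_up, _ = profiles(z, dg + bump, d)
        assert isd_permeability(fe_up, dp).P <= p0 + 1e-15
        _, dp_up = profiles(z, dg, d * (1 + bump))
        assert isd_permeability(fe, dp_up).P >= p0 - 1e-15

    def test_unconverged_window_refuses_unless_overridden(self):
        conv = np.ones(91, dtype=bool)
        conv[45] = False
        fe, dp = flat_profiles(converged=conv)
        with pytest.raises(ConvergenceError):
            isd_permeability(fe, dp)
        res = isd_permeability(fe, dp, allow_unconverged=True)
        assert res.P > 0

    def test_nonpositive_diffusion_is_a_hard_error(self):
        z = np.linspace(-1, 1, 21)
        d = np.full(21, 0.002)
        d[10] = 0.0
        fe = FreeEnergyProfile(z=z, dG=np.zeros(21), dG_error=np.zeros(21),
                               anchored_at=z[0])
        dp = DiffusionProfile(z=z, D=d, D_error=np.zeros(21),
                              converged_mask=np.zeros(21, dtype=bool))
        with pytest.raises((PermeabilityError, ConvergenceError)):
            isd_permeability(fe, dp)
        with pytest.raises(PermeabilityError):
            isd_permeability(fe, dp, allow_unconverged=True)

    def test_half_window_grid_offset_is_regridded(self):
        z = np.arange(-2.0, 2.001, 0.1)
        fe, _ = profiles(z, np.zeros(len(z)), np.full(len(z), 0.002))
        z_d = z + 0.04  # offset below half a window
        dp = DiffusionProfile(z=z_d, D=np.full(len(z), 0.002),
                              D_error=np.zeros(len(z)),
                              converged_mask=np.ones(len(z), dtype=bool))
        res = isd_permeability(fe, dp)
        assert res.P == pytest.approx(1e5 * 0.002 / 4.0, rel=1e-9)
        dp_far = DiffusionProfile(z=z + 0.3, D=np.full(len(z), 0.002),
                                  D_error=np.zeros(len(z)),
                                  converged_mask=np.ones(len(z), dtype=bool))
        with pytest.raises(PermeabilityError):
            isd_permeability(fe, dp_far)


class TestUncertainty:
    def test_zero_errors_give_zero_spread(self):
        fe, dp = flat_profiles()
        assert permeability_uncertainty(fe, dp, n_draws=500, seed=1) == 0.0

    def test_too_few_draws_refused(self):
        fe, dp = flat_profiles()
        with pytest.raises(ValueError):
            permeability_uncertainty(fe, dp, n_draws=50)

    def test_small_dg_errors_match_delta_method(self):
        """With only dG errors, the MC spread matches the first-order
        propagation through the resistance weights within 20%."""
        rng = np.random.default_rng(7)
        z = np.arange(-4.45, 4.4501, 0.1)
        dg = 5.0 * np.exp(-(z**2))
        dg_err = np.full(len(z), 0.05)
        dg_err[0] = 0.0  # anchor
        fe, dp = profiles(z, dg, np.full(len(z), 0.002), dg_err=dg_err)
        p = isd_permeability(fe, dp, 303.15)
        mc = permeability_uncertainty(fe, dp, 303.15, n_draws=20_000, seed=2)
        w = np.gradient(z)  # trapezoid weights on the uniform grid
        r = np.exp((dg - dg[0]) / RT) / 0.002 / 1e5
        inv_p = np.trapezoid(r, z)
        delta = p.P * np.sqrt(np.sum((w * r * dg_err / RT) ** 2)) / inv_p
        assert mc == pytest.approx(delta, rel=0.2)

    def test_doubling_all_errors_doubles_the_spread(self):
        rng = np.random.default_rng(11)
        z = np.arange(-2.0, 2.001, 0.1)
        dg_err = rng.uniform(0.01, 0.05, len(z))
        d_err = rng.uniform(1e-5, 5e-5, len(z))
        fe1, dp1 = profiles(z, np.zeros(len(z)), np.full(len(z), 0.002),
                            dg_err=dg_err, d_err=d_err)
        fe2, dp2 = profiles(z, np.zeros(len(z)), np.full(len(z), 0.002),
                            dg_err=2 * dg_err, d_err=2 * d_err)
        s1 = permeability_uncertainty(fe1, dp1, n_draws=10_000, seed=3)
        s2 = permeability_uncertainty(fe2, dp2, n_draws=10_000, seed=3)
        assert s2 / s1 == pytest.approx(2.0, rel=0.05)

    def test_draws_are_seeded(self):
        fe, dp = flat_profiles(dg_err=np.full(91, 0.1))
        a = permeability_draws(fe, dp, n_draws=200, seed=5)
        b = permeability_draws(fe, dp, n_draws=200, seed=5)
        c = permeability_draws(fe, dp, n_draws=200, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestCompare:
    def test_rt_ln2_offset_detected_by_t_test(self):
        fe, dp = flat_profiles(dg_err=np.full(91, 0.1))
        a = permeability_draws(fe, dp, n_draws=10_000, seed=1)
        b = permeability_draws(fe, dp, n_draws=10_000, seed=2,
                               dG_offset=RT * math.log(2.0))
        cmp = compare_permeability(a, b)
        assert cmp.ratio == pytest.approx(2.0, rel=0.02)
        assert cmp.p_value < 0.05
        assert cmp.significant

    def test_identical_systems_are_not_flagged(self):
        fe, dp = flat_profiles(dg_err=np.full(91, 0.1))
        a = permeability_draws(fe, dp, n_draws=5_000, seed=10)
        b = permeability_draws(fe, dp, n_draws=5_000, seed=11)
        cmp = compare_permeability(a, b)
        assert cmp.p_value > 0.05
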