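"""Inhomogeneous solubility-diffusion permeability.

The membrane permeability to the tracer is the inverse of the integrated
local resistance,

    1/P = ∫ exp(ΔG(z)/RT) / D_z(z) dz,

evaluated with the trapezoidal rule on the window grid.  ΔG enters relative
to bulk water (its anchor), so the exponent vanishes in bulk and the flat
limit P = D/L holds exactly.  Integration bounds default to the full
sampled reaction coordinate: bulk windows contribute negligible resistance,
which avoids an arbitrary membrane-edge cut (an override is provided).

Uncertainty is propagated by seeded Monte Carlo: Gaussian perturbations of
ΔG and D per window, P recomputed per draw.  Two systems are compared with
a two-sided Student t test on their P draws.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .constants import (
    CONSTANTS,
    DEFAULT_TEMPERATURE_K,
    NM_PER_PS_TO_CM_PER_S,
    PhysicalConstants,
    thermal_energy,
)
from .diffusion import DiffusionProfile
from .errors import ConvergenceError, PermeabilityError
from .pmf import FreeEnergyProfile

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "PermeabilityResult",
    "ComparisonResult",
    "isd_permeability",
    "permeability_draws",
    "permeability_uncertainty",
    "compare_permeability",
]

MIN_MC_DRAWS = 100


@dataclass(frozen=True)
class PermeabilityResult:
    """Permeability with its resistance decomposition.

    ``resistance`` holds the per-window resistance density exp(ΔG/RT)/D in
    (s/cm)/nm, so that the trapezoid of ``resistance`` over ``z`` equals
    1/P exactly.
    """

    P: float  # cm/s
    P_error: float | None
    z: np.ndarray
    resistance: np.ndarray  # (s/cm) per nm
    bounds_used: tuple[float, float]
    temperature: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "resistance", np.asarray(self.resistance, dtype=float))
        if self.P <= 0:
            raise ValueError("permeability must be positive")


def _common_grid(
    dG: FreeEnergyProfile,
    D: DiffusionProfile,
    bounds: tuple[float, float] | None,
):
    """Restrict both profiles to one z grid over ``bounds``.

    If the two grids are offset by at most half the window spacing, D is
    re-gridded onto the ΔG grid by linear interpolation (a regridded window
    is converged only if its bracketing windows are).
    """
    z = dG.z
    if len(D.z) == len(z) and np.abs(D.z - z).max() <= 1e-9:
        d_vals, d_errs, mask = D.D, D.D_error, D.converged_mask
    else:
        spacing = np.diff(z).min()
        # nearest-neighbour offset between the two grids
        offsets = np.abs(D.z[:, None] - z[None, :]).min(axis=0)
        if offsets.max() > 0.5 * spacing + 1e-12:
            raise PermeabilityError(
                "free-energy and diffusion grids differ by more than half a window"
            )
        d_vals = np.interp(z, D.z, D.D)
        d_errs = np.interp(z, D.z, np.nan_to_num(D.D_error))
        conv = D.converged_mask.astype(float)
        mask = np.interp(z, D.z, conv) >= 1.0 - 1e-9
    if bounds is None:
        bounds = (float(z[0]), float(z[-1]))
    lo, hi = bounds
    sel = (z >= lo - 1e-9) & (z <= hi + 1e-9)
    if sel.sum() < 2:
        raise PermeabilityError("bounds select fewer than two grid points")
    return (z[sel], dG.dG[sel], dG.dG_error[sel], d_vals[sel], d_errs[sel],
            mask[sel], (float(z[sel][0]), float(z[sel][-1])))


def isd_permeability(
    dG: FreeEnergyProfile,
    D: DiffusionProfile,
    temperature: float = DEFAULT_TEMPERATURE_K,
    bounds: tuple[float, float] | None = None,
    *,
    allow_unconverged: bool = False,
    dG_offset: float = 0.0,
) -> PermeabilityResult:
    """Evaluate 1/P = ∫ exp(ΔG/RT)/D dz over the grid (P in cm/s).

    ``dG_offset`` adds a uniform partitioning free energy (kJ/mol) to ΔG
    inside the exponent; P scales exactly by exp(-dG_offset/RT).  Windows
    whose force ACF never converged refuse to enter the integral unless
    ``allow_unconverged``; a non-positive D anywhere in the bounds is a
    hard error.
    """
    z, g, _, d, _, mask, used = _common_grid(dG, D, bounds)
    if not mask.all() and not allow_unconverged:
        bad = z[~mask]
        raise ConvergenceError(
            f"{len(bad)} window(s) inside the bounds are unconverged "
            f"(first at z={bad[0]:.3f} nm); pass allow_unconverged to override"
        )
    if (d <= 0).any() or np.isnan(d).any():
        raise PermeabilityError("diffusion profile is non-positive inside the bounds")
    rt = thermal_energy(temperature)
    resistance = np.exp((g + dG_offset) / rt) / d / NM_PER_PS_TO_CM_PER_S  # (s/cm)/nm
    inv_p = float(np.trapezoid(resistance, z))
    return PermeabilityResult(
        P=1.0 / inv_p,
        P_error=None,
        z=z,
        resistance=resistance,
        bounds_used=used,
        temperature=temperature,
    )


def permeability_draws(
    dG: FreeEnergyProfile,
    D: DiffusionProfile,
    temperature: float = DEFAULT_TEMPERATURE_K,
    bounds: tuple[float, float] | None = None,
    n_draws: int = 2000,
    seed: int = 0,
    *,
    allow_unconverged: bool = False,
    dG_offset: float = 0.0,
) -> np.ndarray:
    """Monte-Carlo permeability draws under per-window Gaussian errors.

    ΔG and D are perturbed independently per window by their standard
    errors; the ISD integral is re-evaluated per draw.  Draws are seeded
    and reproducible.  Requires at least ``MIN_MC_DRAWS`` draws (smaller
    ensembles give unstable spread estimates).
    """
    if n_draws < MIN_MC_DRAWS:
        raise ValueError(f"n_draws must be >= {MIN_MC_DRAWS}")
    z, g, g_se, d, d_se, mask, _ = _common_grid(dG, D, bounds)
    if not mask.all() and not allow_unconverged:
        raise ConvergenceError("unconverged windows inside the bounds")
    if (d <= 0).any() or np.isnan(d).any():
        raise PermeabilityError("diffusion profile is non-positive inside the bounds")
    rt = thermal_energy(temperature)
    rng = np.random.default_rng(seed)
    d_se = np.nan_to_num(d_se)
    g_draw = g + dG_offset + g_se * rng.standard_normal((n_draws, len(z)))
    d_draw = d + d_se * rng.standard_normal((n_draws, len(z)))
    d_draw = np.clip(d_draw, 1e-12, None)  # guard: keep the resistance defined
    r = np.exp(g_draw / rt) / d_draw / NM_PER_PS_TO_CM_PER_S
    inv_p = np.trapezoid(r, z, axis=1)
    return 1.0 / inv_p


def permeability_uncertainty(
    dG: FreeEnergyProfile,
    D: DiffusionProfile,
    temperature: float = DEFAULT_TEMPERATURE_K,
    bounds: tuple[float, float] | None = None,
    n_draws: int = 2000,
    seed: int = 0,
    *,
    allow_unconverged: bool = False,
) -> float:
    """Standard deviation of the Monte-Carlo permeability draws (cm/s)."""
    if n_draws < MIN_MC_DRAWS:
        raise ValueError(f"n_draws must be >= {MIN_MC_DRAWS}")
    _, _, g_se, _, d_se, _, _ = _common_grid(dG, D, bounds)
    if not np.any(g_se) and not np.any(np.nan_to_num(d_se)):
        return 0.0  # error-free profiles: every draw is identical
    draws = permeability_draws(
        dG, D, temperature, bounds, n_draws, seed, allow_unconverged=allow_unconverged
    )
    return float(draws.std(ddof=1))


@dataclass(frozen=True)
class ComparisonResult:
    """Two-system permeability comparison (Student two-sided t test)."""

    mean_a: float
    mean_b: float
    ratio: float  # mean_a / mean_b
    t_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_permeability(draws_a: np.ndarray, draws_b: np.ndarray) -> ComparisonResult:
    """Compare two ensembles of permeability values (MC draws or replicate-
    wise estimates) with a two-sided Student t test."""
    draws_a = np.asarray(draws_a, dtype=float)
    draws_b = np.asarray(draws_b, dtype=float)
    t, p = _stats.ttest_ind(draws_a, draws_b)
    return ComparisonResult(
        mean_a=float(draws_a.mean()),
        mean_b=float(draws_b.mean()),
        ratio=float(draws_a.mean() / draws_b.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )
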