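"""Synthetic ground-truth data: constraint-force series and toy membranes.

The constraint-force surrogate is a stationary Ornstein-Uhlenbeck (OU)
process per window, advanced with the exact discretization

    F <- mu + (F - mu) e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) xi,

so there is no time-step bias: any estimator error measured downstream
belongs to the pipeline, not the generator.  The window mean is the true
mean force mu = -dG/dz(z0), and the variance is fixed by the fluctuation-
dissipation requirement sigma^2 = (RT)^2 / (D(z0) tau(z0)), which makes the
force-autocorrelation route recover exactly D(z0).

Toy membranes are two leaflets of straight bead chains with known
thickness, area per lipid, chain tilt and hydrogen-bond geometry; they are
the analytic fixtures for every structural metric.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import integrate
from scipy.signal import lfilter

from .constants import DEFAULT_TEMPERATURE_K, NM_PER_PS_TO_CM_PER_S, thermal_energy
from .core import ForceTimeSeries, Snapshot, Trajectory
from .errors import FixtureError, LandscapeError
from .io import write_xvg
from .plan import SamplingPlan

__all__ = [
    "Landscape",
    "SyntheticRunSpec",
    "landscape_presets",
    "generate_window_series",
    "generate_run",
    "write_run_xvg",
    "read_run_xvg",
    "generate_toy_membrane",
]

#: Default force correlation time (ps); of the order of solvent force
#: decorrelation, far below the ACF truncation lag.
DEFAULT_TAU_PS = 0.1

#: Default bulk-water diffusion coefficient (nm^2/ps).
DEFAULT_D_BULK = 0.002


@dataclass(frozen=True)
class Landscape:
    """Analytic free-energy / diffusion / correlation-time landscape.

    ``free_energy`` and its analytic derivative ``mean_force_potential``
    (dG/dz) are callables of z (nm) returning kJ/mol and kJ/mol/nm;
    ``diffusion`` returns nm^2/ps and ``tau`` the force correlation time in
    ps.  All callables must accept numpy arrays.
    """

    name: str
    free_energy: Callable
    dG_dz: Callable
    diffusion: Callable
    tau: Callable

    def validate_at(self, z: float) -> None:
        if not np.isfinite(self.free_energy(z)):
            raise LandscapeError(f"{self.name}: G({z}) is not finite")
        if self.diffusion(z) <= 0:
            raise LandscapeError(f"{self.name}: D({z}) <= 0")
        if self.tau(z) <= 0:
            raise LandscapeError(f"{self.name}: tau({z}) <= 0")

    def resistance(self, z, temperature: float = DEFAULT_TEMPERATURE_K):
        """Local resistance density exp(G/RT)/D in ps/nm^2."""
        rt = thermal_energy(temperature)
        z = np.asarray(z, dtype=float)
        return np.exp(self.free_energy(z) / rt) / self.diffusion(z)

    def permeability(
        self,
        bounds: tuple[float, float],
        temperature: float = DEFAULT_TEMPERATURE_K,
    ) -> float:
        """Analytic solubility-diffusion permeability over ``bounds`` (cm/s).

        1/P = integral of exp(G(z)/RT)/D(z) dz, evaluated by adaptive
        quadrature; the result is converted from nm/ps to cm/s.
        """
        lo, hi = bounds
        inv_p, _ = integrate.quad(
            lambda z: float(self.resistance(z, temperature)), lo, hi, limit=500
        )
        return NM_PER_PS_TO_CM_PER_S / inv_p

    def shifted(self, offset: float) -> "Landscape":
        """Landscape with a uniform free-energy offset added everywhere."""
        g, dg = self.free_energy, self.dG_dz
        return replace(
            self,
            name=f"{self.name}+{offset:g}",
            free_energy=lambda z: g(z) + offset,
            dG_dz=dg,
        )


def _gaussian(height: float, center: float, width: float):
    def g(z):
        return height * np.exp(-((np.asarray(z, dtype=float) - center) ** 2) / (2 * width**2))

    def dg(z):
        z = np.asarray(z, dtype=float)
        return -height * (z - center) / width**2 * np.exp(-((z - center) ** 2) / (2 * width**2))

    return g, dg


def landscape_presets(
    d_bulk: float = DEFAULT_D_BULK, tau: float = DEFAULT_TAU_PS
) -> dict[str, Landscape]:
    """Named analytic landscapes.

    - ``flat``: G = 0, uniform D; the closed-form P = D/L limit.
    - ``gauss_barrier``: a single 12 kJ/mol Gaussian barrier (w = 0.8 nm).
    - ``sc_like``: twin 16 kJ/mol barriers at +-1.5 nm (w = 0.4 nm) over an
      8 kJ/mol central plateau, with D reduced one order of magnitude inside
      the membrane — the qualitative shape of a dense ceramide bilayer's
      water free-energy and diffusivity profiles.
    """
    const_tau = lambda z: tau + 0.0 * np.asarray(z, dtype=float)
    const_d = lambda z: d_bulk + 0.0 * np.asarray(z, dtype=float)

    zero = lambda z: 0.0 * np.asarray(z, dtype=float)
    flat = Landscape("flat", zero, zero, const_d, const_tau)

    g1, dg1 = _gaussian(12.0, 0.0, 0.8)
    gauss = Landscape("gauss_barrier", g1, dg1, const_d, const_tau)

    bl, dbl = _gaussian(16.0, -1.5, 0.4)
    br, dbr = _gaussian(16.0, 1.5, 0.4)
    pl, dpl = _gaussian(8.0, 0.0, 0.8)
    g_sc = lambda z: bl(z) + br(z) + pl(z)
    dg_sc = lambda z: dbl(z) + dbr(z) + dpl(z)
    dip, _ = _gaussian(0.9, 0.0, 1.2)
    d_sc = lambda z: d_bulk * (1.0 - dip(z))
    sc_like = Landscape("sc_like", g_sc, dg_sc, d_sc, const_tau)

    return {l.name: l for l in (flat, gauss, sc_like)}


@dataclass(frozen=True)
class SyntheticRunSpec:
    """Everything needed to emulate one constrained-tracer campaign."""

    landscape: Landscape
    plan: SamplingPlan
    dt: float = 0.05  # ps between force samples
    n_steps: int = 100_000  # samples per window per replicate
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0
    noiseless: bool = False  # sigma = 0 limit (D -> infinity)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


def _window_rng(spec: SyntheticRunSpec, window_id: int, replicate: int) -> np.random.Generator:
    # Distinct, reproducible stream per (seed, window, replicate).
    return np.random.default_rng([spec.seed, window_id, replicate])


def generate_window_series(
    spec: SyntheticRunSpec,
    z0: float,
    *,
    replicate: int = 0,
    config_id: int = 0,
    times: np.ndarray | None = None,
) -> ForceTimeSeries:
    """Generate one window's stationary OU constraint-force series.

    The initial sample is drawn from the stationary law, so the series has
    no equilibration transient.  With ``spec.noiseless`` the series is the
    constant true mean force -dG/dz(z0).
    """
    grid = spec.plan.grid
    window_id = grid.index_of(z0)
    spec.landscape.validate_at(z0)
    mu = -float(spec.landscape.dG_dz(z0))
    if times is None:
        times = spec.dt * np.arange(spec.n_steps)
    if spec.noiseless:
        forces = np.full(spec.n_steps, mu)
        return ForceTimeSeries(window_id, z0, times, forces, config_id, replicate)

    rt = thermal_energy(spec.temperature)
    d = float(spec.landscape.diffusion(z0))
    tau = float(spec.landscape.tau(z0))
    sigma2 = rt**2 / (d * tau)
    sigma = math.sqrt(sigma2)
    a = math.exp(-spec.dt / tau)
    b = sigma * math.sqrt(1.0 - a * a)

    rng = _window_rng(spec, window_id, replicate)
    xi = rng.standard_normal(spec.n_steps)
    # x_k = a x_{k-1} + e_k with e_0 = sigma*xi_0 (stationary start),
    # e_k = b*xi_k; realized as an AR(1) filter.
    e = b * xi
    e[0] = sigma * xi[0]
    x = lfilter([1.0], [1.0, -a], e)
    return ForceTimeSeries(window_id, z0, times, mu + x, config_id, replicate)


def generate_run(spec: SyntheticRunSpec) -> list[ForceTimeSeries]:
    """Generate the full campaign: one series per planned tracer.

    The time grid array is shared between series to keep memory linear in
    the force data only.
    """
    times = spec.dt * np.arange(spec.n_steps)
    out = []
    for window_id, config_id, replicate, z0 in spec.plan.window_assignments():
        out.append(
            generate_window_series(
                spec, z0, replicate=replicate, config_id=config_id, times=times
            )
        )
    return out


def write_run_xvg(series: list[ForceTimeSeries], outdir) -> list[Path]:
    """Write one pull-force XVG per (window, replicate) series."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in series:
        p = outdir / f"pullf_w{s.window_id:03d}_r{s.replicate}.xvg"
        write_xvg(
            p,
            s.times,
            {"force": s.forces},
            title=f"constraint force, window {s.window_id}",
            comments=[
                f"window_id = {s.window_id}",
                f"z0_nm = {s.z0:.6f}",
                f"config_id = {s.config_id}",
                f"replicate = {s.replicate}",
            ],
        )
        paths.append(p)
    return paths


def read_run_xvg(directory, plan: SamplingPlan) -> list[ForceTimeSeries]:
    """Read back a directory of pull-force XVGs written by `write_run_xvg`.

    Window/replicate identity is taken from the file names; z0 from the plan.
    """
    from .io import read_xvg

    directory = Path(directory)
    windows = plan.grid.windows()
    out = []
    for p in sorted(directory.glob("pullf_w*_r*.xvg")):
        stem = p.stem  # pullf_wNNN_rM
        parts = stem.split("_")
        window_id = int(parts[1][1:])
        replicate = int(parts[2][1:])
        df = read_xvg(p)
        out.append(
            ForceTimeSeries(
                window_id=window_id,
                z0=float(windows[window_id]),
                times=df.iloc[:, 0].to_numpy(),
                forces=df.iloc[:, 1].to_numpy(),
                replicate=replicate,
            )
        )
    return out


# ----------------------------------------------------------------------
# Toy membranes
# ----------------------------------------------------------------------
def generate_toy_membrane(
    n_lipids_per_leaflet: int,
    thickness: float = 5.0,
    apl: float = 0.32,
    chain_tilt: float = 0.0,
    n_frames: int = 1,
    seed: int = 0,
    *,
    n_chain_beads: int = 8,
    bead_spacing: float = 0.125,
    chain_sep: float = 0.45,
    jitter: float = 0.0,
    hbond_geometry: tuple[float, float] | None = None,
    water_pad: float = 1.5,
    resname: str = "CER",
) -> Trajectory:
    """Build an idealized two-leaflet membrane of straight bead chains.

    Each lipid has a headgroup marker ``N`` (amide-nitrogen stand-in) lying
    exactly in a plane at +-thickness/2, an amide hydrogen ``H`` pointing
    into the water phase, and two straight chains (sphingoid-like
    ``CS1..CSn`` and fatty-acid-like ``CF1..CFn``) separated laterally by
    ``chain_sep`` and
    tilted ``chain_tilt`` degrees from the membrane normal.  With
    ``hbond_geometry=(d_DA, angle_deg)`` an acceptor ``O`` is placed at that
    donor-acceptor distance and hydrogen-donor-acceptor angle from each
    lipid's own N-H, giving an exactly countable number of hydrogen bonds.

    ``jitter`` adds seeded Gaussian positional noise (nm), redrawn per
    frame; with jitter 0 every geometric property is exact by construction.
    """
    if n_lipids_per_leaflet < 1:
        raise FixtureError("need at least one lipid per leaflet")
    if not (0.0 <= chain_tilt < 90.0):
        raise FixtureError("chain_tilt must lie in [0, 90) degrees")
    if min(thickness, apl, bead_spacing) <= 0 or n_frames < 1:
        raise FixtureError("thickness, apl, bead_spacing, n_frames must be positive")

    tilt = math.radians(chain_tilt)
    lz = thickness + 2.0 * water_pad
    chain_drop = 0.05 + n_chain_beads * bead_spacing * math.cos(tilt)
    if thickness / 2.0 + 0.15 > lz / 2.0 or chain_drop > lz / 2.0 + thickness / 2.0:
        raise FixtureError("chains or headgroups do not fit in the box")

    n = n_lipids_per_leaflet
    lx = ly = math.sqrt(n * apl)
    nx = math.ceil(math.sqrt(n))
    ny = math.ceil(n / nx)

    resids, resnames, names, positions = [], [], [], []
    resid = 0
    for leaflet_sign in (1.0, -1.0):
        for l in range(n):
            resid += 1
            i, j = l % nx, l // nx
            x = (i + 0.5) * lx / nx
            y = (j + 0.5) * ly / ny
            zhead = leaflet_sign * thickness / 2.0
            lipid_atoms = [("N", (x, y, zhead)), ("H", (x, y, zhead + leaflet_sign * 0.1))]
            if hbond_geometry is not None:
                d_da, ang = hbond_geometry
                a = math.radians(ang)
                lipid_atoms.append(
                    ("O", (x + d_da * math.sin(a), y, zhead + leaflet_sign * d_da * math.cos(a)))
                )
            cdir = np.array([math.sin(tilt), 0.0, -leaflet_sign * math.cos(tilt)])
            for label, xoff in (("CS", -chain_sep / 2.0), ("CF", chain_sep / 2.0)):
                base = np.array([x + xoff, y, zhead - leaflet_sign * 0.05])
                for k in range(1, n_chain_beads + 1):
                    p = base + k * bead_spacing * cdir
                    lipid_atoms.append((f"{label}{k}", tuple(p)))
            for name, p in lipid_atoms:
                resids.append(resid)
                resnames.append(resname)
                names.append(name)
                positions.append(p)

    base_positions = np.asarray(positions, dtype=float)
    resids = np.asarray(resids)
    resnames = np.asarray(resnames)
    names = np.asarray(names)
    box = np.array([lx, ly, lz])

    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        pos = base_positions.copy()
        if jitter > 0:
            pos = pos + rng.normal(0.0, jitter, size=pos.shape)
        frames.append(
            Snapshot(
                resids=resids, resnames=resnames, names=names,
                positions=pos, box=box.copy(), time=20.0 * f,
            )
        )
    return Trajectory(frames)
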