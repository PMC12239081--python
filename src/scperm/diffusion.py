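"""Local diffusion from the constraint-force autocorrelation (Kubo route).

For a tracer held at z0 with force fluctuation δF(t) = F(t) - <F>, the local
diffusion coefficient along the membrane normal is

    D_z(z0) = (RT)^2 / ∫_0^∞ <δF(t) δF(0)> dt,

with the time integral truncated at a finite lag once the ACF has decayed.
The ACF uses the unbiased 1/(N-k) estimator; an ACF is "converged" when the
final 10% of its lag range stays below a stated fraction (default 5%) of its
t=0 value.  ACFs of the coverage replicates are averaged before the single
integral (variance reduction before the nonlinear 1/x step); error bars come
from a 5-block partition of each series.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft

from .constants import DEFAULT_TEMPERATURE_K, thermal_energy
from .core import ForceTimeSeries
from .errors import (
    ConvergenceError,
    DegenerateSeriesError,
    InsufficientDataError,
    NonphysicalIntegralError,
)
from .plan import GridSpec

__all__ = ["Acf", "KuboEstimate", "DiffusionProfile", "compute_acf",
           "average_acfs", "check_convergence", "kubo_diffusion",
           "diffusion_profile"]

DEFAULT_CONVERGENCE_THRESHOLD = 0.05
_TAIL_FRACTION = 0.1


@dataclass(frozen=True)
class Acf:
    """Force autocorrelation on a uniform lag grid starting at 0."""

    lags: np.ndarray  # ps
    values: np.ndarray  # (kJ/mol/nm)^2
    n_origin_pairs: int  # samples entering the longest-lag estimate
    converged: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.lags[0] != 0.0:
            raise ValueError("lag grid must start at 0")
        if self.values[0] < -1e-12:
            raise ValueError("ACF at lag 0 must be non-negative")


@dataclass(frozen=True)
class KuboEstimate:
    D: float  # nm^2/ps
    D_error: float | None = None


@dataclass(frozen=True)
class DiffusionProfile:
    """D_z(z) across the window grid with per-window convergence flags."""

    z: np.ndarray
    D: np.ndarray
    D_error: np.ndarray
    converged_mask: np.ndarray
    symmetrized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))
        object.__setattr__(self, "D_error", np.asarray(self.D_error, dtype=float))
        object.__setattr__(self, "converged_mask", np.asarray(self.converged_mask, dtype=bool))
        if not (np.diff(self.z) > 0).all():
            raise ValueError("z grid must be strictly increasing")
        if (self.D[self.converged_mask] <= 0).any():
            raise ValueError("converged windows must have positive D")


def compute_acf(series: ForceTimeSeries, max_lag: float) -> Acf:
    """Unbiased force ACF up to ``max_lag`` (ps) on the sampling grid.

    ACF(k dt) = 1/(N-k) Σ_i δF(t_i) δF(t_{i+k}) with δF the deviation from
    the series' own mean; ACF(0) is the sample variance (ddof=0).  Requires
    the series to span at least twice the requested lag range.
    """
    n = series.n_samples
    dt = series.dt
    if dt <= 0:
        raise InsufficientDataError("series has no time extent")
    if series.duration < 2.0 * max_lag:
        raise InsufficientDataError(
            f"series duration {series.duration:g} ps < 2 x max_lag {max_lag:g} ps"
        )
    k_max = int(np.floor(max_lag / dt + 1e-9))
    d = series.forces - series.forces.mean()
    nfft = _fft.next_fast_len(2 * n)
    spec = _fft.rfft(d, nfft)
    corr = _fft.irfft(spec * np.conj(spec), nfft)[: k_max + 1]
    values = corr / (n - np.arange(k_max + 1))
    return Acf(lags=dt * np.arange(k_max + 1), values=values, n_origin_pairs=n - k_max)


def average_acfs(acfs: list[Acf]) -> Acf:
    """Average ACFs sharing one lag grid (replicate pooling)."""
    lags = acfs[0].lags
    for a in acfs[1:]:
        if len(a.lags) != len(lags) or np.abs(a.lags - lags).max() > 1e-9:
            raise ValueError("ACFs must share the lag grid to be averaged")
    values = np.mean([a.values for a in acfs], axis=0)
    return Acf(lags=lags, values=values, n_origin_pairs=sum(a.n_origin_pairs for a in acfs))


def check_convergence(acf: Acf, threshold: float = DEFAULT_CONVERGENCE_THRESHOLD) -> bool:
    """True iff the final 10% of the lag range stays below threshold x ACF(0)."""
    c0 = acf.values[0]
    if c0 <= 0.0:
        raise DegenerateSeriesError("ACF(0) is zero; convergence undefined")
    tail = acf.values[acf.lags >= (1.0 - _TAIL_FRACTION) * acf.lags[-1]]
    return bool(np.all(np.abs(tail) < threshold * c0))


def kubo_diffusion(
    acf: Acf,
    temperature: float = DEFAULT_TEMPERATURE_K,
    *,
    require_converged: bool = True,
    threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
    block_acfs: list[Acf] | None = None,
) -> KuboEstimate:
    """D = (RT)^2 / ∫ ACF dt (trapezoidal), with optional block error bar.

    A non-positive ACF integral is nonphysical and raises; an unconverged
    ACF raises unless ``require_converged`` is disabled by the caller.  When
    ``block_acfs`` (ACFs of contiguous sub-series) are supplied, the error
    is the standard error of the block-wise D values.
    """
    rt = thermal_energy(temperature)
    integral = float(np.trapezoid(acf.values, acf.lags))
    if integral <= 0.0:
        raise NonphysicalIntegralError(
            f"ACF time integral {integral:g} <= 0; no diffusion coefficient"
        )
    if require_converged:
        converged = acf.converged
        if converged is None:
            converged = check_convergence(acf, threshold)
        if not converged:
            raise ConvergenceError(
                "force ACF has not decayed below the convergence threshold"
            )
    d = rt**2 / integral
    d_err = None
    if block_acfs:
        d_blocks = []
        for b in block_acfs:
            bi = float(np.trapezoid(b.values, b.lags))
            if bi > 0:
                d_blocks.append(rt**2 / bi)
        if len(d_blocks) >= 2:
            d_blocks = np.asarray(d_blocks)
            d_err = float(d_blocks.std(ddof=1) / np.sqrt(len(d_blocks)))
    return KuboEstimate(D=d, D_error=d_err)


def _split_series(s: ForceTimeSeries, n_blocks: int) -> list[ForceTimeSeries]:
    out = []
    for chunk in np.array_split(np.arange(s.n_samples), n_blocks):
        if len(chunk) < 2:
            continue
        out.append(
            ForceTimeSeries(
                s.window_id, s.z0, s.times[chunk] - s.times[chunk[0]],
                s.forces[chunk], s.config_id, s.replicate,
            )
        )
    return out


def diffusion_profile(
    series: list[ForceTimeSeries],
    grid: GridSpec,
    max_lag: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    *,
    threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
    n_blocks: int = 5,
    symmetrize: bool = True,
) -> DiffusionProfile:
    """Assemble D_z(z) across all windows.

    Per window the replicate ACFs are averaged and integrated once; the
    error bar is the spread of D over an ``n_blocks`` partition of each
    series (blocks averaged across replicates before integrating).  With
    ``symmetrize`` the profile is leaflet-averaged as the even part,
    D_sym(z) = (D(z) + D(-z))/2, and a symmetrized window counts as
    converged only if both partners are.
    """
    per_window: dict[int, list[ForceTimeSeries]] = {}
    for s in series:
        per_window.setdefault(grid.index_of(s.z0), []).append(s)

    windows = grid.windows()
    n = grid.n_windows
    d_vals = np.full(n, np.nan)
    d_errs = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    for idx in range(n):
        if idx not in per_window:
            raise InsufficientDataError(f"window {idx} (z={windows[idx]:.3f} nm) has no series")
        reps = per_window[idx]
        pooled = average_acfs([compute_acf(s, max_lag) for s in reps])
        try:
            converged = check_convergence(pooled, threshold)
        except DegenerateSeriesError:
            converged = False
        # blockwise ACFs: block b averaged across replicates
        block_acfs = []
        per_rep_blocks = [_split_series(s, n_blocks) for s in reps]
        n_blk = min(len(b) for b in per_rep_blocks)
        for b in range(n_blk):
            block_acfs.append(
                average_acfs([compute_acf(blocks[b], max_lag) for blocks in per_rep_blocks])
            )
        est = kubo_diffusion(
            pooled, temperature, require_converged=False, block_acfs=block_acfs
        )
        d_vals[idx] = est.D
        d_errs[idx] = est.D_error if est.D_error is not None else np.nan
        mask[idx] = converged

    if not symmetrize:
        return DiffusionProfile(windows, d_vals, d_errs, mask, symmetrized=False)

    d_sym = np.empty_like(d_vals)
    e_sym = np.empty_like(d_errs)
    m_sym = np.empty_like(mask)
    for i, z in enumerate(windows):
        j = int(np.argmin(np.abs(windows + z)))
        if abs(windows[j] + z) > 1e-6 * grid.window_spacing:
            raise InsufficientDataError(
                f"window z={z:.4f} nm has no mirror partner; cannot symmetrize"
            )
        d_sym[i] = 0.5 * (d_vals[i] + d_vals[j])
        e_sym[i] = 0.5 * np.hypot(d_errs[i], d_errs[j])
        m_sym[i] = mask[i] and mask[j]
    return DiffusionProfile(windows, d_sym, e_sym, m_sym, symmetrized=True)
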