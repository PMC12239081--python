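"""Potential of mean constraint force: from force series to ΔG(z).

The mean constraint force per window is integrated along the reaction
coordinate with the trapezoidal rule,

    ΔG(z0) = - ∫_{z_out}^{z0} <F(z)>_t dz,

anchored to zero in bulk water.  Before integration the force profile is
symmetrized to its odd part, F_sym(z) = (F(z) - F(-z))/2, which averages the
two leaflets; the resulting ΔG profile is then exactly even.

Uncertainties: the coverage repeats of each window are treated as the
independent unit (raw samples are heavily autocorrelated), so the window
standard error is the spread of replicate means.  Windows sampled only once
fall back to a 5-block partition of the single series.  Errors propagate
through the trapezoid weights assuming window independence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ForceTimeSeries
from .errors import GapError, PairingError
from .plan import GridSpec

__all__ = ["WindowStats", "FreeEnergyProfile", "bin_forces", "symmetrize_forces",
           "integrate_pmf"]

_FALLBACK_BLOCKS = 5


@dataclass(frozen=True)
class WindowStats:
    """Per-window force statistics after binning."""

    z0: float
    mean_force: float  # kJ/mol/nm
    force_variance: float  # pooled sample variance of retained samples
    standard_error: float  # SE of the mean force
    n_samples: int
    n_replicates: int
    analysis_interval: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.standard_error < 0 or self.force_variance < 0:
            raise ValueError("variance and standard error must be non-negative")


@dataclass(frozen=True)
class FreeEnergyProfile:
    """ΔG(z) on the window grid with propagated uncertainty (kJ/mol)."""

    z: np.ndarray
    dG: np.ndarray
    dG_error: np.ndarray
    anchored_at: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "dG", np.asarray(self.dG, dtype=float))
        object.__setattr__(self, "dG_error", np.asarray(self.dG_error, dtype=float))
        if not (np.diff(self.z) > 0).all():
            raise ValueError("z grid must be strictly increasing")
        if (self.dG_error < 0).any():
            raise ValueError("errors must be non-negative")
        i = int(np.argmin(np.abs(self.z - self.anchored_at)))
        if abs(self.dG[i]) > 1e-9:
            raise ValueError("profile must vanish at its anchor")

    @property
    def anchor_index(self) -> int:
        return int(np.argmin(np.abs(self.z - self.anchored_at)))


def _block_se(values: np.ndarray, n_blocks: int = _FALLBACK_BLOCKS) -> float:
    """SE of the mean from the spread of contiguous block means."""
    blocks = [b for b in np.array_split(values, n_blocks) if len(b)]
    if len(blocks) < 2:
        return 0.0
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def bin_forces(
    series: list[ForceTimeSeries],
    grid: GridSpec,
    analysis_window: tuple[float, float] | None = None,
) -> list[WindowStats]:
    """Bin force series onto the window grid and average over time.

    Samples with times outside ``analysis_window`` (closed interval, ps) are
    discarded — e.g. ``(20000, 40000)`` keeps exactly the last half of a
    40 ns record, dropping the noisier early production.  Every grid window
    must end up with at least one retained sample.

    Returns one :class:`WindowStats` per window, ordered by z.
    """
    per_window: dict[int, list[np.ndarray]] = {}
    for s in series:
        idx = grid.index_of(s.z0)
        if analysis_window is None:
            kept = s.forces
        else:
            t0, t1 = analysis_window
            if t0 > t1:
                raise ValueError("analysis window start exceeds end")
            if t0 > s.times[-1] or t1 < s.times[0]:
                raise ValueError(
                    f"analysis window ({t0}, {t1}) ps lies outside the data range "
                    f"({s.times[0]}, {s.times[-1]}) ps"
                )
            kept = s.forces[(s.times >= t0) & (s.times <= t1)]
        if len(kept):
            per_window.setdefault(idx, []).append(kept)

    windows = grid.windows()
    empty = [i for i in range(grid.n_windows) if i not in per_window]
    if empty:
        raise GapError(
            "no retained samples in windows "
            + ", ".join(f"{i} (z={windows[i]:.3f} nm)" for i in empty)
        )

    if analysis_window is None:
        t_lo = min(float(s.times[0]) for s in series)
        t_hi = max(float(s.times[-1]) for s in series)
        interval = (t_lo, t_hi)
    else:
        interval = (float(analysis_window[0]), float(analysis_window[1]))

    stats = []
    for idx in range(grid.n_windows):
        chunks = per_window[idx]
        pooled = np.concatenate(chunks)
        rep_means = np.array([c.mean() for c in chunks])
        mean = float(pooled.mean())
        var = float(pooled.var(ddof=1)) if len(pooled) > 1 else 0.0
        if len(chunks) > 1:
            se = float(rep_means.std(ddof=1) / np.sqrt(len(chunks)))
        else:
            se = _block_se(chunks[0])
        stats.append(
            WindowStats(
                z0=float(windows[idx]),
                mean_force=mean,
                force_variance=var,
                standard_error=se,
                n_samples=int(len(pooled)),
                n_replicates=len(chunks),
                analysis_interval=interval,
            )
        )
    return stats


def symmetrize_forces(stats: list[WindowStats]) -> list[WindowStats]:
    """Replace the force profile by its odd part (leaflet average).

    F_sym(z) = (F(z) - F(-z))/2; errors combine as half the root sum of
    squares of the pair; a window at z = 0 is forced to zero.  The grid must
    be symmetric about the bilayer center so that windows pair exactly.
    """
    stats = sorted(stats, key=lambda s: s.z0)
    z = np.array([s.z0 for s in stats])
    spacing = np.diff(z).min() if len(z) > 1 else 1.0
    tol = 1e-6 * max(spacing, 1.0)

    out = []
    for s in stats:
        if abs(s.z0) <= tol:
            out.append(
                WindowStats(s.z0, 0.0, s.force_variance, 0.0, s.n_samples,
                            s.n_replicates, s.analysis_interval)
            )
            continue
        j = int(np.argmin(np.abs(z + s.z0)))
        if abs(z[j] + s.z0) > tol:
            raise PairingError(
                f"window z={s.z0:.4f} nm has no mirror partner; grid is not "
                "symmetric about the bilayer center"
            )
        p = stats[j]
        f_sym = 0.5 * (s.mean_force - p.mean_force)
        se = 0.5 * np.hypot(s.standard_error, p.standard_error)
        out.append(
            WindowStats(
                z0=s.z0,
                mean_force=f_sym,
                force_variance=0.5 * (s.force_variance + p.force_variance),
                standard_error=float(se),
                n_samples=s.n_samples + p.n_samples,
                n_replicates=s.n_replicates + p.n_replicates,
                analysis_interval=s.analysis_interval,
            )
        )
    return out


def integrate_pmf(stats: list[WindowStats], anchor: float | None = None) -> FreeEnergyProfile:
    """Trapezoidal integration of the mean-force profile into ΔG(z).

    ΔG(z0) = -∫_{anchor}^{z0} F(z) dz with the anchor defaulting to the most
    bulk-ward window on the negative side (the bulk-water reference).  The
    window grid must be contiguous (uniform spacing); gaps refuse to
    integrate.  Errors propagate through the trapezoid weights treating
    windows as independent.
    """
    stats = sorted(stats, key=lambda s: s.z0)
    z = np.array([s.z0 for s in stats])
    f = np.array([s.mean_force for s in stats])
    se = np.array([s.standard_error for s in stats])
    if len(z) < 2:
        raise GapError("need at least two windows to integrate")
    gaps = np.diff(z)
    h = gaps.min()
    if np.abs(gaps - h).max() > 1e-6 * h:
        raise GapError("window grid has gaps or uneven spacing; integration refused")

    if anchor is None:
        anchor = float(z[0])
    ia = int(np.argmin(np.abs(z - anchor)))
    if abs(z[ia] - anchor) > 1e-6 * h:
        raise GapError(f"anchor {anchor} nm is not a grid window")

    # cumulative trapezoid from the left edge, then re-reference to anchor
    cum = np.concatenate([[0.0], np.cumsum(0.5 * gaps * (f[:-1] + f[1:]))])
    dG = -(cum - cum[ia])

    # error: ΔG(z_k) is a weighted sum of window forces between anchor and k
    var = np.empty_like(dG)
    for k in range(len(z)):
        lo, hi = min(ia, k), max(ia, k)
        if lo == hi:
            var[k] = 0.0
            continue
        w = np.zeros(hi - lo + 1)
        seg = gaps[lo:hi]
        w[:-1] += 0.5 * seg
        w[1:] += 0.5 * seg
        var[k] = float(np.sum((w * se[lo : hi + 1]) ** 2))
    return FreeEnergyProfile(z=z, dG=dG, dG_error=np.sqrt(var), anchored_at=float(z[ia]))
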