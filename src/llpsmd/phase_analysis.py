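"""Slab-trajectory analysis: density profiles, coexisting densities,
critical points, and surface tension.

The binodal is closed with the critical-exponent and rectilinear-diameter
scaling laws,

    ρ_h - ρ_l        = d (1 - T/T_c)^β            (width law, β = 0.325 by
    (ρ_h + ρ_l) / 2  = ρ_c + s (T_c - T)           default: 3D Ising)

fitted jointly by least squares with bootstrap uncertainties.  Surface
tension comes from the pressure-tensor anisotropy across the slab,
γ = (L_z/2) ⟨P_zz - (P_xx + P_yy)/2⟩, the half accounting for the two
interfaces, and scales as γ ∝ (T_c - T)^1.26 near the critical point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .forcefield import AVOGADRO_FACTOR
from .simulator import Trajectory

# kJ/mol/nm^2 -> mN/m
GAMMA_UNIT = 1.0e21 / 6.02214076e23 * 1.0e3


class NoCoexistenceError(RuntimeError):
    """Profile shows no resolvable dense/dilute plateau pair."""


@dataclass
class DensityProfile:
    """Mass-density profile along the slab normal, recentered per frame on
    the slab's center of mass."""

    z: np.ndarray            # bin centers relative to the slab center, nm
    rho: np.ndarray          # g/cm^3
    area: float = np.nan     # box cross-section, nm^2
    species: str | None = None

    def __post_init__(self) -> None:
        if np.any(self.rho < -1e-12):
            raise ValueError("negative densities")
        dz = np.diff(self.z)
        if len(dz) and not np.allclose(dz, dz[0]):
            raise ValueError("bins must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def total_mass(self) -> float:
        """Integral of the profile times the cross-section, g/mol."""
        return float(np.sum(self.rho) * self.bin_width * self.area
                     * AVOGADRO_FACTOR)


@dataclass
class BinodalPoint:
    temperature: float       # K
    rho_low: float           # g/cm^3
    rho_high: float          # g/cm^3
    rho_low_err: float = 0.0
    rho_high_err: float = 0.0

    def __post_init__(self) -> None:
        if not self.rho_high > self.rho_low >= 0:
            raise ValueError("need rho_high > rho_low >= 0")

    @property
    def width(self) -> float:
        return self.rho_high - self.rho_low

    @property
    def diameter(self) -> float:
        return 0.5 * (self.rho_high + self.rho_low)


@dataclass
class PhaseDiagram:
    points: list
    tc: float                # K
    rho_c: float             # g/cm^3
    tc_err: float = 0.0
    rho_c_err: float = 0.0
    beta: float = 0.325
    width_amplitude: float = np.nan
    diameter_slope: float = np.nan
    non_monotonic_width: bool = False

    def __post_init__(self) -> None:
        ts = [p.temperature for p in self.points]
        if ts and not self.tc > max(ts):
            raise ValueError("fitted Tc must exceed all sampled coexistence T")


@dataclass
class SurfaceTensionSeries:
    temperatures: np.ndarray     # K
    gamma: np.ndarray            # mN/m
    errors: np.ndarray | None = None


@dataclass
class GammaScalingFit:
    amplitude: float             # mN/m / K^exponent
    tc: float
    exponent: float = 1.26

    def predict(self, temperature) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        out = self.amplitude * np.clip(self.tc - t, 0.0, None) ** self.exponent
        return float(out) if out.ndim == 0 else out


# -- density profiles ---------------------------------------------------------

def _slab_center(z: np.ndarray, mass: np.ndarray, lz: float) -> float:
    """Mass-weighted center along a periodic axis via the circular mean
    (robust against slabs crossing the boundary and slow slab drift)."""
    theta = 2.0 * np.pi * z / lz
    s = np.average(np.sin(theta), weights=mass)
    c = np.average(np.cos(theta), weights=mass)
    return float(np.arctan2(s, c) / (2.0 * np.pi) * lz % lz)


def density_profile(traj: Trajectory, bins: int = 100,
                    species: str | None = None) -> DensityProfile:
    """Frame-averaged mass-density profile along z.

    ``species`` restricts the *binned* beads to chains of that species; the
    recentering always uses all beads so per-species profiles share one frame
    of reference.
    """
    topo = traj.topology
    if topo is None:
        raise ValueError("trajectory carries no topology")
    lx, ly, lz = traj.box
    mass = topo.mass
    if species is None:
        sel = np.ones(topo.n_beads, dtype=bool)
    else:
        chains = set(topo.chains_of_species(species))
        sel = np.array([c in chains for c in topo.chain_id])
        if not np.any(sel):
            raise ValueError(f"no beads of species {species!r}")
    edges = np.linspace(-lz / 2, lz / 2, bins + 1)
    hist = np.zeros(bins)
    for f in range(traj.n_frames):
        z = np.mod(traj.positions[f][:, 2], lz)
        zc = _slab_center(z, mass, lz)
        zrel = np.mod(z - zc + lz / 2, lz) - lz / 2
        hist += np.histogram(zrel[sel], bins=edges, weights=mass[sel])[0]
    hist /= traj.n_frames
    dz = edges[1] - edges[0]
    rho = hist / (lx * ly * dz * AVOGADRO_FACTOR)   # g/cm^3
    centers = 0.5 * (edges[1:] + edges[:-1])
    return DensityProfile(z=centers, rho=rho, area=float(lx * ly),
                          species=species)


# -- coexisting densities -----------------------------------------------------

def _tanh_profile(z, rho_h, rho_l, z0, w):
    return 0.5 * (rho_h + rho_l) - 0.5 * (rho_h - rho_l) * np.tanh(
        (np.abs(z) - z0) / w)


def coexisting_densities(profile: DensityProfile,
                         temperature: float = np.nan) -> BinodalPoint:
    """Hyperbolic-tangent interface fit returning the two plateau densities.

    Raises :class:`NoCoexistenceError` when the fit does not converge or the
    plateau separation is smaller than 3x the residual noise.
    """
    z, rho = profile.z, profile.rho
    rho_h0 = float(np.mean(rho[np.abs(z) < 0.1 * z.max()])) or float(rho.max())
    rho_l0 = float(np.mean(rho[np.abs(z) > 0.8 * z.max()]))
    p0 = [max(rho_h0, 1e-6), max(rho_l0, 0.0), 0.5 * z.max(),
          0.05 * z.max() + 1e-3]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(_tanh_profile, z, rho, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise NoCoexistenceError(f"interface fit failed: {err}") from err
    rho_h, rho_l, z0, w = popt
    if rho_h < rho_l:           # tanh fit can swap branches
        rho_h, rho_l = rho_l, rho_h
    noise = float(np.std(rho - _tanh_profile(z, *popt)))
    if rho_h - rho_l < 3.0 * noise or w <= 0 or not np.isfinite(pcov).all():
        raise NoCoexistenceError(
            f"plateaus indistinguishable (width {rho_h - rho_l:.3g}, "
            f"noise {noise:.3g})")
    perr = np.sqrt(np.abs(np.diag(pcov)))
    return BinodalPoint(temperature=temperature, rho_low=max(rho_l, 0.0),
                        rho_high=rho_h, rho_low_err=float(perr[1]),
                        rho_high_err=float(perr[0]))


# -- critical point -----------------------------------------------------------

def _fit_scaling_laws(t, width, diam, beta):
    """Joint LSQ of the width and diameter laws; returns (tc, d, rho_c, s)."""
    # linearized initialisations
    wb = width ** (1.0 / beta)
    a1, a0 = np.polyfit(t, wb, 1)           # wb = a1 T + a0
    tc0 = -a0 / a1 if a1 < 0 else t.max() * 1.05
    tc0 = max(tc0, t.max() * 1.0001)
    d0 = float(np.mean(width / np.clip(1 - t / tc0, 1e-12, None) ** beta))
    s0, rc0 = np.polyfit(tc0 - t, diam, 1)

    scale_w = max(np.mean(width), 1e-12)
    scale_d = max(np.mean(diam), 1e-12)

    def residuals(x):
        tc, d, rho_c, s = x
        red = np.clip(1.0 - t / tc, 1e-12, None)
        r1 = (d * red ** beta - width) / scale_w
        r2 = (rho_c + s * (tc - t) - diam) / scale_d
        return np.concatenate([r1, r2])

    sol = least_squares(residuals, x0=[tc0, d0, rc0, s0],
                        bounds=([t.max() * 1.000001, 0, 0, -np.inf],
                                [np.inf] * 4), xtol=1e-14, ftol=1e-14)
    return sol.x


def fit_critical_point(points, beta: float = 0.325, n_bootstrap: int = 200,
                       seed: int = 0) -> PhaseDiagram:
    """Estimate (T_c, ρ_c) from binodal points via the critical-exponent and
    rectilinear-diameter laws, with bootstrap uncertainties."""
    if len(points) < 3:
        raise ValueError("need at least 3 binodal points")
    t = np.array([p.temperature for p in points], dtype=float)
    width = np.array([p.width for p in points])
    diam = np.array([p.diameter for p in points])
    order = np.argsort(t)
    non_monotonic = bool(np.any(np.diff(width[order]) > 0))
    if non_monotonic:
        warnings.warn("binodal width is not monotonically decreasing in T",
                      stacklevel=2)

    tc, d, rho_c, s = _fit_scaling_laws(t, width, diam, beta)

    tcs, rcs = [], []
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(points), size=len(points))
            if len(np.unique(t[idx])) < 3:
                continue
            try:
                bt, _, brc, _ = _fit_scaling_laws(t[idx], width[idx],
                                                  diam[idx], beta)
            except Exception:
                continue
            tcs.append(bt)
            rcs.append(brc)
    tc_err = float(np.std(tcs)) if tcs else 0.0
    rc_err = float(np.std(rcs)) if rcs else 0.0
    return PhaseDiagram(points=list(points), tc=float(tc), rho_c=float(rho_c),
                        tc_err=tc_err, rho_c_err=rc_err, beta=beta,
                        width_amplitude=float(d), diameter_slope=float(s),
                        non_monotonic_width=non_monotonic)


# -- surface tension ----------------------------------------------------------

def surface_tension(traj: Trajectory, n_blocks: int = 5
                    ) -> tuple[float, float]:
    """γ in mN/m from the slab pressure-tensor anisotropy, with a block-
    averaged standard error.

    γ = (L_z / 2) ⟨P_zz − (P_xx + P_yy)/2⟩ — the factor 2 accounts for the
    two interfaces of the slab; invariant under relabeling x ↔ y.
    """
    if traj.pressure is None or len(traj.pressure) == 0:
        raise ValueError("trajectory has no pressure-tensor data")
    p = traj.pressure
    lz = float(traj.box[2])
    gamma_t = 0.5 * lz * (p[:, 2, 2] - 0.5 * (p[:, 0, 0] + p[:, 1, 1]))
    gamma_t = gamma_t * GAMMA_UNIT
    blocks = np.array_split(gamma_t, min(n_blocks, len(gamma_t)))
    means = np.array([b.mean() for b in blocks])
    err = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else 0.0
    return float(gamma_t.mean()), err


def fit_gamma_scaling(series: SurfaceTensionSeries, tc: float,
                      exponent: float = 1.26) -> GammaScalingFit:
    """One-parameter amplitude fit of γ = A (T_c − T)^exponent.

    The exponent is held fixed (1.26, the 3D Ising surface-tension value);
    γ extrapolates to 0 at T_c by construction.
    """
    t = np.asarray(series.temperatures, dtype=float)
    g = np.asarray(series.gamma, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 (T, gamma) points")
    if np.any(t >= tc):
        raise ValueError("all temperatures must lie below Tc")
    x = (tc - t) ** exponent
    amplitude = float(np.dot(x, g) / np.dot(x, x))
    return GammaScalingFit(amplitude=amplitude, tc=tc, exponent=exponent)


# -- RNA scans ----------------------------------------------------------------

def scan_reentrance(entries, electroneutral_ratio: float | None = None):
    """Normalized critical temperature versus RNA/protein mass ratio.

    ``entries`` is a list of (mass_ratio, PhaseDiagram-or-Tc); a ratio of 0
    (the pure protein) must be present and defines the normalization Tc0.
    Returns a pandas DataFrame with the electroneutrality ratio and the
    ratio maximizing Tc/Tc0 in ``attrs``.
    """
    import pandas as pd

    rows = []
    for ratio, item in entries:
        tc = float(getattr(item, "tc", item))
        rows.append((float(ratio), tc))
    rows.sort()
    ratios = np.array([r for r, _ in rows])
    tcs = np.array([tc for _, tc in rows])
    if 0.0 not in ratios:
        raise ValueError("need the pure-protein (ratio 0) entry")
    tc0 = float(tcs[ratios == 0.0][0])
    df = pd.DataFrame({"mass_ratio": ratios, "tc": tcs,
                       "tc_over_tc0": tcs / tc0})
    df.attrs["electroneutral_ratio"] = electroneutral_ratio
    df.attrs["max_stability_ratio"] = float(ratios[np.argmax(tcs)])
    return df
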