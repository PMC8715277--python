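"""Conformational and dynamical observables of condensates.

* P(Rg): mass-weighted radius-of-gyration distributions per species, with an
  optional condensed/dilute phase split for slab systems.
* MSD and diffusion coefficients from chain centers of mass, multiple time
  origins (FFT), automatic diffusive-window detection by the log-log slope.
* Green-Kubo shear rheology: the relaxation modulus
  G(t) = V/(k_B T) ⟨P_αβ(0) P_αβ(t)⟩ averaged over the five independent
  traceless components (xy, xz, yz and the two normal-stress differences),
  a non-negative least-squares Maxwell-mode fit G(t) ≈ Σ G_i exp(-t/τ_i),
  and the zero-shear viscosity η = Σ G_i τ_i.

Internal pressure units are kJ/mol/nm^3 and times ps; viscosities are
reported in mPa·s and diffusion coefficients in nm^2/ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .forcefield import KB
from .simulator import Trajectory

# (kJ/mol/nm^3) * ps -> mPa*s
VISCOSITY_UNIT = 1.0e30 / 6.02214076e23 * 1.0e-12 * 1.0e3


class NoDiffusiveRegimeError(RuntimeError):
    """MSD exhibits no window with log-log slope within 1 +/- 0.1."""


# -- radius of gyration -------------------------------------------------------

@dataclass
class RgHistogram:
    bin_centers: np.ndarray       # nm
    density: np.ndarray           # normalized, integrates to 1
    species: str | None = None
    phase: str | None = None      # 'condensed' | 'dilute' | None
    values: np.ndarray | None = None   # underlying per-chain-frame Rg samples

    def __post_init__(self) -> None:
        if np.any(self.bin_centers < 0):
            raise ValueError("Rg must be non-negative")
        width = self.bin_centers[1] - self.bin_centers[0]
        if abs(float(np.sum(self.density) * width) - 1.0) > 1e-6:
            raise ValueError("histogram must integrate to 1")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _check_unwrapped(traj: Trajectory, chain_slices) -> None:
    half = float(np.min(traj.box)) / 2
    for a, b in chain_slices:
        if b - a < 2:
            continue
        bond = np.diff(traj.positions[:, a:b, :], axis=1)
        if np.abs(bond).max() > half:
            raise ValueError(
                "chain crosses half the box: positions appear wrapped; "
                "Rg needs unwrapped coordinates")


def radius_of_gyration(positions: np.ndarray, mass: np.ndarray) -> float:
    com = np.average(positions, axis=0, weights=mass)
    return float(np.sqrt(np.average(np.sum((positions - com) ** 2, axis=1),
                                    weights=mass)))


def rg_distribution(
    traj: Trajectory,
    species: str | None = None,
    bins: int = 50,
    phase: str | None = None,
    slab_halfwidth: float | None = None,
) -> RgHistogram:
    """Mass-weighted Rg per chain per frame, histogrammed and normalized.

    With ``phase`` set ('condensed' or 'dilute') chains are classified per
    frame by whether their center of mass lies within ``slab_halfwidth`` of
    the slab's (circular-mean) center along z.
    """
    from .phase_analysis import _slab_center

    topo = traj.topology
    chains = (topo.chains_of_species(species) if species is not None
              else range(topo.n_chains))
    slices = [topo.chain_slices[c] for c in chains]
    _check_unwrapped(traj, slices)
    if phase is not None and slab_halfwidth is None:
        raise ValueError("phase selection needs slab_halfwidth")
    lz = float(traj.box[2])
    values = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        if phase is not None:
            zc = _slab_center(np.mod(pos[:, 2], lz), topo.mass, lz)
        for a, b in slices:
            if phase is not None:
                z_com = np.average(np.mod(pos[a:b, 2], lz),
                                   weights=topo.mass[a:b])
                dz = abs((z_com - zc + lz / 2) % lz - lz / 2)
                inside = dz <= slab_halfwidth
                if (phase == "condensed") != inside:
                    continue
            values.append(radius_of_gyration(pos[a:b], topo.mass[a:b]))
    values = np.array(values)
    if len(values) == 0:
        raise ValueError(f"no chains in phase {phase!r}")
    hist, edges = np.histogram(values, bins=bins, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    # guard the degenerate all-identical case (histogram width 0)
    if not np.isfinite(hist).all():
        raise ValueError("degenerate Rg distribution")
    return RgHistogram(bin_centers=centers, density=hist, species=species,
                       phase=phase, values=values)


# -- mean-squared displacement ------------------------------------------------

@dataclass
class MSD:
    times: np.ndarray             # lag times, ps (starts at 0)
    msd: np.ndarray               # nm^2
    block_msd: np.ndarray | None = None   # (n_blocks, n_lags_block)
    block_times: np.ndarray | None = None


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Multiple-time-origin MSD of one coordinate series (FFT method)."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    d = x ** 2
    q = 2.0 * d.sum()
    s1 = np.empty(n)
    for m in range(n):
        if m > 0:
            q -= d[m - 1] + d[n - m]
        s1[m] = q / (n - m)
    return s1 - 2.0 * acf / (n - np.arange(n))


def _com_tracks(traj: Trajectory, species: str | None) -> np.ndarray:
    topo = traj.topology
    chains = (topo.chains_of_species(species) if species is not None
              else range(topo.n_chains))
    tracks = []
    for c in chains:
        a, b = topo.chain_slices[c]
        tracks.append(np.average(traj.positions[:, a:b, :], axis=1,
                                 weights=topo.mass[a:b]))
    return np.array(tracks)      # (C, F, 3)


def msd(traj: Trajectory, species: str | None = None,
        remove_drift: bool = True, n_blocks: int = 5) -> MSD:
    """Chain center-of-mass MSD averaged over chains and time origins.

    ``remove_drift`` subtracts the per-frame system center-of-mass motion.
    Per-block MSDs (5 contiguous trajectory blocks) are kept for the
    diffusion-coefficient error estimate.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    tracks = _com_tracks(traj, species)
    if remove_drift:
        com = np.average(
            traj.positions, axis=1, weights=traj.topology.mass)  # (F, 3)
        tracks = tracks - com[None, :, :]

    def msd_of(block: np.ndarray) -> np.ndarray:
        acc = np.zeros(block.shape[1])
        for c in range(block.shape[0]):
            for k in range(3):
                acc += _msd_fft_1d(np.ascontiguousarray(block[c, :, k]))
        return acc / block.shape[0]

    total = msd_of(tracks)
    dt = traj.frame_spacing
    times = np.arange(len(total)) * dt
    block_msd = None
    block_times = None
    if n_blocks > 1 and traj.n_frames >= 4 * n_blocks:
        fb = traj.n_frames // n_blocks
        block_msd = np.array([msd_of(tracks[:, i * fb:(i + 1) * fb, :])
                              for i in range(n_blocks)])
        block_times = np.arange(fb) * dt
    return MSD(times=times, msd=total, block_msd=block_msd,
               block_times=block_times)


def _diffusive_window(times, values, slope_tol=0.1, min_points=5):
    """Longest contiguous index window with local log-log slope in 1±tol."""
    t = times[1:]
    y = np.clip(values[1:], 1e-300, None)
    logt, logy = np.log(t), np.log(y)
    slope = np.gradient(logy, logt)
    good = np.abs(slope - 1.0) <= slope_tol
    best = None
    start = None
    for i, g in enumerate(np.append(good, False)):
        if g and start is None:
            start = i
        elif not g and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if best is None or best[1] - best[0] < min_points:
        raise NoDiffusiveRegimeError(
            "no contiguous MSD window with log-log slope within "
            f"1±{slope_tol}")
    return best[0] + 1, best[1] + 1     # shift for the dropped t=0


def diffusion_coefficient(m: MSD, fit_window: tuple | None = None
                          ) -> tuple[float, float, tuple]:
    """D = slope/6 of a linear MSD fit inside the diffusive regime.

    Returns (D [nm^2/ps], uncertainty, (i0, i1) window indices). The window
    is auto-detected by the log-log slope criterion when not given; the
    uncertainty is the standard error over per-block estimates.
    """
    if fit_window is None:
        i0, i1 = _diffusive_window(m.times, m.msd)
        # restrict to the first fifth of the series: longer lags average too
        # few time origins for a reliable slope
        i1 = min(i1, max(len(m.times) // 5, i0 + 5))
    else:
        i0, i1 = fit_window
        t = m.times[max(i0, 1):i1]
        y = m.msd[max(i0, 1):i1]
        slope = np.polyfit(np.log(t), np.log(np.clip(y, 1e-300, None)), 1)[0]
        if abs(slope - 1.0) > 0.1:
            raise NoDiffusiveRegimeError(
                f"requested window has log-log slope {slope:.2f}")
    slope = np.polyfit(m.times[i0:i1], m.msd[i0:i1], 1)[0]
    d = slope / 6.0
    err = 0.0
    if m.block_msd is not None:
        ds = []
        j1 = min(i1, len(m.block_times))
        j0 = min(i0, max(j1 - 2, 1))
        for bm in m.block_msd:
            s = np.polyfit(m.block_times[j0:j1], bm[j0:j1], 1)[0]
            ds.append(s / 6.0)
        err = float(np.std(ds, ddof=1) / np.sqrt(len(ds)))
    return float(d), err, (i0, i1)


# -- shear relaxation modulus -------------------------------------------------

@dataclass
class MaxwellMode:
    g: float      # kJ/mol/nm^3
    tau: float    # ps


@dataclass
class RelaxationModulus:
    times: np.ndarray             # lag times, ps
    g: np.ndarray                 # kJ/mol/nm^3
    temperature: float            # K
    volume: float                 # nm^3
    modes: list = field(default_factory=list)    # sorted by tau
    mode_cov: np.ndarray | None = None           # covariance of (g1..gn,t1..tn)
    fit_start_index: int = 0

    def g_fit(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for m in self.modes:
            out = out + m.g * np.exp(-t / m.tau)
        return out


def _acf_fft(x: np.ndarray) -> np.ndarray:
    """Unbiased autocovariance (mean removed), multiple time origins."""
    x = x - x.mean()
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    return acf / (n - np.arange(n))


def relaxation_modulus(
    traj: Trajectory | np.ndarray,
    temperature: float | None = None,
    volume: float | None = None,
    dt: float | None = None,
    max_lag: int | None = None,
) -> RelaxationModulus:
    """G(t) from the stress (pressure-tensor) autocorrelation.

    Averages the five independent components xy, xz, yz, (P_xx - P_yy)/2 and
    (P_yy - P_zz)/2 over multiple time origins. ``traj`` may be a Trajectory
    or a raw (F, 3, 3) tensor series (then dt, temperature and volume are
    required). The series must be at least 10x the longest requested lag.
    """
    if isinstance(traj, Trajectory):
        p = traj.pressure
        dt = traj.frame_spacing
        volume = traj.volume if volume is None else volume
        if temperature is None:
            temperature = float(np.mean(traj.kinetic_temperature))
    else:
        p = np.asarray(traj)
        if dt is None or temperature is None or volume is None:
            raise ValueError("raw series needs dt, temperature and volume")
    n = len(p)
    if max_lag is None:
        max_lag = n // 10
    if n < 10 * max_lag:
        raise ValueError(f"series of {n} frames is shorter than 10x the "
                         f"longest requested lag ({max_lag})")
    comps = [p[:, 0, 1], p[:, 0, 2], p[:, 1, 2],
             0.5 * (p[:, 0, 0] - p[:, 1, 1]),
             0.5 * (p[:, 1, 1] - p[:, 2, 2])]
    acf = np.mean([_acf_fft(c)[: max_lag + 1] for c in comps], axis=0)
    g = volume / (KB * temperature) * acf
    times = np.arange(max_lag + 1) * dt
    return RelaxationModulus(times=times, g=g, temperature=temperature,
                             volume=volume)


def fit_maxwell_modes(modulus: RelaxationModulus, n_modes: int = 8,
                      fit_start: int = 0) -> RelaxationModulus:
    """Maxwell-mode fit of G(t): NNLS over a log-spaced τ grid, pruning of
    zero-weight modes, then nonlinear refinement of the surviving (G_i, τ_i).

    Returns a copy of ``modulus`` with ``modes`` (sorted by τ) and their
    covariance filled in. τ grid spans 2x the frame spacing to 1/4 of the
    series length.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    t = modulus.times[fit_start:]
    g = modulus.g[fit_start:]
    if np.all(g == 0):
        raise ValueError("all-zero modulus")
    dt = modulus.times[1] - modulus.times[0]
    tau_grid = np.geomspace(2 * dt, modulus.times[-1] * 2.5, 60)
    design = np.exp(-t[:, None] / tau_grid[None, :])
    weights, _ = nnls(design, g)
    keep = weights > 0
    taus = tau_grid[keep]
    gs = weights[keep]
    if len(taus) == 0:
        taus = np.array([modulus.times[len(modulus.times) // 2] + dt])
        gs = np.array([max(g[0], 1e-12)])
    if len(taus) > n_modes:
        top = np.argsort(gs * taus)[-n_modes:]
        taus, gs = taus[top], gs[top]

    def residuals(x):
        gg = x[: len(taus)] ** 2
        tt = x[len(taus):] ** 2
        return design_eval(gg, tt) - g

    def design_eval(gg, tt):
        return np.sum(gg[None, :] * np.exp(-t[:, None] / tt[None, :]), axis=1)

    x0 = np.concatenate([np.sqrt(gs), np.sqrt(taus)])
    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, max_nfev=2000)
    k = len(taus)
    gg = sol.x[:k] ** 2
    tt = sol.x[k:] ** 2
    keep = gg * tt > 1e-12 * np.max(gg * tt)
    gg, tt = gg[keep], tt[keep]
    order = np.argsort(tt)
    modes = [MaxwellMode(float(gi), float(ti))
             for gi, ti in zip(gg[order], tt[order])]

    # covariance of (G_i, tau_i) via the Jacobian in those variables
    cov = None
    try:
        jac = np.empty((len(t), 2 * len(modes)))
        for i, m in enumerate(modes):
            e = np.exp(-t / m.tau)
            jac[:, i] = e
            jac[:, len(modes) + i] = m.g * e * t / m.tau ** 2
        resid = modulus.g[fit_start:] - sum(
            m.g * np.exp(-t / m.tau) for m in modes)
        dof = max(len(t) - 2 * len(modes), 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov = None
    return RelaxationModulus(
        times=modulus.times, g=modulus.g, temperature=modulus.temperature,
        volume=modulus.volume, modes=modes, mode_cov=cov,
        fit_start_index=fit_start)


def viscosity(modulus: RelaxationModulus) -> tuple[float, float]:
    """Zero-shear viscosity η = Σ G_i τ_i in mPa·s, with the uncertainty
    propagated from the Maxwell-fit covariance.

    When the fit starts after lag 0, the raw short-time segment of G(t) is
    integrated numerically (trapezoid) and added.
    """
    if not modulus.modes:
        raise ValueError("no Maxwell-mode fit present; run fit_maxwell_modes")
    eta = sum(m.g * m.tau for m in modulus.modes)
    i0 = modulus.fit_start_index
    if i0 > 0:
        eta += float(np.trapezoid(modulus.g[: i0 + 1], modulus.times[: i0 + 1]))
        # subtract the fitted part over the same segment to avoid double count
        eta -= float(np.trapezoid(modulus.g_fit(modulus.times[: i0 + 1]),
                                  modulus.times[: i0 + 1]))
    err = 0.0
    if modulus.mode_cov is not None:
        k = len(modulus.modes)
        grad = np.concatenate([[m.tau for m in modulus.modes],
                               [m.g for m in modulus.modes]])
        var = float(grad @ modulus.mode_cov @ grad)
        err = np.sqrt(max(var, 0.0)) * VISCOSITY_UNIT
    return float(eta) * VISCOSITY_UNIT, err
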