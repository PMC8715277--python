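"""Synthetic-data generators with the statistical structure the analyses
assume, so every pipeline stage is testable at desk scale.

Each generator is a pure function of (parameters, seed); files written from
them carry the generating spec in a '#' header. The generators emulate
functional forms only — binodals obeying the scaling laws, tanh slab
profiles, Ornstein-Uhlenbeck (OU) stress with an exact Maxwell-mode
autocorrelation — not the absolute values of any real protein system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .forcefield import KB, BeadParams, build_interaction_table
from .phase_analysis import BinodalPoint, DensityProfile, _tanh_profile
from .sequences import ProteinSequence
from .simulator import ChainTopology, SystemState


@dataclass(frozen=True)
class FixtureSpec:
    kind: str          # toy_sequence | binodal | tanh_profile | stress_series | langevin_gas
    parameters: dict
    seed: int

    def header(self) -> str:
        return (f"# fixture kind={self.kind} seed={self.seed}\n"
                f"# parameters={json.dumps(self.parameters, sort_keys=True)}\n")


def toy_sequences(style: str, length: int, params: dict | None = None,
                  seed: int = 0) -> list[ProteinSequence]:
    """Deterministic toy peptides for demixing and electrostatics tests.

    * ``hydrophobic``: homopolymer of the maximum-λ residue in the loaded
      parameter table (ties broken alphabetically).
    * ``charged-diblock``: K/D diblock, net charge 0 for even length.
    * ``mixed``: the diblock shuffled (seeded), same composition.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if params is None:
        from .forcefield import load_bead_params
        params = load_bead_params()
    if style == "hydrophobic":
        best = min((p for p in params.values()
                    if p.lam == max(q.lam for q in params.values())),
                   key=lambda p: p.code)
        return [ProteinSequence(f"hydrophobic{length}", best.code * length)]
    if style == "charged-diblock":
        half = length // 2
        seq = "K" * half + "D" * (length - half)
        return [ProteinSequence(f"diblock{length}", seq)]
    if style == "mixed":
        half = length // 2
        letters = list("K" * half + "D" * (length - half))
        rng = np.random.default_rng(seed)
        rng.shuffle(letters)
        return [ProteinSequence(f"mixed{length}", "".join(letters))]
    raise ValueError(f"unknown style {style!r}")


def synthetic_binodal(
    tc: float,
    rho_c: float,
    width_amplitude: float = 0.5,
    diameter_slope: float = 1e-3,
    beta: float = 0.325,
    n_points: int = 6,
    noise: float = 0.0,
    seed: int = 0,
    t_low_frac: float = 0.80,
    t_high_frac: float = 0.98,
) -> list[BinodalPoint]:
    """Binodal points generated exactly from the critical-exponent and
    rectilinear-diameter laws, with multiplicative Gaussian noise."""
    if n_points < 3:
        raise ValueError("need n_points >= 3")
    rng = np.random.default_rng(seed)
    t = np.linspace(t_low_frac * tc, t_high_frac * tc, n_points)
    width = width_amplitude * (1.0 - t / tc) ** beta
    diam = rho_c + diameter_slope * (tc - t)
    rho_h = diam + width / 2
    rho_l = diam - width / 2
    if noise > 0:
        rho_h = rho_h * (1.0 + noise * rng.standard_normal(n_points))
        rho_l = rho_l * (1.0 + noise * rng.standard_normal(n_points))
    points = []
    for ti, lo, hi in zip(t, rho_l, rho_h):
        points.append(BinodalPoint(temperature=float(ti),
                                   rho_low=float(max(lo, 0.0)),
                                   rho_high=float(hi)))
    return points


def tanh_profile(
    rho_h: float,
    rho_l: float,
    z0: float,
    width: float,
    bins: int = 200,
    noise: float = 0.0,
    seed: int = 0,
    box_length: float | None = None,
    area: float = 25.0,
) -> DensityProfile:
    """Symmetric double-interface slab profile
    ρ(z) = (ρh+ρl)/2 − (ρh−ρl)/2 tanh((|z|−z0)/w), optional multiplicative
    Gaussian noise."""
    if not rho_h > rho_l:
        raise ValueError("need rho_h > rho_l")
    lz = box_length if box_length is not None else 4.0 * z0
    z = np.linspace(-lz / 2, lz / 2, bins + 1)
    z = 0.5 * (z[1:] + z[:-1])
    rho = _tanh_profile(z, rho_h, rho_l, z0, width)
    if noise > 0:
        rng = np.random.default_rng(seed)
        rho = np.clip(rho * (1.0 + noise * rng.standard_normal(bins)), 0.0,
                      None)
    return DensityProfile(z=z, rho=rho, area=area)


def stress_series(
    modes,
    temperature: float,
    volume: float,
    n_steps: int,
    dt: float,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic (F, 3, 3) pressure-tensor series whose shear relaxation
    modulus is exactly Σ G_i exp(-t/τ_i).

    Each of the five independent components averaged by the G(t) estimator
    (xy, xz, yz and the two normal-stress differences) is built as a sum of
    independent OU processes with stationary variance G_i k_B T / V and
    correlation time τ_i (exact discretization, stationary start).
    """
    modes = list(modes)
    if not modes:
        raise ValueError("need at least one Maxwell mode")
    gs = np.array([float(m[0]) for m in modes])
    taus = np.array([float(m[1]) for m in modes])
    if np.any(gs < 0) or np.any(taus <= 0):
        raise ValueError("modes need G >= 0 and tau > 0")
    if np.all(gs == 0):
        return np.zeros((n_steps, 3, 3))
    if dt >= taus.min() / 10:
        raise ValueError(f"dt={dt} under-resolves the fastest mode "
                         f"(tau_min={taus.min()}); need dt < tau_min/10")
    rng = np.random.default_rng(seed)
    var = gs * KB * temperature / volume
    decay = np.exp(-dt / taus)
    kick = np.sqrt(var * (1.0 - decay ** 2))
    comps = np.empty((5, n_steps))
    for c in range(5):
        x = rng.standard_normal(len(modes)) * np.sqrt(var)   # stationary start
        for step in range(n_steps):
            comps[c, step] = x.sum()
            x = x * decay + kick * rng.standard_normal(len(modes))
    xy, xz, yz, a, b = comps
    p = np.zeros((n_steps, 3, 3))
    p[:, 0, 1] = p[:, 1, 0] = xy
    p[:, 0, 2] = p[:, 2, 0] = xz
    p[:, 1, 2] = p[:, 2, 1] = yz
    # diagonal chosen so (Pxx-Pyy)/2 = a and (Pyy-Pzz)/2 = b
    p[:, 0, 0] = 2.0 * a
    p[:, 2, 2] = -2.0 * b
    return p


def langevin_gas(n_beads: int = 100, mass: float = 100.0, sigma: float = 0.4,
                 box: float = 20.0, seed: int = 0):
    """Dilute gas of free (non-bonded, λ=0, uncharged) beads: topology, state
    and interaction table for equipartition/diffusion checks."""
    bead = BeadParams("A", mass=mass, charge=0.0, sigma=sigma, lam=0.0)
    table = build_interaction_table([bead], cation_pi_pairs={})
    rng = np.random.default_rng(seed)
    topo = ChainTopology(
        codes=["A"] * n_beads,
        type_index=np.zeros(n_beads, dtype=np.int64),
        chain_id=np.arange(n_beads, dtype=np.int64),
        mass=np.full(n_beads, mass), charge=np.zeros(n_beads),
        lam_scale=np.ones(n_beads),
        bonds=np.empty((0, 2), dtype=np.int64),
        bond_pref=np.empty(0), bond_r0=np.empty(0),
        chain_species=[f"bead{i}" for i in range(n_beads)],
        chain_slices=[(i, i + 1) for i in range(n_beads)],
    )
    # give each single-bead chain the same species name for selections
    topo.chain_species = ["gas"] * n_beads
    positions = rng.uniform(0, box, size=(n_beads, 3))
    state = SystemState(positions=positions,
                        velocities=np.zeros((n_beads, 3)),
                        box=np.array([box, box, box]))
    return topo, state, table


# -- fixture file I/O ---------------------------------------------------------

def save_binodal(points, path, spec: FixtureSpec | None = None) -> None:
    with open(path, "w") as fh:
        if spec is not None:
            fh.write(spec.header())
        fh.write("temperature,rho_low,rho_high\n")
        for p in points:
            fh.write(f"{p.temperature:.17g},{p.rho_low:.17g},{p.rho_high:.17g}\n")


def load_binodal(path) -> list[BinodalPoint]:
    points = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("temperature"):
                continue
            t, lo, hi = (float(x) for x in line.split(","))
            points.append(BinodalPoint(temperature=t, rho_low=lo, rho_high=hi))
    return points


def save_profile(profile: DensityProfile, path,
                 spec: FixtureSpec | None = None) -> None:
    with open(path, "w") as fh:
        if spec is not None:
            fh.write(spec.header())
        fh.write(f"# area={profile.area}\n")
        fh.write("z,rho\n")
        for z, r in zip(profile.z, profile.rho):
            fh.write(f"{z:.10g},{r:.10g}\n")


def load_profile(path) -> DensityProfile:
    zs, rs, area = [], [], np.nan
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# area="):
                area = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#") or line.startswith("z,"):
                continue
            z, r = (float(x) for x in line.split(","))
            zs.append(z)
            rs.append(r)
    return DensityProfile(z=np.array(zs), rho=np.array(rs), area=area)


def save_stress(series: np.ndarray, path, dt: float, temperature: float,
                volume: float, spec: FixtureSpec | None = None) -> None:
    with open(path, "w") as fh:
        if spec is not None:
            fh.write(spec.header())
        fh.write(f"# dt={dt} temperature={temperature} volume={volume}\n")
        fh.write("pxx,pyy,pzz,pxy,pxz,pyz\n")
        for p in series:
            fh.write(f"{p[0, 0]:.10g},{p[1, 1]:.10g},{p[2, 2]:.10g},"
                     f"{p[0, 1]:.10g},{p[0, 2]:.10g},{p[1, 2]:.10g}\n")


def load_stress(path):
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# dt="):
                for kv in line[2:].split():
                    k, v = kv.split("=")
                    meta[k] = float(v)
                continue
            if not line or line.startswith("#") or line.startswith("pxx"):
                continue
            rows.append([float(x) for x in line.split(",")])
    arr = np.array(rows)
    p = np.zeros((len(arr), 3, 3))
    p[:, 0, 0], p[:, 1, 1], p[:, 2, 2] = arr[:, 0], arr[:, 1], arr[:, 2]
    p[:, 0, 1] = p[:, 1, 0] = arr[:, 3]
    p[:, 0, 2] = p[:, 2, 0] = arr[:, 4]
    p[:, 1, 2] = p[:, 2, 1] = arr[:, 5]
    return p, meta
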