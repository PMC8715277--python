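"""Langevin-dynamics engine for direct-coexistence (slab) and bulk runs.

Geometry convention: orthorhombic periodic box, slab axis = z (interfaces
normal to z, box elongated along z).  Positions are integrated *unwrapped*
(needed downstream for radii of gyration and mean-squared displacements);
periodicity enters only through minimum-image distances in the force kernels
and through wrapped coordinates handed to the neighbor search.

Integrator: BAOAB splitting of Langevin dynamics.  In the zero-friction
limit it reduces exactly to velocity Verlet (NVE).  All randomness (initial
velocities, thermostat noise) comes from one seeded generator.

Units: nm, ps, K, g/mol, kJ/mol — a consistent set (1 kJ/mol = 1 (g/mol)
(nm/ps)^2), so kinetic energy and temperature need no conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .forcefield import (
    KB, AVOGADRO_FACTOR, BondParams, ElectrostaticsParams, InteractionTable,
    DEFAULT_PROTEIN_BOND, DEFAULT_RNA_BOND,
)
from .sequences import ProteinSequence, RNASequence


class SimulationDivergedError(RuntimeError):
    """A position update exceeded half the box in one step."""


# -- topology -----------------------------------------------------------------

@dataclass
class ChainTopology:
    """Bead-level description of all molecules in the system.

    Bonds connect consecutive beads of one chain; optional extra restraint
    bonds (elastic networks over structured regions) are appended to the same
    arrays with their own (k, r0).
    """

    codes: list                      # per-bead residue/nucleotide code
    type_index: np.ndarray           # per-bead index into the InteractionTable
    chain_id: np.ndarray             # per-bead chain number
    mass: np.ndarray                 # g/mol
    charge: np.ndarray               # e
    lam_scale: np.ndarray            # per-bead short-range scale (0.7 buried)
    bonds: np.ndarray                # (B, 2) bead indices
    bond_pref: np.ndarray            # (B,) energy prefactor (k or k/2)
    bond_r0: np.ndarray              # (B,) nm
    chain_species: list = field(default_factory=list)   # species name per chain
    chain_slices: list = field(default_factory=list)    # (start, stop) per chain

    def __post_init__(self) -> None:
        for i, j in self.bonds[: len(self.bonds)]:
            if self.chain_id[i] != self.chain_id[j]:
                raise ValueError("bond between beads of different chains")

    @property
    def n_beads(self) -> int:
        return len(self.codes)

    @property
    def n_chains(self) -> int:
        return len(self.chain_slices)

    def chains_of_species(self, name: str) -> list:
        return [k for k, s in enumerate(self.chain_species) if s == name]

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    @classmethod
    def from_sequences(
        cls,
        items: Sequence[tuple[ProteinSequence | RNASequence, int]],
        table: InteractionTable,
        protein_bond: BondParams = DEFAULT_PROTEIN_BOND,
        rna_bond: BondParams = DEFAULT_RNA_BOND,
        buried_scale: float = 0.7,
        elastic_network: bool = False,
        elastic_k: float = 500.0,
        elastic_cutoff: float = 1.0,
    ) -> "ChainTopology":
        """Build a topology from (sequence, copy-count) pairs.

        Residues inside domains flagged buried get ``buried_scale`` on their
        short-range interactions; with ``elastic_network`` those regions also
        receive harmonic restraints between template neighbors within
        ``elastic_cutoff`` (ideal α-helix template), keeping them rigid.
        """
        codes: list[str] = []
        chain_id: list[int] = []
        lam_scale: list[float] = []
        bonds: list[tuple[int, int]] = []
        bond_pref: list[float] = []
        bond_r0: list[float] = []
        species: list[str] = []
        slices: list[tuple[int, int]] = []
        chain = 0
        for seq, count in items:
            is_rna = isinstance(seq, RNASequence)
            bp = rna_bond if is_rna else protein_bond
            residues = seq.residues
            n = len(residues)
            scale = np.ones(n)
            regions: list[tuple[int, int]] = []
            if not is_rna:
                for d in getattr(seq, "structured_regions", ()):
                    scale[d.slice] = buried_scale
                    regions.append((d.start - 1, d.end))
            for _ in range(count):
                offset = len(codes)
                codes.extend(residues)
                chain_id.extend([chain] * n)
                lam_scale.extend(scale)
                for i in range(n - 1):
                    bonds.append((offset + i, offset + i + 1))
                    bond_pref.append(bp.prefactor)
                    bond_r0.append(bp.r0)
                if elastic_network:
                    for a, b in regions:
                        for i, j, r in _helix_restraints(b - a, elastic_cutoff):
                            bonds.append((offset + a + i, offset + a + j))
                            bond_pref.append(0.5 * elastic_k)
                            bond_r0.append(r)
                species.append(seq.id)
                slices.append((offset, offset + n))
                chain += 1
        tidx = table.type_indices(codes)
        return cls(
            codes=codes, type_index=tidx,
            chain_id=np.array(chain_id, dtype=np.int64),
            mass=table.mass[tidx].copy(), charge=table.charge[tidx].copy(),
            lam_scale=np.array(lam_scale),
            bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
            bond_pref=np.array(bond_pref), bond_r0=np.array(bond_r0),
            chain_species=species, chain_slices=slices,
        )


def _helix_template(n: int) -> np.ndarray:
    """Ideal α-helix backbone template (radius 0.23 nm, rise 0.15 nm/res,
    100° per residue)."""
    k = np.arange(n)
    theta = np.deg2rad(100.0) * k
    return np.column_stack([0.23 * np.cos(theta), 0.23 * np.sin(theta), 0.15 * k])


def _helix_restraints(n: int, cutoff: float) -> list[tuple[int, int, float]]:
    """Non-consecutive template pairs within ``cutoff`` and their distances."""
    pos = _helix_template(n)
    out = []
    for i in range(n):
        for j in range(i + 2, n):
            r = float(np.linalg.norm(pos[j] - pos[i]))
            if r <= cutoff:
                out.append((i, j, r))
    return out


# -- state & config -----------------------------------------------------------

@dataclass
class SystemState:
    positions: np.ndarray            # (N, 3) nm, unwrapped
    velocities: np.ndarray           # (N, 3) nm/ps
    box: np.ndarray                  # (3,) edge lengths, nm
    time: float = 0.0                # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def wrapped(self) -> np.ndarray:
        """Positions folded into [0, box) by the minimum-image convention."""
        return np.mod(self.positions, self.box)

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.box.copy(), self.time)


@dataclass
class SimulationConfig:
    timestep: float = 0.01        # ps (10 fs)
    friction: float = 0.01        # 1/ps
    temperature: float = 300.0    # K
    n_steps: int = 1000
    save_interval: int = 100
    skin: float = 0.4             # neighbor-list skin, nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")


@dataclass
class Trajectory:
    """Uniformly spaced snapshots plus per-frame energy terms and the full
    (symmetric) pressure tensor."""

    positions: np.ndarray           # (F, N, 3) unwrapped, nm
    times: np.ndarray               # (F,) ps
    box: np.ndarray                 # (3,) nm
    pressure: np.ndarray            # (F, 3, 3) kJ/mol/nm^3
    energies: dict                  # term -> (F,) kJ/mol
    kinetic_temperature: np.ndarray  # (F,) K
    topology: ChainTopology | None = None

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def frame_spacing(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrapped(self, frame: int) -> np.ndarray:
        return np.mod(self.positions[frame], self.box)


# -- neighbor list ------------------------------------------------------------

def neighbor_list(state: SystemState, cutoff: float, skin: float = 0.0
                  ) -> np.ndarray:
    """Candidate pair set: all pairs within cutoff+skin (superset of pairs
    within cutoff), via a periodic k-d tree."""
    if skin < 0:
        raise ValueError("skin must be non-negative")
    if cutoff + skin > float(np.min(state.box)) / 2:
        raise ValueError("cutoff+skin exceeds half the smallest box edge")
    if state.n_beads == 0:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(state.wrapped(), boxsize=state.box)
    pairs = tree.query_pairs(cutoff + skin, output_type="ndarray")
    return pairs.astype(np.int64)


# -- force kernels ------------------------------------------------------------

@njit(cache=True)
def _nonbonded_kernel(pos, box, pairs, tidx, lscale, q, sigma_t, lam_t, cp_t,
                      eps, kc, inv_ld, rc_factor, rc_dh, forces, virial):
    e_ah = 0.0
    e_dh = 0.0
    e_cp = 0.0
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        ti = tidx[i]
        tj = tidx[j]
        s = sigma_t[ti, tj]
        rc = rc_factor * s
        dudr = 0.0
        if r < rc:
            lam = lam_t[ti, tj] * lscale[i] * lscale[j]
            sr6 = (s / r) ** 6
            lj = 4.0 * eps * (sr6 * sr6 - sr6)
            dlj = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            src6 = (s / rc) ** 6
            ljc = 4.0 * eps * (src6 * src6 - src6)
            if r <= 1.122462048309373 * s:
                e_ah += lj + (1.0 - lam) * eps - lam * ljc
                dudr += dlj
            else:
                e_ah += lam * (lj - ljc)
                dudr += lam * dlj
            ecp = cp_t[ti, tj]
            if ecp > 0.0:
                ljp = 4.0 * ecp * (sr6 * sr6 - sr6)
                dljp = 4.0 * ecp * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                ljpc = 4.0 * ecp * (src6 * src6 - src6)
                e_cp += ljp - ljpc
                dudr += dljp
        qq = q[i] * q[j]
        if qq != 0.0 and r < rc_dh:
            pref = kc * qq
            ex = np.exp(-r * inv_ld)
            e_dh += pref * (ex / r - np.exp(-rc_dh * inv_ld) / rc_dh)
            dudr += -pref * ex * (1.0 / r2 + inv_ld / r)
        if dudr != 0.0:
            fs = -dudr / r
            fx = fs * dx
            fy = fs * dy
            fz = fs * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            virial[0, 0] += dx * fx
            virial[0, 1] += dx * fy
            virial[0, 2] += dx * fz
            virial[1, 0] += dy * fx
            virial[1, 1] += dy * fy
            virial[1, 2] += dy * fz
            virial[2, 0] += dz * fx
            virial[2, 1] += dz * fy
            virial[2, 2] += dz * fz
    return e_ah, e_dh, e_cp


@njit(cache=True)
def _bond_kernel(pos, box, bonds, pref, r0, forces, virial):
    e = 0.0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - r0[k]
        e += pref[k] * d * d
        fs = -2.0 * pref[k] * d / r
        fx = fs * dx
        fy = fs * dy
        fz = fs * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 0] += dy * fx
        virial[1, 1] += dy * fy
        virial[1, 2] += dy * fz
        virial[2, 0] += dz * fx
        virial[2, 1] += dz * fy
        virial[2, 2] += dz * fz
    return e


@dataclass
class ForceResult:
    forces: np.ndarray              # (N, 3) kJ/mol/nm
    energies: dict                  # term -> kJ/mol
    virial: np.ndarray              # (3, 3) kJ/mol

    @property
    def total_energy(self) -> float:
        return float(sum(self.energies.values()))


def _bonded_pair_mask(pairs: np.ndarray, bonds: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of candidate pairs that are NOT chain bonds (nonbonded
    terms are excluded between directly bonded beads)."""
    if len(bonds) == 0 or len(pairs) == 0:
        return np.ones(len(pairs), dtype=bool)
    bond_keys = np.minimum(bonds[:, 0], bonds[:, 1]) * n + np.maximum(bonds[:, 0], bonds[:, 1])
    keys = np.minimum(pairs[:, 0], pairs[:, 1]) * n + np.maximum(pairs[:, 0], pairs[:, 1])
    return ~np.isin(keys, bond_keys)


def compute_forces(
    state: SystemState,
    topology: ChainTopology,
    table: InteractionTable,
    electrostatics: ElectrostaticsParams | None = None,
    pairs: np.ndarray | None = None,
) -> ForceResult:
    """Forces (exact negative gradients of the truncated-shifted potentials),
    per-term energies and the virial tensor Σ r_ij ⊗ f_ij."""
    if not np.all(np.isfinite(state.positions)):
        raise ValueError("non-finite coordinates")
    if electrostatics is None:
        electrostatics = ElectrostaticsParams()
    has_charge = bool(np.any(topology.charge != 0))
    rc_max = table.max_cutoff(has_charge)
    if pairs is None:
        pairs = neighbor_list(state, rc_max, 0.0)
        pairs = pairs[_bonded_pair_mask(pairs, topology.bonds, state.n_beads)]
    forces = np.zeros_like(state.positions)
    virial = np.zeros((3, 3))
    e_ah, e_dh, e_cp = _nonbonded_kernel(
        state.positions, state.box, pairs, topology.type_index,
        topology.lam_scale, topology.charge,
        table.pair_sigma, table.pair_lambda, table.cation_pi_eps,
        table.epsilon, electrostatics.coulomb_prefactor,
        1.0 / electrostatics.debye_length,
        table.short_cutoff_factor, table.dh_cutoff, forces, virial)
    e_bond = 0.0
    if len(topology.bonds):
        e_bond = _bond_kernel(state.positions, state.box, topology.bonds,
                              topology.bond_pref, topology.bond_r0,
                              forces, virial)
    return ForceResult(
        forces=forces,
        energies={"bond": float(e_bond), "ah": float(e_ah),
                  "dh": float(e_dh), "cation_pi": float(e_cp)},
        virial=virial)


# -- initial configuration ----------------------------------------------------

def build_slab_system(
    topology: ChainTopology,
    table: InteractionTable,
    target_density: float,
    box_aspect: float = 3.0,
    seed: int = 0,
    max_chain_restarts: int = 500,
) -> SystemState:
    """Place all chains as self-avoiding random walks in a central dense slab.

    The slab spans x,y fully and a central z-window whose thickness is set so
    that slab mass density equals ``target_density`` (g/cm^3); the box is
    elongated along z by ``box_aspect``. No placed pair is closer than
    0.7 σij. Deterministic for a given seed.
    """
    if target_density <= 0:
        raise ValueError("target density must be positive")
    if box_aspect < 1:
        raise ValueError("box aspect must be >= 1")
    v_slab = topology.total_mass / (AVOGADRO_FACTOR * target_density)  # nm^3
    s = v_slab ** (1.0 / 3.0)
    box = np.array([s, s, box_aspect * s])
    z_lo, z_hi = (box[2] - s) / 2, (box[2] + s) / 2
    # quick feasibility check: hard-core packing fraction of the slab
    radii = 0.35 * table.pair_sigma[topology.type_index, topology.type_index]
    packing = float(np.sum(4 / 3 * np.pi * radii ** 3)) / v_slab
    if packing > 0.55:
        raise ValueError(
            f"target density {target_density} g/cm^3 geometrically infeasible "
            f"(hard-core packing fraction {packing:.2f})")
    rng = np.random.default_rng(seed)
    sigma_self = table.pair_sigma
    placed: list[np.ndarray] = []
    tree: cKDTree | None = None
    placed_tidx: list[int] = []

    def clashes(p: np.ndarray, t: int, chain_pos: list, chain_t: list) -> bool:
        pw = np.mod(p, box)
        if tree is not None:
            idx = tree.query_ball_point(pw, 0.7 * table.pair_sigma.max())
            for q in idx:
                d = placed_arr[q] - pw
                d -= box * np.rint(d / box)
                if np.dot(d, d) < (0.7 * sigma_self[t, placed_tidx[q]]) ** 2:
                    return True
        for q in range(len(chain_pos) - 1):  # skip the bonded predecessor
            d = chain_pos[q] - p
            d -= box * np.rint(d / box)
            if np.dot(d, d) < (0.7 * sigma_self[t, chain_t[q]]) ** 2:
                return True
        return False

    placed_arr = np.empty((0, 3))
    for (a, b) in topology.chain_slices:
        tids = topology.type_index[a:b]
        n = b - a
        bond_lengths = topology.bond_r0[
            (topology.bonds[:, 0] >= a) & (topology.bonds[:, 1] < b)
            & (topology.bonds[:, 1] - topology.bonds[:, 0] == 1)]
        ok = False
        for _ in range(max_chain_restarts):
            start = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                              rng.uniform(z_lo, z_hi)])
            if clashes(start, tids[0], [], []):
                continue
            chain = [start]
            chain_t = [int(tids[0])]
            for i in range(1, n):
                r0 = bond_lengths[i - 1] if len(bond_lengths) >= i else 0.38
                good = False
                for _ in range(50):
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    p = chain[-1] + r0 * u
                    if not (z_lo <= p[2] <= z_hi):
                        continue
                    if clashes(p, int(tids[i]), chain, chain_t):
                        continue
                    good = True
                    break
                if not good:
                    break
                chain.append(p)
                chain_t.append(int(tids[i]))
            if len(chain) == n:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place chain of {n} beads at density "
                f"{target_density} g/cm^3 after {max_chain_restarts} restarts")
        placed.extend(chain)
        placed_tidx.extend(chain_t)
        placed_arr = np.mod(np.array(placed), box)
        tree = cKDTree(placed_arr, boxsize=box)

    positions = np.array(placed)
    return SystemState(positions=positions,
                       velocities=np.zeros_like(positions), box=box)


def minimize_energy(
    state: SystemState,
    topology: ChainTopology,
    table: InteractionTable,
    electrostatics: ElectrostaticsParams | None = None,
    n_steps: int = 500,
    max_displacement: float = 0.02,
    ftol: float = 1.0,
) -> SystemState:
    """Displacement-capped steepest descent to relax builder overlaps before
    dynamics (returns a new state; velocities are zeroed).

    Stops after ``n_steps`` or once the maximum force magnitude falls below
    ``ftol`` (kJ/mol/nm).
    """
    state = state.copy()
    state.velocities[:] = 0.0
    for _ in range(n_steps):
        res = compute_forces(state, topology, table, electrostatics)
        fmax = float(np.abs(res.forces).max())
        if fmax < ftol:
            break
        step = res.forces * (max_displacement / fmax)
        state.positions += step
    return state


def maxwell_boltzmann_velocities(topology: ChainTopology, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(topology.n_beads, 3))
    v *= np.sqrt(KB * temperature / topology.mass)[:, None]
    v -= np.average(v, axis=0, weights=topology.mass)  # zero total momentum
    return v


# -- integrator ---------------------------------------------------------------

def kinetic_temperature(velocities: np.ndarray, mass: np.ndarray) -> float:
    ke2 = float(np.sum(mass[:, None] * velocities ** 2))
    return ke2 / (3.0 * len(mass) * KB)


def run_langevin(
    state: SystemState,
    topology: ChainTopology,
    config: SimulationConfig,
    table: InteractionTable,
    electrostatics: ElectrostaticsParams | None = None,
) -> tuple[Trajectory, SystemState]:
    """BAOAB Langevin dynamics; returns the trajectory and the final state.

    Frames are recorded at t=0 and then every ``save_interval`` steps, each
    carrying per-term potential energies and the instantaneous pressure
    tensor (kinetic + virial)/V.
    """
    if electrostatics is None:
        electrostatics = ElectrostaticsParams(temperature=config.temperature)
    state = state.copy()
    rng = np.random.default_rng(config.seed)
    n = state.n_beads
    dt = config.timestep
    m = topology.mass[:, None]
    if not np.any(state.velocities):
        state.velocities = maxwell_boltzmann_velocities(
            topology, config.temperature, rng)
    c1 = np.exp(-config.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB * config.temperature / topology.mass)[:, None]

    has_charge = bool(np.any(topology.charge != 0))
    rc_max = table.max_cutoff(has_charge)
    half_min_box = float(np.min(state.box)) / 2

    ref_pos = state.positions.copy()
    pairs = neighbor_list(state, rc_max, config.skin)
    pairs = pairs[_bonded_pair_mask(pairs, topology.bonds, n)]

    frames, times, pressures, temps = [], [], [], []
    energies: dict[str, list] = {"bond": [], "ah": [], "dh": [], "cation_pi": []}
    volume = float(np.prod(state.box))

    def record(res: ForceResult) -> None:
        frames.append(state.positions.copy())
        times.append(state.time)
        kin = np.einsum("ni,n,nj->ij", state.velocities, topology.mass,
                        state.velocities)
        pressures.append((kin + res.virial) / volume)
        temps.append(kinetic_temperature(state.velocities, topology.mass))
        for k, v in res.energies.items():
            energies[k].append(v)

    res = compute_forces(state, topology, table, electrostatics, pairs)
    record(res)

    for step in range(config.n_steps):
        v = state.velocities
        v += 0.5 * dt * res.forces / m
        dx1 = 0.5 * dt * v
        state.positions += dx1
        if config.friction > 0:
            v *= c1
            v += c2 * rng.standard_normal(size=(n, 3))
        dx2 = 0.5 * dt * v
        state.positions += dx2
        if max(np.abs(dx1).max(), np.abs(dx2).max()) > half_min_box:
            raise SimulationDivergedError(
                f"step {step}: displacement exceeded half the box "
                f"(max |dx| = {max(np.abs(dx1).max(), np.abs(dx2).max()):.3g} nm); "
                "reduce the timestep or check the starting configuration")
        disp = np.abs(state.positions - ref_pos).max()
        if disp > config.skin / 2:
            ref_pos = state.positions.copy()
            pairs = neighbor_list(state, rc_max, config.skin)
            pairs = pairs[_bonded_pair_mask(pairs, topology.bonds, n)]
        res = compute_forces(state, topology, table, electrostatics, pairs)
        v += 0.5 * dt * res.forces / m
        state.time += dt
        if (step + 1) % config.save_interval == 0:
            record(res)

    traj = Trajectory(
        positions=np.array(frames), times=np.array(times),
        box=state.box.copy(), pressure=np.array(pressures),
        energies={k: np.array(v) for k, v in energies.items()},
        kinetic_temperature=np.array(temps), topology=topology)
    return traj, state


# -- trajectory I/O -----------------------------------------------------------

def write_extxyz(traj: Trajectory, path) -> None:
    """Plain-text extended-XYZ; the comment line carries time, box and the
    flattened pressure tensor."""
    codes = traj.topology.codes if traj.topology is not None else None
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            pos = traj.positions[f]
            fh.write(f"{len(pos)}\n")
            p = " ".join(f"{x:.8g}" for x in traj.pressure[f].ravel())
            b = " ".join(f"{x:.8g}" for x in traj.box)
            fh.write(f'time={traj.times[f]:.8g} box="{b}" pressure="{p}"\n')
            for i, (x, y, z) in enumerate(pos):
                c = codes[i] if codes is not None else "X"
                fh.write(f"{c} {x:.8f} {y:.8f} {z:.8f}\n")


def read_extxyz(path) -> Trajectory:
    frames, times, pressures = [], [], []
    box = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            n = int(header)
            meta = fh.readline()
            fields = dict(
                (kv.split("=", 1)[0], kv.split("=", 1)[1])
                for kv in _split_quoted(meta))
            times.append(float(fields["time"]))
            box = np.array([float(x) for x in fields["box"].split()])
            pressures.append(np.array(
                [float(x) for x in fields["pressure"].split()]).reshape(3, 3))
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(x) for x in parts[1:4]]
            frames.append(pos)
    return Trajectory(
        positions=np.array(frames), times=np.array(times), box=box,
        pressure=np.array(pressures), energies={},
        kinetic_temperature=np.zeros(len(frames)))


def _split_quoted(line: str) -> list[str]:
    import shlex
    return shlex.split(line.strip())


def write_pdb(state: SystemState, topology: ChainTopology, path) -> None:
    """Minimal PDB snapshot (one CA-style atom per bead), wrapped coordinates
    in Å."""
    pos = state.wrapped() * 10.0
    with open(path, "w") as fh:
        bx = state.box * 10.0
        fh.write(f"CRYST1{bx[0]:9.3f}{bx[1]:9.3f}{bx[2]:9.3f}"
                 f"  90.00  90.00  90.00 P 1           1\n")
        for i, (x, y, z) in enumerate(pos):
            chain = int(topology.chain_id[i]) % 62
            code = topology.codes[i]
            fh.write(
                f"ATOM  {i % 99999 + 1:5d}  CA  {code:>3s} A{(i % 9999) + 1:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")
        fh.write("END\n")
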