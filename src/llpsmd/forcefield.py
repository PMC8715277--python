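"""Sequence-dependent coarse-grained force field for disordered proteins and RNA.

One bead per amino acid (or nucleotide), implicit solvent. Four interaction
terms:

* harmonic bonds between consecutive beads,
* short-range hydropathy-scaled Ashbaugh-Hatch (AH) pair potential,
* screened Debye-Hückel (DH) electrostatics (Yukawa form),
* an extra Lennard-Jones well for cation-π pairs (R/K against F/W/Y).

Residues buried inside structured globular domains have their short-range
interactions scaled down by 30% (``interaction_scale = 0.7``), entering the
pair hydropathy as the product of the two bead scales.

Internal units: nm, kJ/mol, K, g/mol, elementary charge.  Parameter values
are data, not code: they are read from tab-separated tables (see
:func:`load_bead_params`, :func:`load_cation_pi`); the tables shipped with
the package hold the published values of this model family.

All pair terms are truncated **and shifted** at their cutoff so the energy is
continuous there (forces inherit a small discontinuity of the untruncated
tail, negligible at 3.5σ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

# -- physical constants (CODATA), in internal units ---------------------------
KB = 0.008314462618          # Boltzmann constant, kJ/mol/K
COULOMB_K = 138.935458       # 1/(4 pi eps0), kJ nm / mol / e^2 (vacuum)
AVOGADRO_FACTOR = 602.214076  # (g/mol) / (nm^3) -> g/cm^3 divisor

CATION_RESIDUES = frozenset("RK")
AROMATIC_RESIDUES = frozenset("FWY")

DEFAULT_EPSILON = 0.8368          # AH energy scale, kJ/mol (0.2 kcal/mol)
DEFAULT_SHORT_CUTOFF_FACTOR = 3.5  # short-range cutoff, units of sigma_ij
DEFAULT_DH_CUTOFF = 3.5            # nm


class UnknownResidueError(KeyError):
    """A sequence code with no force-field parameter entry."""


@dataclass(frozen=True)
class BeadParams:
    """Per-residue / per-nucleotide force-field entry."""

    code: str
    mass: float            # g/mol
    charge: float          # e
    sigma: float           # nm
    lam: float             # hydropathy, dimensionless in [0, 1]
    interaction_scale: float = 1.0  # 0.7 for buried globular-domain residues

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda out of [0,1] for {self.code}: {self.lam}")
        if self.sigma <= 0 or self.mass <= 0:
            raise ValueError(f"non-positive sigma/mass for {self.code}")
        if not 0.0 < self.interaction_scale <= 1.0:
            raise ValueError(f"interaction_scale out of (0,1] for {self.code}")

    def buried(self, scale: float = 0.7) -> "BeadParams":
        """Copy of this entry with short-range interactions scaled down."""
        return BeadParams(self.code, self.mass, self.charge, self.sigma,
                          self.lam, self.interaction_scale * scale)


@dataclass(frozen=True)
class BondParams:
    """Harmonic bond, U = k (r - r0)^2 (or k/2 with ``half_prefactor``).

    The prefactor convention is configurable because both are in common use;
    whichever is chosen is recorded in run configs.
    """

    k: float                      # kJ/mol/nm^2
    r0: float                     # nm
    half_prefactor: bool = False

    def __post_init__(self) -> None:
        if self.k <= 0 or self.r0 <= 0:
            raise ValueError("bond k and r0 must be positive")

    @property
    def prefactor(self) -> float:
        return 0.5 * self.k if self.half_prefactor else self.k


DEFAULT_PROTEIN_BOND = BondParams(k=8033.0, r0=0.38)
DEFAULT_RNA_BOND = BondParams(k=8033.0, r0=0.50)


def debye_length(ionic_strength: float, temperature: float,
                 permittivity: float = 80.0) -> float:
    """Debye screening length in nm for a 1:1 salt.

    Parameters
    ----------
    ionic_strength : mM
    temperature : K
    permittivity : relative dielectric constant of the medium
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    bjerrum = COULOMB_K / (permittivity * KB * temperature)         # nm
    # ion number density for both species of a 1:1 salt, nm^-3
    n_ions = 2.0 * ionic_strength * 1e-3 * 0.602214076
    kappa_sq = 4.0 * np.pi * bjerrum * n_ions
    return float(1.0 / np.sqrt(kappa_sq))


@dataclass
class ElectrostaticsParams:
    """Screened-Coulomb parameters; the Debye length is derived, not set."""

    ionic_strength: float = 150.0    # mM
    temperature: float = 300.0       # K
    relative_permittivity: float = 80.0

    @property
    def debye_length(self) -> float:
        return debye_length(self.ionic_strength, self.temperature,
                            self.relative_permittivity)

    @property
    def coulomb_prefactor(self) -> float:
        """kJ nm/mol per unit-charge pair in this medium."""
        return COULOMB_K / self.relative_permittivity


# -- pair potentials ----------------------------------------------------------

def _lj(r, sigma, epsilon):
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def _lj_deriv(r, sigma, epsilon):
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r


def bond_energy(r, p: BondParams):
    """Harmonic bond energy, kJ/mol. Minimum 0 at r = r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    out = p.prefactor * (r - p.r0) ** 2
    return float(out) if out.ndim == 0 else out


def bond_force(r, p: BondParams):
    """-dU/dr of the harmonic bond."""
    r = np.asarray(r, dtype=float)
    out = -2.0 * p.prefactor * (r - p.r0)
    return float(out) if out.ndim == 0 else out


def ah_energy(r, sigma: float, lam: float, epsilon: float = DEFAULT_EPSILON,
              cutoff: float | None = None):
    """Ashbaugh-Hatch hydropathy-scaled LJ energy, kJ/mol.

    For r <= 2^(1/6) σ the potential is LJ(r) + (1-λ)ε (purely repulsive at
    λ=0); beyond the minimum it is λ·LJ(r). Continuous at the split point,
    truncated and shifted to 0 at ``cutoff`` (default 3.5σ).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    if cutoff is None:
        cutoff = DEFAULT_SHORT_CUTOFF_FACTOR * sigma
    rmin = 2.0 ** (1.0 / 6.0) * sigma
    shift = lam * _lj(cutoff, sigma, epsilon)
    lj = _lj(r, sigma, epsilon)
    inner = lj + (1.0 - lam) * epsilon
    outer = lam * lj
    out = np.where(r <= rmin, inner, outer) - shift
    out = np.where(r < cutoff, out, 0.0)
    return float(out) if out.ndim == 0 else out


def ah_force(r, sigma: float, lam: float, epsilon: float = DEFAULT_EPSILON,
             cutoff: float | None = None):
    """-dU/dr of :func:`ah_energy` (the shift does not change the force)."""
    r = np.asarray(r, dtype=float)
    if cutoff is None:
        cutoff = DEFAULT_SHORT_CUTOFF_FACTOR * sigma
    rmin = 2.0 ** (1.0 / 6.0) * sigma
    dlj = _lj_deriv(r, sigma, epsilon)
    out = -np.where(r <= rmin, dlj, lam * dlj)
    out = np.where(r < cutoff, out, 0.0)
    return float(out) if out.ndim == 0 else out


def dh_energy(r, qi: float, qj: float, ep: ElectrostaticsParams,
              cutoff: float = DEFAULT_DH_CUTOFF):
    """Debye-Hückel (Yukawa) screened-Coulomb energy, kJ/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    pref = qi * qj * ep.coulomb_prefactor
    lam_d = ep.debye_length
    out = pref * (np.exp(-r / lam_d) / r - np.exp(-cutoff / lam_d) / cutoff)
    out = np.where(r < cutoff, out, 0.0)
    return float(out) if out.ndim == 0 else out


def dh_force(r, qi: float, qj: float, ep: ElectrostaticsParams,
             cutoff: float = DEFAULT_DH_CUTOFF):
    """-dU/dr of :func:`dh_energy`."""
    r = np.asarray(r, dtype=float)
    pref = qi * qj * ep.coulomb_prefactor
    lam_d = ep.debye_length
    out = pref * np.exp(-r / lam_d) * (1.0 / r ** 2 + 1.0 / (lam_d * r))
    out = np.where(r < cutoff, out, 0.0)
    return float(out) if out.ndim == 0 else out


# -- interaction table --------------------------------------------------------

@dataclass
class InteractionTable:
    """Cached combining rules over the bead types of a system.

    σij and λij are arithmetic means; λij additionally carries the product of
    the two beads' ``interaction_scale`` (buried-residue scaling).  Cation-π
    well depths form their own symmetric matrix (zero for non-cation-π pairs).
    """

    codes: tuple[str, ...]
    pair_sigma: np.ndarray          # (n, n), nm
    pair_lambda: np.ndarray         # (n, n)
    cation_pi_eps: np.ndarray       # (n, n), kJ/mol; 0 where not applicable
    epsilon: float                  # AH energy scale, kJ/mol
    charge: np.ndarray              # (n,), e
    mass: np.ndarray                # (n,), g/mol
    short_cutoff_factor: float = DEFAULT_SHORT_CUTOFF_FACTOR
    dh_cutoff: float = DEFAULT_DH_CUTOFF
    index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {c: i for i, c in enumerate(self.codes)}
        n = len(self.codes)
        for name in ("pair_sigma", "pair_lambda", "cation_pi_eps"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} has wrong shape {m.shape}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} is not symmetric")
        if np.any(self.short_cutoff_factor * self.pair_sigma <= 0):
            raise ValueError("cutoffs must be positive")

    @property
    def max_short_cutoff(self) -> float:
        return float(self.short_cutoff_factor * self.pair_sigma.max())

    def max_cutoff(self, has_charges: bool = True) -> float:
        rc = self.max_short_cutoff
        if has_charges and np.any(self.charge != 0):
            rc = max(rc, self.dh_cutoff)
        return rc

    def type_indices(self, codes: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self.index[c] for c in codes], dtype=np.int64)
        except KeyError as err:
            raise UnknownResidueError(
                f"no force-field entry for code {err.args[0]!r}") from err

    def sigma_of(self, a: str, b: str) -> float:
        return float(self.pair_sigma[self.index[a], self.index[b]])

    def lambda_of(self, a: str, b: str) -> float:
        return float(self.pair_lambda[self.index[a], self.index[b]])


def cation_pi_energy(r, pair: tuple[str, str], table: InteractionTable,
                     cutoff: float | None = None):
    """Extra LJ energy for cation-π pairs; exactly 0 for all other pairs."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    a, b = pair
    eps = float(table.cation_pi_eps[table.index[a], table.index[b]])
    if eps == 0.0:
        out = np.zeros_like(r)
        return float(out) if out.ndim == 0 else out
    sigma = table.sigma_of(a, b)
    if cutoff is None:
        cutoff = table.short_cutoff_factor * sigma
    out = _lj(r, sigma, eps) - _lj(cutoff, sigma, eps)
    out = np.where(r < cutoff, out, 0.0)
    return float(out) if out.ndim == 0 else out


def cation_pi_force(r, pair: tuple[str, str], table: InteractionTable,
                    cutoff: float | None = None):
    """-dU/dr of :func:`cation_pi_energy`."""
    r = np.asarray(r, dtype=float)
    a, b = pair
    eps = float(table.cation_pi_eps[table.index[a], table.index[b]])
    if eps == 0.0:
        out = np.zeros_like(r)
        return float(out) if out.ndim == 0 else out
    sigma = table.sigma_of(a, b)
    if cutoff is None:
        cutoff = table.short_cutoff_factor * sigma
    out = -_lj_deriv(r, sigma, eps)
    out = np.where(r < cutoff, out, 0.0)
    return float(out) if out.ndim == 0 else out


def build_interaction_table(
    params: Iterable[BeadParams],
    epsilon: float = DEFAULT_EPSILON,
    cation_pi_pairs: Mapping[tuple[str, str], float] | None = None,
    short_cutoff_factor: float = DEFAULT_SHORT_CUTOFF_FACTOR,
    dh_cutoff: float = DEFAULT_DH_CUTOFF,
) -> InteractionTable:
    """Apply combining rules once and cache them as an :class:`InteractionTable`.

    ``cation_pi_pairs`` maps (cation, aromatic) residue pairs to their LJ well
    depths; pairs must be (R,K) x (F,W,Y).  ``None`` loads the packaged table.
    """
    params = list(params)
    codes = tuple(p.code for p in params)
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate bead codes")
    sig = np.array([p.sigma for p in params])
    lam = np.array([p.lam for p in params])
    scale = np.array([p.interaction_scale for p in params])
    pair_sigma = 0.5 * (sig[:, None] + sig[None, :])
    pair_lambda = 0.5 * (lam[:, None] + lam[None, :]) * (scale[:, None] * scale[None, :])

    if cation_pi_pairs is None:
        cation_pi_pairs = load_cation_pi()
    index = {c: i for i, c in enumerate(codes)}
    cp = np.zeros_like(pair_sigma)
    for (a, b), well in cation_pi_pairs.items():
        pair = {a, b}
        if not (pair & CATION_RESIDUES and pair & AROMATIC_RESIDUES):
            raise ValueError(f"invalid cation-pi pair {(a, b)}")
        if a in index and b in index:
            cp[index[a], index[b]] = well
            cp[index[b], index[a]] = well

    return InteractionTable(
        codes=codes, pair_sigma=pair_sigma, pair_lambda=pair_lambda,
        cation_pi_eps=cp, epsilon=epsilon,
        charge=np.array([p.charge for p in params]),
        mass=np.array([p.mass for p in params]),
        short_cutoff_factor=short_cutoff_factor, dh_cutoff=dh_cutoff,
    )


# -- parameter table I/O ------------------------------------------------------

def _data_path(name: str):
    return resources.files("llpsmd.data").joinpath(name)


def load_bead_params(path=None) -> dict[str, BeadParams]:
    """Read a TSV parameter table: code, mass, charge, sigma, lambda.

    Lines starting with '#' are comments. ``path=None`` loads the packaged
    amino-acid table.
    """
    if path is None:
        path = _data_path("aa_params.tsv")
    out: dict[str, BeadParams] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, mass, charge, sigma, lam = line.split("\t")
            out[code] = BeadParams(code, float(mass), float(charge),
                                   float(sigma), float(lam))
    if not out:
        raise ValueError(f"empty parameter table: {path}")
    return out


def load_rna_params(path=None) -> dict[str, BeadParams]:
    """RNA bead table (one bead per nucleotide, charge -1 e for uridine)."""
    if path is None:
        path = _data_path("rna_params.tsv")
    return load_bead_params(path)


def load_cation_pi(path=None) -> dict[tuple[str, str], float]:
    """Read the cation-π pair table: res_i, res_j, epsilon [kJ/mol]."""
    if path is None:
        path = _data_path("cation_pi.tsv")
    out: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, eps = line.split("\t")
            out[(a, b)] = float(eps)
    return out


def default_params(include_rna: bool = True) -> dict[str, BeadParams]:
    """Packaged amino-acid (+ RNA) parameter set, keyed by one-letter code."""
    params = load_bead_params()
    if include_rna:
        params.update(load_rna_params())
    return params
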