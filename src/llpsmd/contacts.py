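"""Residue-residue and protein-RNA contact statistics.

A pair of beads on different chains is "in contact" in a frame when their
minimum-image distance is at or below a pair-specific cutoff adapted to the
range of the hydropathy-scale potential: cutoff_ij = scale × 2^(1/6) σ_ij
(scale 1.2 by default, covering the attractive well).  Boundary distances
exactly equal to the cutoff count as contacts.

Two complementary views are produced: position-resolved maps (averaged over
chain replicas and frames, reported as percentages) and residue-type pair
counts, optionally renormalized by amino-acid abundance so that rare but
strongly interacting pairs (e.g. R-Y cation-π) can be ranked fairly against
abundant ones (e.g. G-G).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .forcefield import InteractionTable
from .sequences import Domain
from .simulator import Trajectory, ChainTopology


def contact_cutoffs(table: InteractionTable, scale: float = 1.2) -> np.ndarray:
    """Per-type-pair contact cutoffs, scale × 2^(1/6) σij (nm)."""
    if scale <= 0:
        raise ValueError("cutoff scale must be positive")
    return scale * 2.0 ** (1.0 / 6.0) * table.pair_sigma


@dataclass
class ContactMap:
    """Position-resolved intermolecular contact frequencies for one protein
    species, as the percentage of (frame, chain-pair) observations in which
    the position pair is in contact. Optional right-edge vector holds the
    average number of RNA-bead contacts per protein position per replica."""

    labels: np.ndarray              # residue positions, 1-based
    freq: np.ndarray                # (n, n) percentages, symmetric
    frames_used: int
    species: str
    rna_freq: np.ndarray | None = None   # (n,) mean RNA contacts per replica
    rna_species: str | None = None

    def __post_init__(self) -> None:
        if np.any(self.freq < 0) or np.any(self.freq > 100 + 1e-9):
            raise ValueError("frequencies must lie in [0, 100]")
        if not np.allclose(self.freq, self.freq.T):
            raise ValueError("contact map must be symmetric")

    @property
    def total(self) -> float:
        return float(self.freq.sum())


@dataclass
class ContactRanking:
    """Residue-type pairs ordered by raw or abundance-normalized frequency;
    ties broken lexicographically by pair label."""

    entries: list                   # (pair_label, raw, normalized)
    key: str = "raw"

    def pairs(self) -> list:
        return [e[0] for e in self.entries]


def _frame_contact_pairs(pos, box, tidx, cutoffs, bonds, n):
    """Bead index pairs in contact (closed interval) in one frame."""
    wrapped = np.mod(pos, box)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(float(cutoffs.max()) * (1 + 1e-12),
                             output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]]
    d -= box * np.rint(d / box)
    r = np.sqrt((d * d).sum(axis=1))
    keep = r <= cutoffs[tidx[pairs[:, 0]], tidx[pairs[:, 1]]]
    pairs = pairs[keep]
    if len(bonds):
        bond_keys = bonds[:, 0].astype(np.int64) * n + bonds[:, 1]
        bond_keys = np.concatenate([bond_keys,
                                    bonds[:, 1].astype(np.int64) * n + bonds[:, 0]])
        keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
        pairs = pairs[~np.isin(keys, bond_keys)]
    return pairs


def _positions_in_chain(topo: ChainTopology) -> np.ndarray:
    pos = np.empty(topo.n_beads, dtype=np.int64)
    for a, b in topo.chain_slices:
        pos[a:b] = np.arange(b - a)
    return pos


def contact_map(
    traj: Trajectory,
    cutoffs: np.ndarray,
    species: str | None = None,
    intermolecular_only: bool = True,
    rna_species: str | None = None,
) -> ContactMap:
    """Position-by-position contact frequencies for one protein species.

    freq[i, j] = 100 × P(contact between position i on one chain and position
    j on another), averaged over frames and all ordered chain pairs of the
    species (unordered for i == j), so co-located chains give 100 and values
    never exceed 100.  With ``intermolecular_only=False`` non-bonded
    intramolecular contacts are added, normalized per chain.
    """
    topo = traj.topology
    if topo is None:
        raise ValueError("trajectory carries no topology")
    if traj.n_frames == 0:
        raise ValueError("no frames")
    if species is None:
        species = topo.chain_species[0]
    chains = topo.chains_of_species(species)
    if len(chains) < 2:
        raise ValueError(f"need >= 2 chains of species {species!r}")
    npc = len(chains)
    chain_set = np.zeros(topo.n_chains, dtype=bool)
    chain_set[chains] = True
    a0, b0 = topo.chain_slices[chains[0]]
    nres = b0 - a0
    pos_in_chain = _positions_in_chain(topo)

    rna_chains = None
    if rna_species is not None:
        rna_chains = np.zeros(topo.n_chains, dtype=bool)
        rna_chains[topo.chains_of_species(rna_species)] = True
        n_rna = int(np.sum(rna_chains))
        if n_rna == 0:
            raise ValueError(f"no chains of species {rna_species!r}")

    counts = np.zeros((nres, nres))
    intra_counts = np.zeros((nres, nres))
    rna_counts = np.zeros(nres)
    for f in range(traj.n_frames):
        pairs = _frame_contact_pairs(traj.positions[f], traj.box,
                                     topo.type_index, cutoffs, topo.bonds,
                                     topo.n_beads)
        if len(pairs) == 0:
            continue
        ci = topo.chain_id[pairs[:, 0]]
        cj = topo.chain_id[pairs[:, 1]]
        pi = pos_in_chain[pairs[:, 0]]
        pj = pos_in_chain[pairs[:, 1]]
        both = chain_set[ci] & chain_set[cj]
        inter = both & (ci != cj)
        np.add.at(counts, (pi[inter], pj[inter]), 1.0)
        np.add.at(counts, (pj[inter], pi[inter]), 1.0)
        if not intermolecular_only:
            intra = both & (ci == cj)
            np.add.at(intra_counts, (pi[intra], pj[intra]), 1.0)
            np.add.at(intra_counts, (pj[intra], pi[intra]), 1.0)
        if rna_chains is not None:
            pr = chain_set[ci] & rna_chains[cj]
            rp = rna_chains[ci] & chain_set[cj]
            np.add.at(rna_counts, pi[pr], 1.0)
            np.add.at(rna_counts, pj[rp], 1.0)

    # counts were double-accumulated (both orientations): diagonal got 2 per
    # observation, off-diagonal 1 per ordered observation.
    n_ordered = npc * (npc - 1)
    freq = counts / (traj.n_frames * n_ordered) * 100.0
    np.fill_diagonal(freq, np.diag(counts) / 2.0
                     / (traj.n_frames * n_ordered / 2) * 100.0)
    if not intermolecular_only:
        ifreq = intra_counts / (traj.n_frames * npc) * 100.0
        np.fill_diagonal(ifreq, 0.0)
        freq = np.clip(freq + ifreq, 0.0, 100.0)
    rna_freq = None
    if rna_chains is not None:
        rna_freq = rna_counts / (traj.n_frames * npc)
    return ContactMap(labels=np.arange(1, nres + 1), freq=freq,
                      frames_used=traj.n_frames, species=species,
                      rna_freq=rna_freq, rna_species=rna_species)


def type_contact_counts(
    traj: Trajectory,
    cutoffs: np.ndarray,
    intermolecular_only: bool = True,
) -> dict:
    """Frame-averaged counts of contacts by unordered residue-type pair,
    per protein replica (all species pooled)."""
    topo = traj.topology
    if traj.n_frames == 0:
        raise ValueError("no frames")
    codes = np.array(topo.codes)
    out: dict[tuple[str, str], float] = {}
    for f in range(traj.n_frames):
        pairs = _frame_contact_pairs(traj.positions[f], traj.box,
                                     topo.type_index, cutoffs, topo.bonds,
                                     topo.n_beads)
        if len(pairs) == 0:
            continue
        if intermolecular_only:
            pairs = pairs[topo.chain_id[pairs[:, 0]]
                          != topo.chain_id[pairs[:, 1]]]
        for a, b in zip(codes[pairs[:, 0]], codes[pairs[:, 1]]):
            key = (a, b) if a <= b else (b, a)
            out[key] = out.get(key, 0.0) + 1.0
    n_norm = traj.n_frames * max(topo.n_chains, 1)
    return {k: v / n_norm for k, v in sorted(out.items())}


def normalize_by_abundance(counts: dict, composition: dict) -> dict:
    """normalized(a,b) = raw(a,b) / (f_a f_b (2 - δ_ab)).

    The denominator is the relative number of (a, b) pairs available, so the
    normalized value is a per-pair contact propensity; its relative ordering
    does not depend on the overall scale of the counts.
    """
    out = {}
    for (a, b), raw in counts.items():
        fa = composition.get(a, 0.0)
        fb = composition.get(b, 0.0)
        if fa == 0.0 or fb == 0.0:
            if raw > 0:
                raise ValueError(f"zero abundance for pair {(a, b)} with "
                                 f"nonzero count {raw}")
            continue
        delta = 1.0 if a == b else 0.0
        out[(a, b)] = raw / (fa * fb * (2.0 - delta))
    return out


def top_contacts(counts: dict, k: int, key: str = "raw",
                 composition: dict | None = None) -> ContactRanking:
    """Top-k residue-type pairs by raw or abundance-normalized frequency."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if key not in ("raw", "normalized"):
        raise ValueError("key must be 'raw' or 'normalized'")
    normalized = (normalize_by_abundance(counts, composition)
                  if composition is not None else {})
    entries = []
    for pair, raw in counts.items():
        entries.append(("-".join(pair), float(raw),
                        float(normalized.get(pair, np.nan))))
    col = 1 if key == "raw" else 2
    entries.sort(key=lambda e: (-e[col], e[0]))
    return ContactRanking(entries=entries[:k], key=key)


def domain_aggregate(cmap: ContactMap, domains) -> pd.DataFrame:
    """Block sums of the position map over domain intervals.

    Positions not covered by any interval go into an ``other`` block; the
    grand total of the blocks equals the sum of the map. Overlapping
    intervals are an error.
    """
    n = len(cmap.labels)
    assignment = np.full(n, -1, dtype=int)
    names = []
    for k, d in enumerate(domains):
        label = d.label if isinstance(d, Domain) else d[0]
        start, end = (d.start, d.end) if isinstance(d, Domain) else (d[1], d[2])
        if end > n or start < 1:
            raise ValueError(f"domain {label} {start}-{end} outside map 1-{n}")
        if np.any(assignment[start - 1:end] >= 0):
            raise ValueError(f"overlapping domain intervals at {label}")
        assignment[start - 1:end] = k
        names.append(f"{label}({start}-{end})")
    if np.any(assignment < 0):
        names.append("other")
        assignment[assignment < 0] = len(names) - 1
    nb = len(names)
    blocks = np.zeros((nb, nb))
    np.add.at(blocks, (assignment[:, None] * np.ones(n, dtype=int),
                       np.ones(n, dtype=int)[:, None] * assignment), cmap.freq)
    return pd.DataFrame(blocks, index=names, columns=names)


def contacts_per_protein(
    traj: Trajectory,
    cutoffs: np.ndarray,
    protein_species: list | None = None,
    rna_species: list | None = None,
) -> dict:
    """Frame-averaged contact counts per protein replica, by partner class.

    Returns {'protein_protein', 'protein_rna', 'rna_rna', 'total'};
    total = protein_protein + protein_rna (classes involving proteins).
    Protein-protein contacts count twice per contact (once for each protein
    involved), matching a per-replica bookkeeping.
    """
    topo = traj.topology
    if protein_species is None:
        protein_species = [s for s in dict.fromkeys(topo.chain_species)
                           if not s.startswith("polyU")]
    if rna_species is None:
        rna_species = [s for s in dict.fromkeys(topo.chain_species)
                       if s.startswith("polyU")]
    is_protein_chain = np.zeros(topo.n_chains, dtype=bool)
    for s in protein_species:
        is_protein_chain[topo.chains_of_species(s)] = True
    is_rna_chain = np.zeros(topo.n_chains, dtype=bool)
    for s in rna_species:
        is_rna_chain[topo.chains_of_species(s)] = True
    npc = int(np.sum(is_protein_chain))
    if npc == 0:
        raise ValueError("no protein chains")

    pp = pr = rr = 0.0
    for f in range(traj.n_frames):
        pairs = _frame_contact_pairs(traj.positions[f], traj.box,
                                     topo.type_index, cutoffs, topo.bonds,
                                     topo.n_beads)
        if len(pairs) == 0:
            continue
        ci = topo.chain_id[pairs[:, 0]]
        cj = topo.chain_id[pairs[:, 1]]
        inter = ci != cj
        ci, cj = ci[inter], cj[inter]
        pi_p = is_protein_chain[ci]
        pj_p = is_protein_chain[cj]
        pi_r = is_rna_chain[ci]
        pj_r = is_rna_chain[cj]
        pp += float(np.sum(pi_p & pj_p))
        pr += float(np.sum((pi_p & pj_r) | (pi_r & pj_p)))
        rr += float(np.sum(pi_r & pj_r))
    norm = traj.n_frames * npc
    out = {"protein_protein": 2.0 * pp / norm, "protein_rna": pr / norm,
           "rna_rna": rr / norm}
    out["total"] = out["protein_protein"] + out["protein_rna"]
    return out
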