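"""Sequence and domain bookkeeping for proteins and poly-U RNA.

FASTA I/O goes through Biopython. Domain annotations are 1-based inclusive
intervals (the convention used when quoting residue ranges such as 186-251),
read from tab-separated files with columns
``seq_id  label  start  end  buried_flag``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .forcefield import BeadParams, UnknownResidueError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
DOMAIN_LABELS = {"PLD", "RGG", "RRM1", "RRM2", "ZF", "NTD", "NLS", "LCD", "other"}


@dataclass(frozen=True)
class Domain:
    """Annotated interval of a protein sequence, 1-based inclusive."""

    label: str
    start: int
    end: int
    buried: bool = False  # rigid/structured region (RRMs, ZF, helices)

    def __post_init__(self) -> None:
        if self.label not in DOMAIN_LABELS:
            raise ValueError(f"unknown domain label {self.label!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def slice(self) -> slice:
        """0-based half-open python slice for this interval."""
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str
    domains: tuple[Domain, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"illegal residue codes in {self.id}: {sorted(bad)}")
        if not self.residues:
            raise ValueError(f"empty sequence {self.id}")
        for d in self.domains:
            if d.end > len(self.residues):
                raise ValueError(
                    f"domain {d.label} {d.start}-{d.end} outside 1-{len(self.residues)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def structured_regions(self) -> tuple[Domain, ...]:
        return tuple(d for d in self.domains if d.buried)

    def domain(self, label: str) -> Domain:
        for d in self.domains:
            if d.label == label:
                return d
        raise KeyError(f"{self.id} has no domain {label!r}")

    def extract(self, *intervals: tuple[int, int], id: str | None = None
                ) -> "ProteinSequence":
        """Concatenate 1-based inclusive intervals into a new sequence."""
        parts = []
        for start, end in intervals:
            if start < 1 or end > len(self) or end < start:
                raise ValueError(f"interval {start}-{end} outside 1-{len(self)}")
            parts.append(self.residues[start - 1:end])
        return ProteinSequence(id or f"{self.id}_fragment", "".join(parts))

    def extract_domain(self, label: str) -> "ProteinSequence":
        d = self.domain(label)
        return self.extract((d.start, d.end), id=f"{self.id}-{label}")


@dataclass(frozen=True)
class RNASequence:
    """Homopolymeric single-stranded RNA, one bead per nucleotide."""

    id: str
    length: int
    code: str = "U"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("RNA length must be >= 1")

    def __len__(self) -> int:
        return self.length

    @property
    def residues(self) -> str:
        return self.code * self.length


def make_polyU(n: int, id: str | None = None) -> RNASequence:
    """Poly-uridine strand of ``n`` nucleotides (charge -1 e per bead)."""
    return RNASequence(id or f"polyU{n}", int(n))


# -- I/O ----------------------------------------------------------------------

def read_fasta(path) -> list[ProteinSequence]:
    """Read protein sequences, preserving order; codes are uppercased and
    validated against the 20 standard one-letter amino-acid codes."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(seqs, path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_domains(path) -> dict[str, tuple[Domain, ...]]:
    """Read a domain annotation TSV: seq_id, label, start, end, buried_flag."""
    out: dict[str, list[Domain]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, label, start, end, buried = line.split("\t")
            out.setdefault(seq_id, []).append(
                Domain(label, int(start), int(end), buried.lower() in ("1", "true", "yes")))
    return {k: tuple(v) for k, v in out.items()}


def attach_domains(seqs, domains) -> list[ProteinSequence]:
    return [replace(s, domains=domains.get(s.id, ())) for s in seqs]


def load_reference_proteins() -> dict[str, ProteinSequence]:
    """The packaged FUS, hnRNPA1 (isoform A1-B) and TDP-43 sequences with
    their domain annotations."""
    data = resources.files("llpsmd.data")
    seqs = read_fasta(data.joinpath("proteins.fasta"))
    doms = read_domains(data.joinpath("domains.tsv"))
    return {s.id: s for s in attach_domains(seqs, doms)}


def hnrnpa1_a_lcd(hnrnpa1: ProteinSequence) -> ProteinSequence:
    """The low-complexity domain of hnRNPA1 isoform A1-A, assembled from the
    two segments it shares with isoform A1-B (residues 186-251 and 304-372
    in A1-B numbering)."""
    return hnrnpa1.extract((186, 251), (304, 372), id="hnRNPA1-A-LCD")


# -- composition & charge arithmetic -----------------------------------------

def composition(seq) -> dict[str, float]:
    """Residue-type fractions (sum to 1). Permutation-invariant."""
    residues = seq.residues
    if not residues:
        raise ValueError("empty sequence")
    n = len(residues)
    out: dict[str, float] = {}
    for c in residues:
        out[c] = out.get(c, 0.0) + 1.0
    return {c: k / n for c, k in sorted(out.items())}


def _lookup(params: dict[str, BeadParams], code: str) -> BeadParams:
    try:
        return params[code]
    except KeyError:
        raise UnknownResidueError(f"no parameter entry for code {code!r}")


def net_charge(seq, params: dict[str, BeadParams]) -> float:
    """Sum of per-bead charges, in e."""
    return float(sum(_lookup(params, c).charge for c in seq.residues))


def chain_mass(seq, params: dict[str, BeadParams]) -> float:
    """Sum of bead masses, g/mol."""
    return float(sum(_lookup(params, c).mass for c in seq.residues))


class NoElectroneutralPoint(ValueError):
    """The protein carries no net positive charge to balance RNA."""


def electroneutral_mass_ratio(protein: ProteinSequence, rna: RNASequence,
                              params: dict[str, BeadParams]) -> float:
    """RNA/protein mass ratio (mg RNA per mg protein) at which the mixture is
    electroneutral.

    ratio = (Q_protein * m_nucleotide) / (|q_nucleotide| * M_protein); the
    result is independent of the RNA strand length because RNA charge per
    unit mass is length-free.
    """
    q_protein = net_charge(protein, params)
    if q_protein <= 0:
        raise NoElectroneutralPoint(
            f"{protein.id} has net charge {q_protein:+.0f} e; "
            "no RNA amount can neutralize it")
    nuc = _lookup(params, rna.code)
    if nuc.charge >= 0:
        raise ValueError("RNA bead must carry negative charge")
    return q_protein * nuc.mass / (abs(nuc.charge) * chain_mass(protein, params))
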