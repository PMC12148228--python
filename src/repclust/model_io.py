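"""Domain types and file IO for the repertoire-clustering pipeline.

All coordinates and intervals are 0-based, half-open. AIRR Rearrangement
fields (1-based, closed) are converted at the read/write boundary.

The central container is :class:`AntibodyRecord`: one antibody with its
heavy-chain amino-acid sequence, optional light chain and nucleotide
sequence, per-chain region boundaries (FR1..FR4, CDR1..CDR3), germline
V/J gene calls and provenance (curated vs simulated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "REGION_ORDER",
    "AntibodyRecord",
    "EpitopeAnnotation",
    "AntibodyPair",
    "ReferenceGene",
    "SubstitutionModel",
    "ClusterAssignment",
    "BackboneModel",
    "FormatError",
    "read_airr",
    "write_airr",
    "read_fasta",
    "write_fasta",
    "read_reference_fasta",
    "write_reference_fasta",
    "read_pair_table",
    "write_pair_table",
    "read_epitope_table",
    "write_epitope_table",
    "read_fivemer_table",
    "write_fivemer_table",
    "read_backbone_pdb",
    "write_backbone_pdb",
    "translate_nt",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

#: canonical ordering of variable-domain regions along a chain
REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def translate_nt(nt: str) -> str:
    """Translate a nucleotide string in frame 0 (length must be 3n)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"nucleotide length {len(nt)} is not a multiple of 3")
    return str(Seq(nt).translate())


def _check_aa(seq: str, what: str) -> None:
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"{what} contains non-standard letters: {sorted(bad)}")


def _check_nt(seq: str, what: str) -> None:
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"{what} contains non-ACGT letters: {sorted(bad)}")


def _check_regions(regions: Mapping[str, tuple[int, int]], seq_len: int, chain: str) -> None:
    prev_end = 0
    prev_name = None
    for name in REGION_ORDER:
        if name not in regions:
            continue
        start, end = regions[name]
        if not (0 <= start < end <= seq_len):
            raise ValueError(
                f"{chain} region {name} interval ({start},{end}) out of bounds for length {seq_len}"
            )
        if start < prev_end:
            raise ValueError(
                f"{chain} region {name} overlaps or precedes {prev_name}"
            )
        prev_end = end
        prev_name = name
    extra = set(regions) - set(REGION_ORDER)
    if extra:
        raise ValueError(f"unknown region names: {sorted(extra)}")


@dataclass(frozen=True)
class AntibodyRecord:
    """One antibody: sequences, region boundaries, gene calls, provenance.

    ``regions`` maps chain name ("heavy"/"light") to a map of region name
    (FR1..FR4, CDR1..CDR3) to half-open (start, end) over the amino-acid
    sequence of that chain.
    """

    antibody_id: str
    heavy_aa: str
    light_aa: str | None = None
    heavy_nt: str | None = None
    regions: Mapping[str, Mapping[str, tuple[int, int]]] = field(default_factory=dict)
    v_call: str | None = None
    j_call: str | None = None
    source: str = "curated"  # {curated, simulated}
    shm_rate: float | None = None

    def __post_init__(self):
        if not self.antibody_id:
            raise ValueError("antibody_id must be non-empty")
        _check_aa(self.heavy_aa, f"{self.antibody_id} heavy_aa")
        if self.light_aa is not None:
            _check_aa(self.light_aa, f"{self.antibody_id} light_aa")
        if self.heavy_nt is not None:
            _check_nt(self.heavy_nt, f"{self.antibody_id} heavy_nt")
            if translate_nt(self.heavy_nt) != self.heavy_aa:
                raise ValueError(
                    f"{self.antibody_id}: heavy_nt does not translate to heavy_aa in frame 0"
                )
        if self.source not in ("curated", "simulated"):
            raise ValueError(f"source must be curated|simulated, got {self.source!r}")
        if self.shm_rate is not None and not (0.0 <= self.shm_rate <= 1.0):
            raise ValueError(f"shm_rate {self.shm_rate} outside [0,1]")
        for chain, regmap in self.regions.items():
            if chain not in ("heavy", "light"):
                raise ValueError(f"unknown chain {chain!r}")
            seq = self.heavy_aa if chain == "heavy" else self.light_aa
            if seq is None:
                raise ValueError(f"regions given for absent {chain} chain")
            _check_regions(regmap, len(seq), chain)

    def region_seq(self, chain: str, region: str) -> str:
        """Amino-acid subsequence of a region (e.g. heavy CDR3 = CDRH3)."""
        start, end = self.regions[chain][region]
        seq = self.heavy_aa if chain == "heavy" else self.light_aa
        return seq[start:end]

    @property
    def cdrh3(self) -> str:
        return self.region_seq("heavy", "CDR3")

    def cdr_lengths(self) -> tuple[int, ...]:
        """(H1, H2, H3, L1, L2, L3) CDR amino-acid lengths; light lengths
        are 0 when the light chain or its boundaries are absent."""
        out = []
        for chain in ("heavy", "light"):
            for cdr in ("CDR1", "CDR2", "CDR3"):
                regmap = self.regions.get(chain, {})
                if cdr in regmap:
                    s, e = regmap[cdr]
                    out.append(e - s)
                else:
                    out.append(0)
        return tuple(out)

    def with_(self, **kwargs) -> "AntibodyRecord":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EpitopeAnnotation:
    """The antigen-residue set bound by one antibody, with assay metadata."""

    antibody_id: str
    antigen_id: str
    residues: frozenset[tuple[str, int]]
    assay_positive: bool = True
    structure_method: str = "xray"  # {xray, other}
    species: str = "human"
    scfv: bool = False
    chains_assigned: bool = True

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.antibody_id}: residue set must be non-empty")
        for chain, idx in self.residues:
            if not (isinstance(idx, (int, np.integer)) and idx > 0):
                raise ValueError(f"{self.antibody_id}: residue index {idx!r} not a positive integer")
        if self.structure_method not in ("xray", "other"):
            raise ValueError(f"structure_method must be xray|other, got {self.structure_method!r}")


@dataclass(frozen=True)
class AntibodyPair:
    """A curated functionally similar pair, canonically ordered id_a < id_b."""

    id_a: str
    id_b: str
    jaccard: float
    cdrh3_identity: float
    same_cdr_lengths: bool

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError(f"pair members must differ: {self.id_a}")
        if self.id_a > self.id_b:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)
        for name in ("jaccard", "cdrh3_identity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0,1]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass(frozen=True)
class ReferenceGene:
    """A germline V or J gene segment (nucleotide) with reading-frame offset."""

    name: str
    segment: str  # {V, J}
    nt_seq: str
    frame: int = 0

    def __post_init__(self):
        if self.segment not in ("V", "J"):
            raise ValueError(f"segment must be V|J, got {self.segment!r}")
        _check_nt(self.nt_seq, f"{self.name} nt_seq")
        if len(self.nt_seq) < 3:
            raise ValueError(f"{self.name}: nt_seq shorter than one codon")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0..2, got {self.frame}")
        if "*" in self.translation:
            raise ValueError(f"{self.name}: internal stop codon in translation")

    @property
    def coding_nt(self) -> str:
        """In-frame portion, trimmed to whole codons."""
        nt = self.nt_seq[self.frame :]
        return nt[: len(nt) - len(nt) % 3]

    @property
    def translation(self) -> str:
        return translate_nt(self.coding_nt)


@dataclass
class SubstitutionModel:
    """Context-dependent nucleotide substitution likelihoods.

    A fivemer model scores substitution of the central base of a 5-mer
    context; its table is keyed ``("center", fivemer, target_base)``.
    A trimer model (obtained by aggregation) scores the start, center or
    end base of a 3-mer, keyed ``(position, trimer, target_base)``, and
    carries the standard deviation of the fivemer values it averaged.
    """

    context_len: int
    table: dict[tuple[str, str, str], float]
    dispersion: dict[tuple[str, str, str], float] = field(default_factory=dict)

    POSITIONS = ("start", "center", "end")

    def __post_init__(self):
        if self.context_len not in (3, 5):
            raise ValueError(f"context_len must be 3 or 5, got {self.context_len}")
        for (pos, ctx, target), lik in self.table.items():
            if pos not in self.POSITIONS:
                raise ValueError(f"unknown position {pos!r}")
            if len(ctx) != self.context_len:
                raise ValueError(f"context {ctx!r} has wrong length for context_len={self.context_len}")
            if not (math.isfinite(lik) and lik >= 0):
                raise ValueError(f"likelihood for {(pos, ctx, target)} must be finite and >= 0")

    def likelihood(self, position: str, context: str, target: str) -> float:
        key = (position, context, target)
        if key not in self.table:
            raise KeyError(f"missing substitution-model entry {key}")
        return self.table[key]


@dataclass
class ClusterAssignment:
    """antibody_id -> cluster id map plus method/settings provenance.

    Antibodies absent from ``assignment`` are unclustered.
    """

    method: str
    settings: dict
    assignment: dict[str, int]

    @property
    def sizes(self) -> list[int]:
        """Histogram of cluster sizes (sorted descending)."""
        counts: dict[int, int] = {}
        for cid in self.assignment.values():
            counts[cid] = counts.get(cid, 0) + 1
        return sorted(counts.values(), reverse=True)

    @property
    def n_clustered(self) -> int:
        return len(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for aid, cid in self.assignment.items():
            out.setdefault(cid, []).append(aid)
        return out

    def co_clustered(self, id_a: str, id_b: str) -> bool:
        a = self.assignment.get(id_a)
        return a is not None and a == self.assignment.get(id_b)


DEFAULT_BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class BackboneModel:
    """Backbone coordinates of one antibody model, region-labelled.

    ``atoms`` is an ordered list of (region label, residue index, atom
    name, xyz) with xyz in Ångström. Region labels are "H:FR1" .. "L:CDR3"
    (chain prefix + region name).
    """

    antibody_id: str
    atoms: list[tuple[str, int, str, np.ndarray]]
    backbone_atoms: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS

    def __post_init__(self):
        for region, _res, _atom, xyz in self.atoms:
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"{self.antibody_id}: non-finite coordinate in {region}")

    def coords(self, *, cdr: bool | None = None) -> np.ndarray:
        """(n, 3) coordinate array; cdr=True selects CDR atoms, False
        framework atoms, None all atoms."""
        rows = []
        for region, _res, atom, xyz in self.atoms:
            if atom not in self.backbone_atoms:
                continue
            is_cdr = "CDR" in region
            if cdr is None or is_cdr == cdr:
                rows.append(xyz)
        return np.array(rows, dtype=float).reshape(-1, 3)

    def cdr_length_class(self) -> tuple[int, ...]:
        """Residue counts per CDR region, (H1,H2,H3,L1,L2,L3) order."""
        seen: dict[str, set[int]] = {}
        for region, res, _atom, _xyz in self.atoms:
            if "CDR" in region:
                seen.setdefault(region, set()).add(res)
        out = []
        for chain in "HL":
            for i in "123":
                out.append(len(seen.get(f"{chain}:CDR{i}", ())))
        return tuple(out)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneModel":
        atoms = [
            (region, res, atom, rotation @ xyz + translation)
            for region, res, atom, xyz in self.atoms
        ]
        return BackboneModel(self.antibody_id, atoms, self.backbone_atoms)


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV

_AIRR_MANDATORY = ("sequence", "v_call", "j_call", "junction_aa")

# AIRR-style region boundary fields, interpreted here over the amino-acid
# sequence (1-based, closed; converted to 0-based half-open on read)
_AIRR_REGION_FIELDS = {
    "FR1": ("fwr1_start", "fwr1_end"),
    "CDR1": ("cdr1_start", "cdr1_end"),
    "FR2": ("fwr2_start", "fwr2_end"),
    "CDR2": ("cdr2_start", "cdr2_end"),
    "FR3": ("fwr3_start", "fwr3_end"),
    "CDR3": ("cdr3_start", "cdr3_end"),
    "FR4": ("fwr4_start", "fwr4_end"),
}


def read_airr(path: str | Path) -> list[AntibodyRecord]:
    """Read an AIRR Rearrangement TSV into :class:`AntibodyRecord` objects.

    Requires the mandatory columns sequence, v_call, j_call, junction_aa.
    Heavy-chain region boundaries are taken from the AIRR boundary fields
    when present, else left unset.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _AIRR_MANDATORY:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory AIRR column '{col}'")
    records = []
    for i, row in df.iterrows():
        nt = row["sequence"].strip().upper()
        aa = row.get("sequence_aa", "") or (translate_nt(nt) if nt else "")
        regions: dict[str, dict[str, tuple[int, int]]] = {}
        heavy_regs = {}
        for region, (cs, ce) in _AIRR_REGION_FIELDS.items():
            if cs in df.columns and ce in df.columns and row[cs] and row[ce]:
                heavy_regs[region] = (int(row[cs]) - 1, int(row[ce]))
        if heavy_regs:
            regions["heavy"] = heavy_regs
        light_aa = row.get("light_sequence_aa", "") or None
        shm = row.get("shm_rate", "")
        records.append(
            AntibodyRecord(
                antibody_id=row.get("sequence_id", "") or f"row{i}",
                heavy_aa=aa,
                light_aa=light_aa,
                heavy_nt=nt or None,
                regions=regions,
                v_call=row["v_call"] or None,
                j_call=row["j_call"] or None,
                source=row.get("source", "") or "curated",
                shm_rate=float(shm) if shm else None,
            )
        )
    return records


def write_airr(records: Sequence[AntibodyRecord], path: str | Path) -> Path:
    """Write records as AIRR Rearrangement TSV (v1.x field names)."""
    rows = []
    for r in records:
        heavy_regs = r.regions.get("heavy", {})
        junction = heavy_regs.get("CDR3")
        row = {
            "sequence_id": r.antibody_id,
            "sequence": r.heavy_nt or "",
            "sequence_aa": r.heavy_aa,
            "v_call": r.v_call or "",
            "j_call": r.j_call or "",
            "junction_aa": r.heavy_aa[junction[0] : junction[1]] if junction else "",
            "source": r.source,
            "shm_rate": "" if r.shm_rate is None else repr(r.shm_rate),
            "light_sequence_aa": r.light_aa or "",
        }
        for region, (cs, ce) in _AIRR_REGION_FIELDS.items():
            if region in heavy_regs:
                s, e = heavy_regs[region]
                row[cs], row[ce] = s + 1, e
            else:
                row[cs] = row[ce] = ""
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence map; duplicate ids are an error."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    dups = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            dups.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if dups:
        raise FormatError(f"{path}: duplicate FASTA ids: {sorted(set(dups))}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


def read_reference_fasta(path: str | Path, segment: str, frame: int = 0) -> list[ReferenceGene]:
    """Read a germline segment FASTA as :class:`ReferenceGene` objects."""
    return [
        ReferenceGene(name=name, segment=segment, nt_seq=seq, frame=frame)
        for name, seq in read_fasta(path).items()
    ]


def write_reference_fasta(genes: Iterable[ReferenceGene], path: str | Path) -> Path:
    return write_fasta({g.name: g.nt_seq for g in genes}, path)


# ---------------------------------------------------------------------------
# Pair / epitope CSV tables

_PAIR_COLUMNS = ["id_a", "id_b", "jaccard", "cdrh3_identity", "same_cdr_lengths"]


def write_pair_table(pairs: Sequence[AntibodyPair], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "jaccard": p.jaccard,
                "cdrh3_identity": p.cdrh3_identity,
                "same_cdr_lengths": p.same_cdr_lengths,
            }
            for p in pairs
        ],
        columns=_PAIR_COLUMNS,
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_pair_table(path: str | Path) -> list[AntibodyPair]:
    df = pd.read_csv(path)
    for col in _PAIR_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing pair-table column '{col}'")
    return [
        AntibodyPair(
            id_a=str(row.id_a),
            id_b=str(row.id_b),
            jaccard=float(row.jaccard),
            cdrh3_identity=float(row.cdrh3_identity),
            same_cdr_lengths=bool(row.same_cdr_lengths),
        )
        for row in df.itertuples()
    ]


def _residues_to_str(residues: frozenset[tuple[str, int]]) -> str:
    return ";".join(f"{c}:{i}" for c, i in sorted(residues))


def _residues_from_str(s: str) -> frozenset[tuple[str, int]]:
    out = set()
    for tok in s.split(";"):
        chain, idx = tok.split(":")
        out.add((chain, int(idx)))
    return frozenset(out)


def write_epitope_table(epitopes: Sequence[EpitopeAnnotation], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "antibody_id": e.antibody_id,
                "antigen_id": e.antigen_id,
                "residues": _residues_to_str(e.residues),
                "assay_positive": e.assay_positive,
                "structure_method": e.structure_method,
                "species": e.species,
                "scfv": e.scfv,
                "chains_assigned": e.chains_assigned,
            }
            for e in epitopes
        ]
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_epitope_table(path: str | Path) -> list[EpitopeAnnotation]:
    df = pd.read_csv(path)
    needed = ["antibody_id", "antigen_id", "residues"]
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: missing epitope-table column '{col}'")
    out = []
    for row in df.itertuples():
        out.append(
            EpitopeAnnotation(
                antibody_id=str(row.antibody_id),
                antigen_id=str(row.antigen_id),
                residues=_residues_from_str(str(row.residues)),
                assay_positive=bool(getattr(row, "assay_positive", True)),
                structure_method=str(getattr(row, "structure_method", "xray")),
                species=str(getattr(row, "species", "human")),
                scfv=bool(getattr(row, "scfv", False)),
                chains_assigned=bool(getattr(row, "chains_assigned", True)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fivemer substitution table CSV (columns: context,target_base,likelihood)

def write_fivemer_table(model: SubstitutionModel, path: str | Path) -> Path:
    if model.context_len != 5:
        raise ValueError("fivemer table writer requires a fivemer model")
    rows = [
        {"context": ctx, "target_base": target, "likelihood": lik}
        for (pos, ctx, target), lik in sorted(model.table.items())
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_fivemer_table(path: str | Path) -> SubstitutionModel:
    df = pd.read_csv(path)
    for col in ("context", "target_base", "likelihood"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing fivemer-table column '{col}'")
    table = {
        ("center", str(row.context).upper(), str(row.target_base).upper()): float(row.likelihood)
        for row in df.itertuples()
    }
    return SubstitutionModel(context_len=5, table=table)


# ---------------------------------------------------------------------------
# PDB backbone coordinates

_REGION_TO_CHAIN = {"H": "H", "L": "L"}


def write_backbone_pdb(model: BackboneModel, path: str | Path, records_regions=None) -> Path:
    """Write backbone coordinates as PDB ATOM records (one chain per
    antibody chain; region labels reconstructed on read from a region map)."""
    path = Path(path)
    with open(path, "w") as fh:
        serial = 1
        for region, res, atom, xyz in model.atoms:
            chain = region.split(":")[0]
            name = atom.center(4) if len(atom) < 4 else atom
            fh.write(
                f"ATOM  {serial:5d} {name:<4s} GLY {chain}{res + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           "
                f"{atom[0]}\n"
            )
            serial += 1
        fh.write("END\n")
    return path


def read_backbone_pdb(
    path: str | Path,
    antibody_id: str,
    regions: Mapping[str, Mapping[str, tuple[int, int]]],
    backbone_atoms: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS,
) -> BackboneModel:
    """Read ATOM coordinate records into a :class:`BackboneModel`.

    ``regions`` gives per-chain region boundaries over residue indices
    (0-based, half-open) so atoms can be region-labelled. Residues missing
    any configured backbone atom are an error naming the missing atoms.
    """
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    structure = pdb_file.get_structure(model=1)
    atoms: list[tuple[str, int, str, np.ndarray]] = []
    per_residue: dict[tuple[str, int], set[str]] = {}
    chain_name = {"H": "heavy", "L": "light"}
    for i in range(structure.array_length()):
        chain = str(structure.chain_id[i])
        res = int(structure.res_id[i]) - 1
        atom = str(structure.atom_name[i])
        if atom not in backbone_atoms:
            continue
        regmap = regions.get(chain_name.get(chain, chain), {})
        label = None
        for region, (s, e) in regmap.items():
            if s <= res < e:
                label = f"{chain}:{region}"
                break
        if label is None:
            label = f"{chain}:FR?"
        per_residue.setdefault((chain, res), set()).add(atom)
        atoms.append((label, res, atom, np.asarray(structure.coord[i], dtype=float)))
    missing = {
        f"{chain}{res + 1}": sorted(set(backbone_atoms) - present)
        for (chain, res), present in per_residue.items()
        if set(backbone_atoms) - present
    }
    if missing:
        raise FormatError(f"{path}: residues missing backbone atoms: {missing}")
    return BackboneModel(antibody_id, atoms, backbone_atoms)
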