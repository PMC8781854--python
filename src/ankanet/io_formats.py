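"""Readers and writers for every external format the pipeline touches.

All protein coordinates are 1-based inclusive (UniProt convention) throughout
the package; conversion to 0-based happens only inside these functions.

Formats handled here:

* FASTA (plain and aligned) via Biopython,
* Calpha-only PDB (fixed-width ATOM records; pLDDT or B-factor column),
* DSSP output (classic ``mkdssp`` files and this package's DSSP-like TSV),
* TSV tables for repeat annotations, variants, and cluster reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.DSSP import make_dssp_dict
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ankanet")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: three-letter -> one-letter lookup used by the PDB reader
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

#: DSSP eight-state alphabet; blank is mapped to coil on read
DSSP_STATES = set("HGIEBTSC")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class AnnotationError(FormatError):
    """Raised when a repeat/domain annotation row fails validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """A protein sequence plus its 1-based inclusive repeat annotations.

    ``repeats`` must be sorted by start and non-overlapping; both conditions
    are enforced at construction.  ``meta`` carries generator ground truth
    (family label, planted identity) and is never required downstream.
    """

    accession: str
    sequence: str
    repeats: list[tuple[int, int]] = field(default_factory=list)
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        prev_end = 0
        self.repeats = [tuple(r) for r in self.repeats]
        for i, (start, end) in enumerate(self.repeats, start=1):
            if not (1 <= start <= end <= n):
                raise AnnotationError(
                    f"{self.accession} repeat {i}: range ({start},{end}) out of "
                    f"bounds for sequence of length {n}"
                )
            if start <= prev_end:
                raise AnnotationError(
                    f"{self.accession} repeat {i}: range ({start},{end}) overlaps "
                    f"or is unsorted relative to the previous repeat"
                )
            prev_end = end

    @property
    def n_copies(self) -> int:
        return len(self.repeats)

    def repeat_domain_sequence(self) -> str:
        """Concatenated sequence of all annotated repeat copies."""
        return "".join(self.sequence[s - 1:e] for s, e in self.repeats)

    def copy_of(self, position: int) -> Optional[tuple[int, int]]:
        """Return (copy_number, motif_position) for a residue, or None."""
        for c, (start, end) in enumerate(self.repeats, start=1):
            if start <= position <= end:
                return c, position - start + 1
        return None


@dataclass
class CaResidue:
    chain: str
    resnum: int
    aa: str
    x: float
    y: float
    z: float
    plddt: Optional[float] = None


@dataclass
class CaStructure:
    """Ordered Calpha trace of one chain (or one generated solenoid)."""

    residues: list[CaResidue]
    source: str = "predicted"  # "predicted" | "experimental"

    def __post_init__(self) -> None:
        nums = [r.resnum for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise FormatError("residue numbers must be strictly increasing")
        if not np.isfinite(self.coords()).all():
            raise FormatError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        return np.array([[r.x, r.y, r.z] for r in self.residues], dtype=float)

    def resnums(self) -> list[int]:
        return [r.resnum for r in self.residues]

    def plddt_values(self) -> np.ndarray:
        return np.array(
            [np.nan if r.plddt is None else r.plddt for r in self.residues]
        )


@dataclass
class VariantRecord:
    accession: str
    position: int
    ref: str
    alt: str
    condition: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"variant position must be >= 1, got {self.position}")
        if not self.is_frameshift() and self.ref not in AMINO_ACIDS:
            raise FormatError(f"unknown reference residue {self.ref!r}")

    def is_frameshift(self) -> bool:
        return self.ref == "fs" or self.alt.endswith("fs")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {accession: sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=acc, description="") for acc, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# repeat annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, fasta_path: str | Path) -> list[ProteinRecord]:
    """Join a repeat-annotation TSV with its FASTA into validated records.

    The TSV must carry a header line ``accession  repeat_index  start  end``.
    Ranges are validated against sequence bounds; overlap, inversion, or
    out-of-bounds coordinates raise :class:`AnnotationError` naming the row.
    """
    seqs = read_fasta(fasta_path)
    by_acc: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["accession", "repeat_index", "start", "end"]
        if header[: len(required)] != required:
            raise FormatError(
                f"{path}: expected header {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                acc, idx, start, end = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if start > end:
                raise AnnotationError(f"{path}:{lineno}: start {start} > end {end}")
            by_acc.setdefault(acc, []).append((idx, start, end))

    records = []
    for acc, rows in by_acc.items():
        if acc not in seqs:
            raise AnnotationError(f"accession {acc} has annotations but no sequence")
        rows.sort()
        try:
            records.append(
                ProteinRecord(acc, seqs[acc], [(s, e) for _, s, e in rows])
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{path}: {exc}") from exc
    # FASTA-only entries come through with zero repeats
    for acc, seq in seqs.items():
        if acc not in by_acc:
            records.append(ProteinRecord(acc, seq))
    return records


def write_annotations(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\trepeat_index\tstart\tend\n")
        for rec in records:
            for i, (s, e) in enumerate(rec.repeats, start=1):
                fh.write(f"{rec.accession}\t{i}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# PDB (Calpha only)
# ---------------------------------------------------------------------------

def read_pdb_calpha(
    path: str | Path,
    chain: Optional[str] = None,
    source: str = "predicted",
) -> CaStructure:
    """Extract one Calpha per residue from a PDB file.

    First model only.  altLoc duplicates collapse to the highest-occupancy
    conformer (Biopython's disordered-atom default).  Residues with no
    Calpha are skipped with a warning.  The B-factor column is exposed as
    ``plddt`` (AlphaFold convention); for experimental structures it is the
    crystallographic B-factor and the pLDDT filter is simply not applied.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Biopython PDBConstructionWarnings
        model = PDBParser(QUIET=True).get_structure("s", str(path))
        try:
            first_model = next(iter(model))
        except StopIteration:
            raise FormatError(f"{path}: no ATOM records") from None

    chains = {c.id: c for c in first_model}
    if not chains:
        raise FormatError(f"{path}: no ATOM records")
    if chain is None:
        chain_obj = next(iter(chains.values()))
    elif chain in chains:
        chain_obj = chains[chain]
    else:
        raise FormatError(
            f"{path}: chain {chain!r} not present; available: {sorted(chains)}"
        )

    residues = []
    for res in chain_obj:
        hetflag, resnum, _icode = res.id
        if hetflag.strip():
            continue
        if "CA" not in res:
            logger.warning("%s: residue %s %d lacks a Calpha, skipped",
                           path, res.resname, resnum)
            continue
        atom = res["CA"]  # DisorderedAtom resolves to highest occupancy
        x, y, z = atom.coord
        aa = _THREE_TO_ONE.get(res.resname.strip(), "X")
        residues.append(
            CaResidue(chain_obj.id, resnum, aa, float(x), float(y), float(z),
                      plddt=float(atom.bfactor))
        )
    if not residues:
        raise FormatError(f"{path}: chain {chain_obj.id} has no Calpha atoms")
    return CaStructure(residues, source=source)


def write_pdb_calpha(structure: CaStructure, path: str | Path) -> None:
    """Write a Calpha-only PDB file (fixed-width ATOM records, 3-decimal XYZ)."""
    with open(path, "w") as fh:
        for i, r in enumerate(structure.residues, start=1):
            resname = _ONE_TO_THREE.get(r.aa, "UNK")
            b = 0.0 if r.plddt is None else r.plddt
            fh.write(
                f"ATOM  {i:5d}  CA  {resname:>3s} {r.chain:1s}{r.resnum:4d}    "
                f"{r.x:8.3f}{r.y:8.3f}{r.z:8.3f}{1.00:6.2f}{b:6.2f}          "
                f" C  \n"
            )
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# DSSP / secondary structure
# ---------------------------------------------------------------------------

def collapse_ss(ss: str) -> str:
    """Three-state collapse: H,G,I -> H; E,B -> E; everything else -> C."""
    if ss in "HGI":
        return "H"
    if ss in "EB":
        return "E"
    return "C" if ss not in "TC" else ss


def read_dssp(path: str | Path, collapse: bool = False) -> dict[int, str]:
    """Parse per-residue secondary structure from a DSSP file.

    Accepts classic ``mkdssp`` output (delegated to Biopython) or this
    package's DSSP-like TSV (``resnum  aa  ss`` with a header).  Blank DSSP
    assignments become ``C``.  With ``collapse=True`` the eight states fold
    into the three-letter alphabet H/E/C (turns T are kept as printed, since
    the consensus plots distinguish H/T/C).
    """
    path = Path(path)
    text_head = path.open().readline()
    mapping: dict[int, str] = {}
    if text_head.startswith("resnum"):
        with path.open() as fh:
            fh.readline()
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                try:
                    resnum, _aa, ss = int(parts[0]), parts[1], parts[2]
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: unparseable line") from exc
                ss = ss if ss.strip() else "C"
                if ss not in DSSP_STATES:
                    raise FormatError(f"{path}:{lineno}: unknown SS state {ss!r}")
                mapping[resnum] = ss
    else:
        try:
            dssp_dict, _keys = make_dssp_dict(str(path))
        except Exception as exc:  # Biopython raises bare Exception subclasses
            raise FormatError(f"{path}: not parseable as DSSP output: {exc}") from exc
        for (_chain, (_het, resnum, _icode)), values in dssp_dict.items():
            ss = values[1]
            mapping[resnum] = "C" if ss in (" ", "-", "") else ss
    if collapse:
        mapping = {k: collapse_ss(v) for k, v in mapping.items()}
    return mapping


def write_ss_tsv(
    resnums: Sequence[int], aas: Sequence[str], ss: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("resnum\taa\tss\n")
        for n, a, s in zip(resnums, aas, ss):
            fh.write(f"{n}\t{a}\t{s}\n")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV (accession, position, ref, alt, condition)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["accession", "position", "ref", "alt"]:
            raise FormatError(f"{path}: unexpected variant header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                out.append(
                    VariantRecord(
                        parts[0], int(parts[1]), parts[2], parts[3],
                        parts[4] if len(parts) > 4 else "",
                    )
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad variant row") from exc
    return out


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tposition\tref\talt\tcondition\n")
        for v in variants:
            fh.write(f"{v.accession}\t{v.position}\t{v.ref}\t{v.alt}\t{v.condition}\n")
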