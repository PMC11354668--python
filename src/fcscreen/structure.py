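"""Typed model of antibody–ssDNA complexes and PDB I/O.

The model distinguishes three entity families relevant to the screening
pipeline: protein receptor chains (amino acids), a single ssDNA ligand chain
(deoxynucleotides), and N-glycan chains (monosaccharides).  Residues keep
their author numbering — all region definitions (hinge, CH2/CH3 windows) are
expressed in author numbering of the reference antibody structure.

Only heavy atoms are retained: the downstream contact cutoffs (3–6 Å band)
operate at heavy-atom scale and the docked poses are rigid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

AMINO_ACIDS: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)
NUCLEOTIDES: frozenset[str] = frozenset({"DA", "DC", "DG", "DT"})
#: HETATM residue names treated as glycan building blocks by default.
DEFAULT_MONOSACCHARIDES: frozenset[str] = frozenset(
    {"NAG", "MAN", "BMA", "GAL", "FUC", "FRU"}
)

KIND_AMINO_ACID = "amino_acid"
KIND_NUCLEOTIDE = "nucleotide"
KIND_MONOSACCHARIDE = "monosaccharide"
KIND_OTHER = "other"

#: Region labels and their Fab/Fc groupings.
FAB_REGIONS: frozenset[str] = frozenset({"VH", "CH1", "VL", "CL"})
FC_REGIONS: frozenset[str] = frozenset({"CH2", "CH3", "glycan"})
HINGE_REGION = "hinge"
ALL_REGIONS: frozenset[str] = FAB_REGIONS | FC_REGIONS | {HINGE_REGION}
UNASSIGNED = "unassigned"


class PDBParseError(ValueError):
    """Raised for records that cannot be interpreted; carries the line number."""


class NoLigandError(ValueError):
    """Raised when a complex does not contain exactly one ssDNA chain."""


def residue_kind(name: str, monosaccharides: frozenset[str] = DEFAULT_MONOSACCHARIDES) -> str:
    """Classify a residue name into one of the four entity kinds."""
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return KIND_AMINO_ACID
    if name in NUCLEOTIDES:
        return KIND_NUCLEOTIDE
    if name in monosaccharides:
        return KIND_MONOSACCHARIDE
    return KIND_OTHER


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    name: str
    kind: str
    atoms: list[Atom]
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(
                f"residue {self.name} {self.chain_id}{self.seq_num} has no atoms"
            )
        expected = residue_kind(self.name)
        # A custom monosaccharide whitelist may rescue names the default
        # lookup marks "other"; anything else must agree with the lookup.
        if self.kind != expected and not (
            self.kind == KIND_MONOSACCHARIDE and expected == KIND_OTHER
        ):
            raise ValueError(
                f"kind {self.kind!r} inconsistent with residue name {self.name!r}"
            )

    @property
    def site(self) -> tuple[str, int]:
        """(chain_id, seq_num) — the key used for binding-site bookkeeping."""
        return (self.chain_id, self.seq_num)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class ComplexStructure:
    complex_id: str
    receptor_chains: dict[str, list[Residue]]
    ligand_chain: list[Residue]
    glycan_chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        if not self.receptor_chains:
            raise ValueError("complex must contain at least one protein chain")
        for res in self.ligand_chain:
            if res.kind != KIND_NUCLEOTIDE:
                raise ValueError(
                    f"ligand chain contains non-nucleotide residue {res.name}"
                )

    @property
    def ligand_chain_id(self) -> str:
        return self.ligand_chain[0].chain_id if self.ligand_chain else ""

    def receptor_residues(self) -> list[Residue]:
        """Protein and glycan residues in deterministic (chain, seq) order."""
        out: list[Residue] = []
        for cid in sorted(self.receptor_chains):
            out.extend(self.receptor_chains[cid])
        for cid in sorted(self.glycan_chains):
            out.extend(self.glycan_chains[cid])
        return out

    def all_residues(self) -> list[Residue]:
        return self.receptor_residues() + list(self.ligand_chain)


# ---------------------------------------------------------------------------
# PDB parsing / writing
#
# Fixed-column ATOM/HETATM records only; this keeps exact control over the
# contracts the pipeline needs (altloc tie-breaking, line-numbered errors,
# byte-stable normalized output for generated fixtures).
# ---------------------------------------------------------------------------

_HYDROGENS = {"H", "D"}


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    # Two-letter elements occupy columns 13-14; single letters are digits-padded.
    head = stripped.lstrip("0123456789")
    return head[:1].upper() if head else ""


def parse_complex(
    pdb_text: str,
    complex_id: str,
    monosaccharides: frozenset[str] = DEFAULT_MONOSACCHARIDES,
) -> ComplexStructure:
    """Parse a PDB-format string into a typed complex.

    Hydrogens and waters are discarded; alternate locations resolve to the
    highest-occupancy copy (ties keep the first encountered).

    Raises
    ------
    PDBParseError
        On an unparseable ATOM/HETATM record (message names the line number).
    NoLigandError
        If no ssDNA chain, or more than one, is present.
    """
    # (chain, seq, name, atom name) -> (occupancy, order, Atom)
    picked: dict[tuple[str, int, str, str], tuple[float, int, Atom]] = {}
    order_of_residue: dict[tuple[str, int, str], int] = {}
    counter = 0

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6]
        if record not in ("ATOM  ", "HETATM"):
            continue
        try:
            atom_name = line[12:16]
            res_name = line[17:20].strip().upper()
            chain_id = line[21].strip() or "_"
            seq_num = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip().upper() or _guess_element(atom_name)
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"unparseable PDB record at line {lineno}: {exc}") from exc

        if res_name == "HOH" or element in _HYDROGENS:
            continue

        atom = Atom(name=atom_name.strip(), element=element, coords=(x, y, z))
        key = (chain_id, seq_num, res_name, atom.name)
        reskey = (chain_id, seq_num, res_name)
        order_of_residue.setdefault(reskey, counter)
        counter += 1
        prev = picked.get(key)
        if prev is None or occupancy > prev[0]:
            # strict '>' keeps the first-encountered copy on occupancy ties
            picked[key] = (occupancy, counter, atom)

    if not picked:
        raise PDBParseError("no ATOM/HETATM records found")

    # Group atoms back into residues, preserving file order.
    residues: dict[tuple[str, int, str], list[Atom]] = {}
    for (chain_id, seq_num, res_name, _), (_, order, atom) in sorted(
        picked.items(), key=lambda kv: kv[1][1]
    ):
        residues.setdefault((chain_id, seq_num, res_name), []).append(atom)

    receptor: dict[str, list[Residue]] = {}
    glycans: dict[str, list[Residue]] = {}
    dna_chains: dict[str, list[Residue]] = {}
    for reskey in sorted(residues, key=lambda k: order_of_residue[k]):
        chain_id, seq_num, res_name = reskey
        kind = residue_kind(res_name, monosaccharides)
        res = Residue(chain_id, seq_num, res_name, kind, residues[reskey])
        if kind == KIND_NUCLEOTIDE:
            dna_chains.setdefault(chain_id, []).append(res)
        elif kind == KIND_MONOSACCHARIDE:
            glycans.setdefault(chain_id, []).append(res)
        elif kind == KIND_AMINO_ACID:
            receptor.setdefault(chain_id, []).append(res)
        else:
            logger.warning(
                "%s: residue %s %s%d has unknown type; excluded from analysis",
                complex_id, res_name, chain_id, seq_num,
            )

    if len(dna_chains) == 0:
        raise NoLigandError(f"{complex_id}: no ligand (ssDNA) chain found")
    if len(dna_chains) > 1:
        raise NoLigandError(
            f"{complex_id}: ambiguous ligand — {len(dna_chains)} DNA chains "
            f"({', '.join(sorted(dna_chains))})"
        )
    if not receptor:
        raise PDBParseError(f"{complex_id}: no protein receptor chain found")

    (ligand,) = dna_chains.values()
    ligand.sort(key=lambda r: r.seq_num)  # 5'->3' by author numbering
    for chain in receptor.values():
        chain.sort(key=lambda r: r.seq_num)
    for chain in glycans.values():
        chain.sort(key=lambda r: r.seq_num)

    return ComplexStructure(
        complex_id=complex_id,
        receptor_chains=receptor,
        ligand_chain=ligand,
        glycan_chains=glycans,
    )


def write_pdb(structure: ComplexStructure) -> str:
    """Serialize a complex as a normalized PDB string (heavy atoms only)."""
    lines: list[str] = []
    serial = 1

    def emit(res: Residue, record: str) -> None:
        nonlocal serial
        for atom in res.atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"{record:<6s}{serial:5d} {name:<4s} {res.name:>3s} "
                f"{res.chain_id}{res.seq_num:4d}    "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
            serial += 1

    # re-emit in a canonical order: protein chains, glycans, then the ligand
    for cid in sorted(structure.receptor_chains):
        for res in structure.receptor_chains[cid]:
            emit(res, "ATOM")
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    for cid in sorted(structure.glycan_chains):
        for res in structure.glycan_chains[cid]:
            emit(res, "HETATM")
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    for res in structure.ligand_chain:
        emit(res, "ATOM")
    lines.append(f"TER   {serial:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionInterval:
    chain: str
    start: int
    end: int
    region: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.region not in ALL_REGIONS:
            raise ValueError(f"unknown region label {self.region!r}")

    def contains(self, chain_id: str, seq_num: int) -> bool:
        return chain_id == self.chain and self.start <= seq_num <= self.end


@dataclass
class RegionMap:
    """Chain-interval → antibody region lookup (author numbering).

    Fab grouping = {VH, CH1, VL, CL}; Fc grouping = {CH2, CH3, glycan};
    the hinge is its own grouping.
    """

    intervals: list[RegionInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chain: dict[str, list[RegionInterval]] = {}
        for iv in self.intervals:
            by_chain.setdefault(iv.chain, []).append(iv)
        for chain, ivs in by_chain.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping intervals on chain {chain}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    def region_of(self, chain_id: str, seq_num: int) -> str | None:
        for iv in self.intervals:
            if iv.contains(chain_id, seq_num):
                return iv.region
        return None

    def chains(self) -> set[str]:
        return {iv.chain for iv in self.intervals}

    @staticmethod
    def grouping(region: str | None) -> str | None:
        """Map a region label to its Fab/Fc/hinge grouping."""
        if region in FAB_REGIONS:
            return "Fab"
        if region in FC_REGIONS:
            return "Fc"
        if region == HINGE_REGION:
            return "hinge"
        return None

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RegionMap":
        items = payload["regions"] if "regions" in payload else payload
        intervals = [
            RegionInterval(
                chain=str(d["chain"]),
                start=int(d["start"]),
                end=int(d["end"]),
                region=str(d["region"]),
            )
            for d in items
        ]
        return cls(intervals=intervals)

    @classmethod
    def from_yaml(cls, text: str) -> "RegionMap":
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> dict:
        return {
            "regions": [
                {"chain": iv.chain, "start": iv.start, "end": iv.end, "region": iv.region}
                for iv in self.intervals
            ]
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def default_region_map() -> RegionMap:
    """The region map shipped for 1IGT-style chain naming (A/C light, B/D heavy).

    The published descriptions of the Fc span are internally inconsistent; the
    shipped default uses the 242–474 window with the hinge at 455–475 and is
    meant to be overridden for other receptors (see ``data/regions_1igt.yaml``).
    """
    text = resources.files("fcscreen.data").joinpath("regions_1igt.yaml").read_text()
    return RegionMap.from_yaml(text)


def assign_regions(structure: ComplexStructure, region_map: RegionMap) -> ComplexStructure:
    """Return a copy of the structure with per-residue region labels.

    Every receptor residue gets a label or ``"unassigned"``; glycan residues
    are always labeled ``"glycan"``.  Intervals naming chains absent from the
    structure produce a warning, not an error.
    """
    present = set(structure.receptor_chains) | set(structure.glycan_chains)
    for missing in sorted(region_map.chains() - present):
        warnings.warn(
            f"{structure.complex_id}: region map references chain {missing!r} "
            "not present in the structure",
            stacklevel=2,
        )

    receptor = {
        cid: [
            replace(res, region=region_map.region_of(res.chain_id, res.seq_num) or UNASSIGNED)
            for res in chain
        ]
        for cid, chain in structure.receptor_chains.items()
    }
    glycans = {
        cid: [replace(res, region="glycan") for res in chain]
        for cid, chain in structure.glycan_chains.items()
    }
    return ComplexStructure(
        complex_id=structure.complex_id,
        receptor_chains=receptor,
        ligand_chain=list(structure.ligand_chain),
        glycan_chains=glycans,
    )
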