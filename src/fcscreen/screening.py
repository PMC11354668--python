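"""Binding-mode classification, Fc-binder screening, and mutation comparison.

Modes (checked in order of precedence):

- ``FAB``   — every contacted receptor residue lies in the Fab grouping
- ``MODE1`` — every contacted receptor residue lies in the Fc grouping
  (CH2/CH3/glycan); the only mode flagged as Fc-bound
- ``MODE2`` — at least one contacted residue lies in the hinge interval
- ``MODE3`` — a majority of contacting nucleotides touch the Fc while the
  remainder touch only CH1 or CL
- ``UNCLASSIFIED`` otherwise (including ligands with zero contacts)

Docking scores are consumed from a pose table, never computed here.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from fcscreen.interface import Contact
from fcscreen.structure import ComplexStructure, RegionMap

logger = logging.getLogger(__name__)

DEFAULT_MAJORITY_THRESHOLD = 0.5


class BindingMode(str, enum.Enum):
    FAB = "FAB"
    MODE1 = "MODE1"
    MODE2 = "MODE2"
    MODE3 = "MODE3"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class PoseRecord:
    ligand_id: str
    pose_rank: int
    zdock_score: float

    def __post_init__(self) -> None:
        if self.pose_rank < 1:
            raise ValueError("pose_rank must be >= 1 (rank 1 = highest score)")


@dataclass
class ScreeningRecord:
    ligand_id: str
    mode: BindingMode
    fc_bound: bool
    zdock_score: float | None
    region_fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.fc_bound != (self.mode == BindingMode.MODE1):
            raise ValueError("fc_bound must hold exactly for MODE1")
        for grouping, frac in self.region_fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction for {grouping} outside [0, 1]: {frac}")


@dataclass(frozen=True)
class MutationComparison:
    ligand_id: str
    score_before: float
    score_after: float
    site_still_contacted: bool

    @property
    def delta(self) -> float:
        """score_after − score_before; negative means lost favorability."""
        return self.score_after - self.score_before


def read_pose_table(path: str | Path) -> list[PoseRecord]:
    """Read a TSV pose table with columns ligand_id, pose_rank, zdock_score."""
    df = pd.read_csv(path, sep="\t")
    required = {"ligand_id", "pose_rank", "zdock_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pose table missing columns: {sorted(missing)}")
    return [
        PoseRecord(str(r.ligand_id), int(r.pose_rank), float(r.zdock_score))
        for r in df.itertuples()
    ]


def classify_binding_mode(
    structure: ComplexStructure,
    contacts: Sequence[Contact],
    region_map: RegionMap | None = None,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
    zdock_score: float | None = None,
) -> ScreeningRecord:
    """Classify one docked ligand's binding mode from its interface contacts.

    Receptor residues must already carry region labels (``assign_regions``);
    ``region_map`` is only consulted as a fallback for unlabeled residues.
    """
    n_nt = max(len(structure.ligand_chain), 1)

    def region_of(c: Contact) -> str | None:
        res = c.receptor_residue
        if res.region is not None and res.region != "unassigned":
            return res.region
        if region_map is not None:
            return region_map.region_of(res.chain_id, res.seq_num)
        return None

    contacted_regions: list[str | None] = [region_of(c) for c in contacts]
    groupings = [RegionMap.grouping(r) for r in contacted_regions]

    # Per-nucleotide view: which groupings / regions does each base touch?
    nt_groupings: dict[int, set[str]] = {}
    nt_regions: dict[int, set[str]] = {}
    for c, region, grouping in zip(contacts, contacted_regions, groupings):
        nt = c.ligand_residue.seq_num
        nt_groupings.setdefault(nt, set()).add(grouping or "unassigned")
        nt_regions.setdefault(nt, set()).add(region or "unassigned")

    region_fractions = {
        g: sum(1 for gs in nt_groupings.values() if g in gs) / n_nt
        for g in ("Fab", "Fc", "hinge")
    }

    def record(mode: BindingMode) -> ScreeningRecord:
        return ScreeningRecord(
            ligand_id=structure.complex_id,
            mode=mode,
            fc_bound=mode == BindingMode.MODE1,
            zdock_score=zdock_score,
            region_fractions=region_fractions,
        )

    if not contacts:
        logger.warning("%s: ligand has zero contacts; UNCLASSIFIED", structure.complex_id)
        return record(BindingMode.UNCLASSIFIED)

    if all(g == "Fab" for g in groupings):
        return record(BindingMode.FAB)
    if all(g == "Fc" for g in groupings):
        return record(BindingMode.MODE1)
    if any(g == "hinge" for g in groupings):
        return record(BindingMode.MODE2)

    contacting = list(nt_groupings)
    fc_nts = [nt for nt in contacting if "Fc" in nt_groupings[nt]]
    non_fc_regions = {
        r or "unassigned" for r, g in zip(contacted_regions, groupings) if g != "Fc"
    }
    if (
        len(fc_nts) / len(contacting) >= majority_threshold
        and non_fc_regions <= {"CH1", "CL"}
    ):
        return record(BindingMode.MODE3)
    return record(BindingMode.UNCLASSIFIED)


def screen_fc_binders(records: Sequence[ScreeningRecord]) -> list[ScreeningRecord]:
    """Filter Fc-specific binders and rank them by docking score.

    Descending score; ties broken by ligand_id lexicographically.  Records
    without a score sort after scored ones.
    """
    if not records:
        raise ValueError("screen_fc_binders requires a non-empty record list")
    hits = [r for r in records if r.fc_bound]
    hits.sort(
        key=lambda r: (
            -(r.zdock_score if r.zdock_score is not None else float("-inf")),
            r.ligand_id,
        )
    )
    return hits


def mutation_report(
    before: tuple[PoseRecord, Sequence[Contact]],
    after: tuple[PoseRecord, Sequence[Contact]],
    site: tuple[str, int],
) -> MutationComparison:
    """Compare docking score and site engagement before/after a point mutation."""
    (pose_before, _), (pose_after, contacts_after) = before, after
    if pose_before.ligand_id != pose_after.ligand_id:
        raise ValueError(
            f"mismatched ligands: {pose_before.ligand_id!r} vs {pose_after.ligand_id!r}"
        )
    contacted_sites = {
        (c.receptor_residue.chain_id, c.receptor_residue.seq_num) for c in contacts_after
    }
    return MutationComparison(
        ligand_id=pose_before.ligand_id,
        score_before=pose_before.zdock_score,
        score_after=pose_after.zdock_score,
        site_still_contacted=tuple(site) in contacted_sites,
    )
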