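"""Ligand–receptor interface contacts and per-site binding frequencies.

A contact is established at residue-pair granularity: a ssDNA base and a
receptor unit (amino acid or monosaccharide) are in contact when any pair of
their heavy atoms lies within the applicable distance cutoff.  The admissible
cutoff band is 3–6 Å; the shipped default is a single 4.5 Å cutoff, with an
optional per-class map (hydrogen-bond-capable N/O pairs vs. everything else).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from fcscreen.structure import (
    KIND_AMINO_ACID,
    KIND_MONOSACCHARIDE,
    KIND_NUCLEOTIDE,
    ComplexStructure,
    Residue,
)

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.5
#: Optional interaction-class cutoffs mirroring the 3-6 Å band:
#: N/O atom pairs are hydrogen-bond capable and get the tight cutoff.
HBOND_CLASS_CUTOFFS: dict[str, float] = {"hbond": 3.5, "other": 6.0}
_HBOND_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class ContactParams:
    """Distance cutoffs for contact detection (all in Å, within (0, 10])."""

    default_cutoff: float = DEFAULT_CUTOFF
    cutoff_by_class: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, value in {"default": self.default_cutoff, **self.cutoff_by_class}.items():
            if not (0.0 < value <= 10.0):
                raise ValueError(f"cutoff {label}={value} outside (0, 10] Å")

    def cutoff_for(self, klass: str) -> float:
        return float(self.cutoff_by_class.get(klass, self.default_cutoff))

    @property
    def max_cutoff(self) -> float:
        return max([self.default_cutoff, *self.cutoff_by_class.values()])


def interaction_class(element_a: str, element_b: str) -> str:
    """'hbond' when both atoms are N/O (hydrogen-bond capable), else 'other'."""
    if element_a.upper() in _HBOND_ELEMENTS and element_b.upper() in _HBOND_ELEMENTS:
        return "hbond"
    return "other"


@dataclass(frozen=True)
class Contact:
    ligand_residue: Residue
    receptor_residue: Residue
    min_distance: float
    interaction_class: str

    def __post_init__(self) -> None:
        if self.ligand_residue.kind != KIND_NUCLEOTIDE:
            raise ValueError("ligand side of a contact must be a nucleotide")
        if self.receptor_residue.kind not in (KIND_AMINO_ACID, KIND_MONOSACCHARIDE):
            raise ValueError(
                "receptor side of a contact must be an amino acid or monosaccharide"
            )


def find_contacts(structure: ComplexStructure, params: ContactParams | None = None) -> list[Contact]:
    """Detect all base/receptor-unit contacts in one complex.

    Returns one :class:`Contact` per residue pair with at least one qualifying
    heavy-atom pair; ``min_distance`` is the minimum heavy-atom distance of the
    pair.  Ordering is deterministic: (receptor chain, receptor seq, ligand seq).
    An empty ligand yields an empty list.
    """
    params = params or ContactParams()
    ligand = structure.ligand_chain
    receptor_units = [
        r
        for r in structure.receptor_residues()
        if r.kind in (KIND_AMINO_ACID, KIND_MONOSACCHARIDE)
    ]
    if not ligand or not receptor_units:
        return []

    lig_coords, lig_elem, lig_idx = _flatten(ligand)
    rec_coords, rec_elem, rec_idx = _flatten(receptor_units)

    tree = cKDTree(rec_coords)
    neighbor_lists = tree.query_ball_point(lig_coords, r=params.max_cutoff)

    # residue-pair -> [min distance over all atom pairs within query radius,
    #                  distance of closest qualifying pair, its class]
    best: dict[tuple[int, int], list] = {}
    for a, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            continue
        la = lig_coords[a]
        for b in neighbors:
            d = float(np.linalg.norm(la - rec_coords[b]))
            klass = interaction_class(lig_elem[a], rec_elem[b])
            qualifies = d <= params.cutoff_for(klass)
            key = (lig_idx[a], rec_idx[b])
            entry = best.setdefault(key, [np.inf, np.inf, None])
            entry[0] = min(entry[0], d)
            if qualifies and d < entry[1]:
                entry[1] = d
                entry[2] = klass

    contacts = [
        Contact(
            ligand_residue=ligand[li],
            receptor_residue=receptor_units[ri],
            min_distance=dist,
            interaction_class=klass,
        )
        for (li, ri), (dist, _qd, klass) in best.items()
        if klass is not None
    ]
    contacts.sort(
        key=lambda c: (
            c.receptor_residue.chain_id,
            c.receptor_residue.seq_num,
            c.ligand_residue.seq_num,
        )
    )
    return contacts


def _flatten(residues: Sequence[Residue]) -> tuple[np.ndarray, list[str], list[int]]:
    coords: list[tuple[float, float, float]] = []
    elements: list[str] = []
    owner: list[int] = []
    for i, res in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.coords)
            elements.append(atom.element)
            owner.append(i)
    return np.asarray(coords, dtype=float), elements, owner


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------


@dataclass
class BindingFrequencyProfile:
    """Per-site complex counts across an ensemble.

    ``counts[(chain, seq_num, name)]`` is the number of complexes whose
    interface includes that receptor site (each complex counted at most once
    per site).  ``contact_counts`` keeps the raw residue-pair contact tallies
    for transparency.
    """

    counts: dict[tuple[str, int, str], int]
    contact_counts: dict[tuple[str, int, str], int]
    ensemble_size: int

    def fraction(self, site: tuple[str, int, str]) -> float:
        return self.counts.get(site, 0) / self.ensemble_size

    def fractions(self) -> dict[tuple[str, int, str], float]:
        return {site: n / self.ensemble_size for site, n in self.counts.items()}


def binding_frequency(
    ensemble: Sequence[tuple[ComplexStructure, Sequence[Contact]]],
    region_filter: Iterable[str] | None = None,
) -> BindingFrequencyProfile:
    """Aggregate per-site binding frequencies over an ensemble of complexes.

    ``region_filter`` restricts to receptor residues whose assigned region is
    in the given set (e.g. the Fc grouping); ``None`` keeps every site.
    """
    if not ensemble:
        raise ValueError("binding_frequency requires a non-empty ensemble")
    allowed = set(region_filter) if region_filter is not None else None

    counts: dict[tuple[str, int, str], int] = {}
    raw: dict[tuple[str, int, str], int] = {}
    for _, contacts in ensemble:
        seen: set[tuple[str, int, str]] = set()
        for c in contacts:
            res = c.receptor_residue
            if allowed is not None and res.region not in allowed:
                continue
            site = (res.chain_id, res.seq_num, res.name)
            raw[site] = raw.get(site, 0) + 1
            seen.add(site)
        for site in seen:
            counts[site] = counts.get(site, 0) + 1

    ordered = dict(sorted(counts.items()))
    raw_ordered = dict(sorted(raw.items()))
    return BindingFrequencyProfile(
        counts=ordered, contact_counts=raw_ordered, ensemble_size=len(ensemble)
    )


def interface_composition(contacts: Iterable[Contact]) -> dict[str, dict[str, float]]:
    """Share of interface contacts per residue/sugar type, as percentages.

    Amino acids and monosaccharides are normalized separately: each family
    present sums to 100%.
    """
    tallies: dict[str, dict[str, int]] = {KIND_AMINO_ACID: {}, KIND_MONOSACCHARIDE: {}}
    total = 0
    for c in contacts:
        fam = tallies[c.receptor_residue.kind]
        fam[c.receptor_residue.name] = fam.get(c.receptor_residue.name, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("interface_composition requires at least one contact")

    out: dict[str, dict[str, float]] = {}
    for family, fam_counts in tallies.items():
        fam_total = sum(fam_counts.values())
        if fam_total:
            out[family] = {
                name: 100.0 * n / fam_total for name, n in sorted(fam_counts.items())
            }
    return out
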