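"""Base-vs-structural-unit contact propensity statistics.

For base *i* and receptor unit *j* (amino-acid type or monosaccharide type)
with ``N_ij`` residue-pair contacts and ``T_j`` total dataset contacts for
unit *j*, the propensity is

    P_ij = (N_ij / sum_j N_ij) / (T_j / sum_j T_j)

i.e. unit *j*'s share of base-*i* contacts normalized by unit *j*'s share of
all contacts.  P > 1 flags a favored pairing, P < 1 a disfavored one, and a
proportionally distributed table gives P = 1 everywhere defined.  Units with
T_j = 0 are undefined (serialized as "NA", never as a number).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from fcscreen.interface import Contact
from fcscreen.structure import AMINO_ACIDS, KIND_MONOSACCHARIDE

BASES: tuple[str, ...] = ("DA", "DC", "DG", "DT")

FAVORED = "favored"
DISFAVORED = "disfavored"
NEUTRAL = "neutral"


@dataclass
class ContactTable:
    """Contact count matrix N (bases × units) and per-unit dataset totals T."""

    N: pd.DataFrame
    T: pd.Series

    def __post_init__(self) -> None:
        units = list(self.N.columns) + [u for u in self.T.index if u not in self.N.columns]
        self.N = self.N.reindex(index=list(BASES), columns=units, fill_value=0).astype(int)
        self.T = self.T.reindex(units, fill_value=0).astype(int)
        if (self.N.to_numpy() < 0).any() or (self.T.to_numpy() < 0).any():
            raise ValueError("contact counts must be non-negative")
        violation = self.N.max(axis=0) > self.T
        if violation.any():
            bad = list(self.T.index[violation])
            raise ValueError(f"T_j smaller than max_i N_ij for units: {bad}")

    @classmethod
    def from_contacts(
        cls,
        contacts: Iterable[Contact],
        totals: Mapping[str, int] | None = None,
    ) -> "ContactTable":
        """Tally a contact set; T defaults to column sums of the same set."""
        counts: dict[str, dict[str, int]] = {}
        for c in contacts:
            base = c.ligand_residue.name
            unit = c.receptor_residue.name
            counts.setdefault(unit, {})
            counts[unit][base] = counts[unit].get(base, 0) + 1
        units = sorted(set(counts) | set(totals or {}))
        n = pd.DataFrame(
            {u: [counts.get(u, {}).get(b, 0) for b in BASES] for u in units},
            index=list(BASES),
            dtype=int,
        )
        if totals is None:
            t = n.sum(axis=0)
        else:
            t = pd.Series(totals).reindex(units, fill_value=0)
        return cls(N=n, T=t)

    def scaled(self, factor: int) -> "ContactTable":
        if factor <= 0:
            raise ValueError("scale factor must be a positive integer")
        return ContactTable(N=self.N * factor, T=self.T * factor)


@dataclass
class PropensityTable:
    """Propensity matrix P (NaN marks undefined cells) and per-unit presence %."""

    P: pd.DataFrame
    presence: pd.Series

    def classify(self) -> pd.DataFrame:
        """Label each defined cell favored/disfavored/neutral by P ⋛ 1."""
        def label(x: float) -> str | float:
            if np.isnan(x):
                return np.nan
            if x > 1.0:
                return FAVORED
            if x < 1.0:
                return DISFAVORED
            return NEUTRAL

        return self.P.map(label)

    def to_tsv(self) -> str:
        out = self.P.copy()
        return out.to_csv(sep="\t", na_rep="NA", float_format="%.6g")


def contact_propensity(
    table: ContactTable,
    normalize_over: Literal["units", "bases"] = "units",
) -> PropensityTable:
    """Compute the propensity matrix from a contact table.

    ``normalize_over="units"`` (default) takes base *i*'s contact shares across
    units; the alternative ``"bases"`` normalizes each unit's contacts across
    bases instead.  Both divide by unit *j*'s share of the dataset totals.
    """
    n = table.N.to_numpy(dtype=float)
    t = table.T.to_numpy(dtype=float)
    if n.sum() == 0 or t.sum() == 0:
        raise ValueError("contact table is all zero")
    inconsistent = (t == 0) & (n.sum(axis=0) > 0)
    if inconsistent.any():
        bad = list(table.T.index[inconsistent])
        raise ValueError(f"units with contacts but zero dataset total: {bad}")

    t_share = t / t.sum()  # unit j's share of all dataset contacts
    with np.errstate(divide="ignore", invalid="ignore"):
        if normalize_over == "units":
            row_sums = n.sum(axis=1, keepdims=True)
            n_share = np.where(row_sums > 0, n / row_sums, np.nan)
        elif normalize_over == "bases":
            col_sums = n.sum(axis=0, keepdims=True)
            n_share = np.where(col_sums > 0, n / col_sums, np.nan)
        else:
            raise ValueError(f"unknown normalization {normalize_over!r}")
        p = n_share / t_share[np.newaxis, :]
    p[:, t == 0] = np.nan  # undefined, not zero

    presence = pd.Series(100.0 * t_share, index=table.T.index, name="presence_pct")
    return PropensityTable(
        P=pd.DataFrame(p, index=table.N.index, columns=table.N.columns),
        presence=presence,
    )


def presence_share(
    table: ContactTable, family: Literal["amino_acid", "monosaccharide"]
) -> pd.Series:
    """Per-unit share (%) of dataset contacts within one structural family."""
    if family == "amino_acid":
        members = [u for u in table.T.index if u in AMINO_ACIDS]
    elif family == KIND_MONOSACCHARIDE:
        members = [u for u in table.T.index if u not in AMINO_ACIDS]
    else:
        raise ValueError(f"unknown family {family!r}")
    sub = table.T.loc[members]
    total = sub.sum()
    if total == 0:
        raise ValueError(f"no contacts in family {family!r}")
    return 100.0 * sub / total
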