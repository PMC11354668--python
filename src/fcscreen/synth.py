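"""Deterministic generators for every input the pipeline consumes.

Toy antibody-like complexes use a simplified atom model (CA-only amino
acids, single-phosphorus nucleotides, single-ring-atom sugars): the contact
logic only needs heavy-atom coordinates.  Receptor residues sit on a coarse
grid whose spacing guarantees that exactly the planted ligand/site pairs
fall inside the default contact cutoff and every other pair is at least
2 Å beyond it — the planted truth is unambiguous by construction.

All generators are pure functions of their spec (seed included): the same
spec always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fcscreen.interface import DEFAULT_CUTOFF
from fcscreen.kinetics import (
    DEFAULT_CONCENTRATIONS_MG_ML,
    DEFAULT_MOLAR_MASS,
    Sensorgram,
    SensorgramStep,
    langmuir_response,
    mg_per_ml_to_molar,
)
from fcscreen.screening import BindingMode
from fcscreen.structure import (
    Atom,
    ComplexStructure,
    RegionMap,
    Residue,
    default_region_map,
    residue_kind,
)

#: Toy receptor skeleton: (chain, seq_num, residue name) covering every
#: region of the default map plus two short glycan chains.
RECEPTOR_SKELETON: tuple[tuple[str, int, str], ...] = (
    # light chains (VL / CL)
    ("A", 10, "ASP"), ("A", 50, "TYR"), ("A", 150, "SER"), ("A", 180, "LYS"),
    ("C", 10, "ASP"), ("C", 50, "TYR"), ("C", 150, "SER"), ("C", 180, "LYS"),
    # heavy chains (VH / CH1 / CH2 / CH3 / hinge)
    ("B", 10, "GLY"), ("B", 50, "SER"),
    ("B", 150, "PRO"), ("B", 200, "THR"),
    ("B", 250, "PRO"), ("B", 300, "LYS"), ("B", 310, "ILE"),
    ("B", 400, "GLU"), ("B", 423, "GLU"), ("B", 440, "TYR"),
    ("B", 460, "LYS"), ("B", 470, "LYS"),
    ("D", 10, "GLY"), ("D", 50, "SER"),
    ("D", 150, "PRO"), ("D", 200, "THR"),
    ("D", 250, "PRO"), ("D", 300, "LYS"), ("D", 310, "ILE"),
    ("D", 400, "GLU"), ("D", 423, "GLU"), ("D", 440, "TYR"),
    ("D", 460, "LYS"), ("D", 470, "LYS"),
    # glycan chains
    ("E", 1, "NAG"), ("E", 2, "NAG"), ("E", 3, "BMA"), ("E", 4, "MAN"),
    ("E", 5, "GAL"), ("E", 6, "FUC"),
    ("F", 1, "NAG"), ("F", 2, "NAG"), ("F", 3, "BMA"), ("F", 4, "MAN"),
)

#: Distance at which planted ligand bases sit from their target site (Å);
#: comfortably inside the 4.5 Å default cutoff even after jitter.
PLANTED_CONTACT_DISTANCE = 3.5
_JITTER = 0.05  # Å, uniform; small enough to never flip planted truth
_LIGAND_BASES = ("DG", "DT", "DA", "DC")


class SpecError(ValueError):
    """Raised when a generator spec is internally inconsistent."""


@dataclass(frozen=True)
class ComplexSpec:
    seed: int
    n_nucleotides: int
    planted_mode: BindingMode
    planted_contact_sites: tuple[tuple[str, int], ...]
    spacing: float = 25.0

    def __post_init__(self) -> None:
        if self.n_nucleotides < 1:
            raise SpecError("n_nucleotides must be >= 1")
        if len(self.planted_contact_sites) > self.n_nucleotides:
            raise SpecError("more planted sites than nucleotides")
        if self.spacing < 2.0 * (DEFAULT_CUTOFF + 2.0 + PLANTED_CONTACT_DISTANCE):
            raise SpecError(f"grid spacing {self.spacing} too small for unambiguous truth")
        _validate_mode_sites(self.planted_mode, self.planted_contact_sites)


def _validate_mode_sites(
    mode: BindingMode, sites: Sequence[tuple[str, int]], region_map: RegionMap | None = None
) -> None:
    region_map = region_map or default_region_map()
    skeleton = {(c, s): name for c, s, name in RECEPTOR_SKELETON}
    groupings: list[str] = []
    regions: list[str] = []
    for chain, seq in sites:
        if (chain, seq) not in skeleton:
            raise SpecError(f"planted site ({chain}, {seq}) not in the toy receptor skeleton")
        if residue_kind(skeleton[(chain, seq)]) == "monosaccharide":
            region = "glycan"
        else:
            region = region_map.region_of(chain, seq) or "unassigned"
        regions.append(region)
        groupings.append(RegionMap.grouping(region) or "unassigned")

    if not sites:
        raise SpecError("at least one planted contact site is required")
    if mode == BindingMode.FAB and not all(g == "Fab" for g in groupings):
        raise SpecError("FAB spec requires all planted sites in the Fab grouping")
    if mode == BindingMode.MODE1 and not all(g == "Fc" for g in groupings):
        raise SpecError("MODE1 spec requires all planted sites in the Fc grouping")
    if mode == BindingMode.MODE2 and not any(g == "hinge" for g in groupings):
        raise SpecError("MODE2 spec requires at least one hinge site")
    if mode == BindingMode.MODE3:
        n_fc = sum(g == "Fc" for g in groupings)
        rest = [r for r, g in zip(regions, groupings) if g != "Fc"]
        if n_fc == 0 or not rest or not set(rest) <= {"CH1", "CL"}:
            raise SpecError(
                "MODE3 spec requires a mix of Fc sites and CH1/CL sites only"
            )
        if n_fc / len(sites) < 0.5:
            raise SpecError("MODE3 spec requires a majority of Fc sites")


def _receptor_layout(spacing: float) -> dict[tuple[str, int], np.ndarray]:
    """Deterministic grid coordinates for every skeleton residue."""
    side = int(np.ceil(np.sqrt(len(RECEPTOR_SKELETON))))
    layout = {}
    for idx, (chain, seq, _) in enumerate(RECEPTOR_SKELETON):
        ix, iy = divmod(idx, side)
        layout[(chain, seq)] = np.array([ix * spacing, iy * spacing, 0.0])
    return layout


def make_toy_complex(
    spec: ComplexSpec, complex_id: str | None = None
) -> tuple[ComplexStructure, list[tuple[int, tuple[str, int]]]]:
    """Build a toy complex with planted contacts.

    Returns the structure plus the ground truth as a list of
    ``(ligand_seq_num, (receptor_chain, receptor_seq_num))`` pairs.
    Nucleotide *k* (1-based) is paired with planted site *k*; surplus
    nucleotides are parked far from every receptor atom.
    """
    rng = np.random.default_rng(spec.seed)
    layout = _receptor_layout(spec.spacing)

    def jitter() -> np.ndarray:
        return rng.uniform(-_JITTER, _JITTER, size=3)

    receptor: dict[str, list[Residue]] = {}
    glycans: dict[str, list[Residue]] = {}
    for chain, seq, name in RECEPTOR_SKELETON:
        kind = residue_kind(name)
        coords = layout[(chain, seq)] + jitter()
        if kind == "monosaccharide":
            atom = Atom(name="C1", element="C", coords=tuple(coords))
            glycans.setdefault(chain, []).append(Residue(chain, seq, name, kind, [atom]))
        else:
            atom = Atom(name="CA", element="C", coords=tuple(coords))
            receptor.setdefault(chain, []).append(Residue(chain, seq, name, kind, [atom]))

    ligand: list[Residue] = []
    truth: list[tuple[int, tuple[str, int]]] = []
    for k in range(1, spec.n_nucleotides + 1):
        base = _LIGAND_BASES[(k - 1) % len(_LIGAND_BASES)]
        if k <= len(spec.planted_contact_sites):
            chain, seq = spec.planted_contact_sites[k - 1]
            angle = 2.0 * np.pi * (k - 1) / max(spec.n_nucleotides, 1)
            direction = np.array([0.0, np.cos(angle) * 0.2, 1.0])
            direction /= np.linalg.norm(direction)
            coords = layout[(chain, seq)] + PLANTED_CONTACT_DISTANCE * direction
            truth.append((k, (chain, seq)))
        else:
            coords = np.array([-500.0 - 40.0 * k, -500.0, -500.0]) + jitter()
        ligand.append(
            Residue("L", k, base, "nucleotide", [Atom("P", "P", tuple(coords))])
        )

    structure = ComplexStructure(
        complex_id=complex_id or f"toy-seed{spec.seed}",
        receptor_chains=receptor,
        ligand_chain=ligand,
        glycan_chains=glycans,
    )
    return structure, truth


# -- ensembles ---------------------------------------------------------------

#: Site templates drawn from per mode when building ensembles.
_MODE_SITE_POOLS: dict[BindingMode, tuple[tuple[tuple[str, int], ...], ...]] = {
    BindingMode.FAB: (
        (("A", 10), ("B", 150)),
        (("C", 50), ("D", 200), ("A", 150)),
        (("B", 10), ("B", 50)),
    ),
    BindingMode.MODE1: (
        (("B", 250), ("B", 423), ("E", 1)),
        (("B", 300), ("B", 400), ("F", 3)),
        (("D", 250), ("D", 423), ("E", 4)),
        (("B", 423), ("D", 423)),
    ),
    BindingMode.MODE2: (
        (("B", 460), ("B", 250)),
        (("D", 470), ("D", 300)),
        (("B", 460),),
    ),
    BindingMode.MODE3: (
        (("B", 250), ("B", 300), ("B", 310), ("B", 400), ("B", 423), ("D", 250), ("E", 2), ("A", 150), ("C", 150), ("B", 150)),
        (("B", 250), ("B", 423), ("D", 300), ("D", 400), ("A", 150)),
    ),
}


def _largest_remainder_counts(n: int, proportions: Mapping[BindingMode, float]) -> dict[BindingMode, int]:
    raw = {m: n * p for m, p in proportions.items()}
    counts = {m: int(np.floor(v)) for m, v in raw.items()}
    shortfall = n - sum(counts.values())
    by_remainder = sorted(raw, key=lambda m: (raw[m] - counts[m], str(m)), reverse=True)
    for m in by_remainder[:shortfall]:
        counts[m] += 1
    return counts


def make_ensemble(
    n: int,
    mode_proportions: Mapping[BindingMode, float],
    seed: int,
) -> tuple[list[tuple[ComplexStructure, list[tuple[int, tuple[str, int]]], BindingMode]], pd.DataFrame]:
    """Generate ``n`` toy complexes with planted modes plus a pose-score table.

    Mode counts follow the proportions via largest-remainder rounding, so a
    share of 49/140 over n=140 yields exactly 49 complexes of that mode.
    Scores are uniform on [16, 33] (the magnitude range of typical rigid
    docking scores for this problem; the distribution itself is arbitrary).

    Returns ``(complexes, pose_table)`` where each complex entry is
    ``(structure, planted_truth, planted_mode)``.
    """
    if n <= 0:
        raise SpecError("ensemble size must be positive")
    total = sum(mode_proportions.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise SpecError(f"mode proportions must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(n, mode_proportions)
    modes: list[BindingMode] = []
    for mode in sorted(counts, key=str):
        modes.extend([mode] * counts[mode])
    order = rng.permutation(len(modes))
    modes = [modes[i] for i in order]

    complexes = []
    rows = []
    for i, mode in enumerate(modes, start=1):
        pool = _MODE_SITE_POOLS[mode]
        sites = pool[int(rng.integers(len(pool)))]
        n_nt = max(len(sites), 8)
        spec = ComplexSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_nucleotides=n_nt,
            planted_mode=mode,
            planted_contact_sites=tuple(sites),
        )
        ligand_id = f"L{i:03d}"
        structure, truth = make_toy_complex(spec, complex_id=ligand_id)
        complexes.append((structure, truth, mode))
        rows.append(
            {
                "ligand_id": ligand_id,
                "pose_rank": 1,
                "zdock_score": round(float(rng.uniform(16.0, 33.0)), 2),
            }
        )
    pose_table = pd.DataFrame(rows, columns=["ligand_id", "pose_rank", "zdock_score"])
    return complexes, pose_table


# -- sensorgrams -------------------------------------------------------------


@dataclass(frozen=True)
class SensorgramSpec:
    seed: int
    k_on: float
    k_dis: float
    r_max: float
    concentrations_mg_ml: tuple[float, ...] = DEFAULT_CONCENTRATIONS_MG_ML
    noise_sigma: float = 0.0
    drift: float = 0.0  # nm/s, linear, applied across each cycle
    phase_duration: float = 300.0  # association and dissociation, s
    baseline_duration: float = 60.0
    dt: float = 1.0
    molar_mass: float = DEFAULT_MOLAR_MASS
    include_regeneration: bool = False

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SpecError("noise sigma must be >= 0")
        if self.k_on <= 0 or self.k_dis <= 0 or self.r_max <= 0:
            raise SpecError("kinetic truth parameters must be positive")
        if self.phase_duration <= 0 or self.dt <= 0:
            raise SpecError("durations must be positive")


def simulate_sensorgram(spec: SensorgramSpec, ligand_id: str = "synthetic") -> Sensorgram:
    """Simulate a multi-concentration association/dissociation sensorgram.

    Each concentration cycle is baseline → association → dissociation
    (→ regeneration when requested); the sensor is reset between cycles.
    Gaussian noise and optional linear drift are added on top of the exact
    1:1 closed forms.
    """
    rng = np.random.default_rng(spec.seed)
    steps: list[SensorgramStep] = []

    def noisy(values: np.ndarray, times: np.ndarray, t_offset: float) -> np.ndarray:
        out = values + spec.drift * (t_offset + times)
        if spec.noise_sigma > 0:
            out = out + rng.normal(0.0, spec.noise_sigma, size=values.shape)
        return out

    t_phase = np.arange(0.0, spec.phase_duration + spec.dt / 2, spec.dt)
    t_base = np.arange(0.0, spec.baseline_duration + spec.dt / 2, spec.dt)

    for c_mg in spec.concentrations_mg_ml:
        c_molar = mg_per_ml_to_molar(c_mg, spec.molar_mass)
        steps.append(
            SensorgramStep(
                phase="baseline",
                concentration=0.0,
                times=t_base,
                responses=noisy(np.zeros_like(t_base), t_base, 0.0),
                concentration_mg_ml=0.0,
            )
        )
        assoc = langmuir_response(
            t_phase, c_molar, spec.k_on, spec.k_dis, spec.r_max, "association"
        )
        steps.append(
            SensorgramStep(
                phase="association",
                concentration=c_molar,
                times=t_phase,
                responses=noisy(np.asarray(assoc), t_phase, spec.baseline_duration),
                concentration_mg_ml=c_mg,
            )
        )
        r0 = float(
            langmuir_response(
                spec.phase_duration, c_molar, spec.k_on, spec.k_dis, spec.r_max, "association"
            )
        )
        dissoc = langmuir_response(
            t_phase, 0.0, spec.k_on, spec.k_dis, spec.r_max, "dissociation", r0=r0
        )
        steps.append(
            SensorgramStep(
                phase="dissociation",
                concentration=0.0,
                times=t_phase,
                responses=noisy(
                    np.asarray(dissoc), t_phase, spec.baseline_duration + spec.phase_duration
                ),
                concentration_mg_ml=0.0,
            )
        )
        if spec.include_regeneration:
            t_regen = np.arange(0.0, 20.0 + spec.dt / 2, spec.dt)
            steps.append(
                SensorgramStep(
                    phase="regeneration",
                    concentration=0.0,
                    times=t_regen,
                    responses=np.zeros_like(t_regen),
                    concentration_mg_ml=0.0,
                )
            )
    return Sensorgram(ligand_id=ligand_id, steps=steps)
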