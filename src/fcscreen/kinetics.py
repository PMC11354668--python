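"""1:1 Langmuir BLI kinetics: closed forms, global fitting, and decision rules.

The binding model is the standard 1:1 scheme

    dR/dt = k_on * C * (R_max - R) - k_dis * R

whose association phase from R(0) = 0 has the closed form

    R(t) = R_eq * (1 - exp(-(k_on*C + k_dis) * t)),
    R_eq = R_max * k_on * C / (k_on * C + k_dis)

and whose dissociation phase from level R0 is R(t) = R0 * exp(-k_dis * t).
The equilibrium dissociation constant is K_D = k_dis / k_on (units 1/Ms,
1/s, M).  Fitting is a global nonlinear least squares over every
association/dissociation phase of a concentration series, sharing
(k_on, k_dis, R_max).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

PHASES = ("baseline", "loading", "association", "dissociation", "regeneration")

DEFAULT_MOLAR_MASS = 150_000.0  # IgG, g/mol
DEFAULT_CONCENTRATIONS_MG_ML = (0.0125, 0.025, 0.05, 0.1, 0.2)
DEFAULT_BINDING_THRESHOLD_NM = 0.02
DEFAULT_R2_MIN = 0.85


class KineticFitError(RuntimeError):
    """Raised when the global fit fails to converge or has no usable data."""


def mg_per_ml_to_molar(c_mg_ml: float, molar_mass: float = DEFAULT_MOLAR_MASS) -> float:
    """Convert an analyte concentration from mg/mL to mol/L.

    1 mg/mL = 1 g/L, so M = c / molar_mass.
    """
    if c_mg_ml <= 0:
        raise ValueError(f"concentration must be positive, got {c_mg_ml}")
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    return c_mg_ml / molar_mass


def compute_kd(k_on: float, k_dis: float) -> float:
    """Equilibrium dissociation constant K_D = k_dis / k_on (M)."""
    if k_on <= 0:
        raise ValueError(f"k_on must be positive, got {k_on}")
    if k_dis < 0:
        raise ValueError(f"k_dis must be non-negative, got {k_dis}")
    return k_dis / k_on


def langmuir_response(
    t: np.ndarray | float,
    concentration: float,
    k_on: float,
    k_dis: float,
    r_max: float,
    phase: Literal["association", "dissociation"],
    r0: float = 0.0,
) -> np.ndarray | float:
    """Closed-form 1:1 response at time ``t`` (seconds from phase start)."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if k_on <= 0 or k_dis < 0 or r_max <= 0:
        raise ValueError("kinetic parameters must be positive (k_dis may be 0)")
    t = np.asarray(t, dtype=float)
    if phase == "association":
        k_obs = k_on * concentration + k_dis
        r_eq = r_max * k_on * concentration / k_obs if k_obs > 0 else 0.0
        return r_eq * (1.0 - np.exp(-k_obs * t))
    if phase == "dissociation":
        return r0 * np.exp(-k_dis * t)
    raise ValueError(f"phase must be association or dissociation, got {phase!r}")


@dataclass
class SensorgramStep:
    """One instrument phase: times (s, strictly increasing) and responses (nm).

    ``concentration`` is the analyte molarity during the step (0 for
    dissociation/baseline); ``concentration_mg_ml`` is kept for serialization.
    """

    phase: str
    concentration: float
    times: np.ndarray
    responses: np.ndarray
    concentration_mg_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.shape != self.responses.shape:
            raise ValueError("times and responses must have equal length")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing within a step")


@dataclass
class Sensorgram:
    ligand_id: str
    steps: list[SensorgramStep] = field(default_factory=list)

    def association_steps(self) -> list[SensorgramStep]:
        return [s for s in self.steps if s.phase == "association"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, step in enumerate(self.steps):
            rows.append(
                pd.DataFrame(
                    {
                        "step_index": i,
                        "phase": step.phase,
                        "concentration_mg_ml": step.concentration_mg_ml,
                        "time_s": step.times,
                        "response_nm": step.responses,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        ligand_id: str | None = None,
        molar_mass: float = DEFAULT_MOLAR_MASS,
    ) -> "Sensorgram":
        df = pd.read_csv(path)
        required = {"step_index", "phase", "concentration_mg_ml", "time_s", "response_nm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sensorgram CSV {path} missing columns: {sorted(missing)}")
        steps = []
        for _, group in df.groupby("step_index", sort=True):
            c_mg = float(group["concentration_mg_ml"].iloc[0])
            steps.append(
                SensorgramStep(
                    phase=str(group["phase"].iloc[0]),
                    concentration=mg_per_ml_to_molar(c_mg, molar_mass) if c_mg > 0 else 0.0,
                    times=group["time_s"].to_numpy(),
                    responses=group["response_nm"].to_numpy(),
                    concentration_mg_ml=c_mg,
                )
            )
        name = ligand_id if ligand_id is not None else Path(path).stem
        return cls(ligand_id=name, steps=steps)


@dataclass
class AssayConfig:
    molar_mass: float = DEFAULT_MOLAR_MASS
    concentrations_mg_ml: tuple[float, ...] = DEFAULT_CONCENTRATIONS_MG_ML
    binding_call_threshold: float = DEFAULT_BINDING_THRESHOLD_NM
    r2_min: float = DEFAULT_R2_MIN

    def __post_init__(self) -> None:
        if self.binding_call_threshold <= 0:
            raise ValueError("binding_call_threshold must be positive")
        cs = tuple(float(c) for c in self.concentrations_mg_ml)
        if any(c <= 0 for c in cs) or len(set(cs)) != len(cs):
            raise ValueError("concentrations must be positive and distinct")
        self.concentrations_mg_ml = cs

    @classmethod
    def from_yaml(cls, text: str) -> "AssayConfig":
        import yaml

        payload = yaml.safe_load(text) or {}
        return cls(**payload)


@dataclass
class KineticFit:
    k_on: float
    k_dis: float
    k_d: float
    r_max: float
    r_squared: float
    reliable: bool

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_dis <= 0 or self.k_d <= 0:
            raise ValueError("fitted rate constants must be positive")
        if not math.isclose(self.k_d, self.k_dis / self.k_on, rel_tol=1e-12):
            raise ValueError("K_D must equal k_dis / k_on")


# -- fitting ----------------------------------------------------------------

_FIT_X0 = (1e4, 1e-3)  # k_on, k_dis initial guesses
_FIT_BOUNDS_LO = (1.0, 1e-7, 1e-6)
_FIT_BOUNDS_HI = (1e9, 1.0, 10.0)


def _zeroed_cycles(sensorgram: Sensorgram) -> list[tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Extract (C, t_assoc, r_assoc, t_dissoc, r_dissoc) cycles, baseline-zeroed.

    Each association step is zeroed to the mean of the final second of the
    preceding baseline step (if any); its paired dissociation step, when
    present, shares the same offset.  Regeneration and loading steps are
    parsed but never fitted.
    """
    cycles = []
    last_baseline_offset = 0.0
    steps = sensorgram.steps
    i = 0
    while i < len(steps):
        step = steps[i]
        if step.phase == "baseline" and step.times.size:
            tail = step.times >= step.times[-1] - 1.0
            last_baseline_offset = float(step.responses[tail].mean())
        elif step.phase == "association":
            t0 = step.times - step.times[0]
            r = step.responses - last_baseline_offset
            t_d = np.empty(0)
            r_d = np.empty(0)
            if i + 1 < len(steps) and steps[i + 1].phase == "dissociation":
                nxt = steps[i + 1]
                t_d = nxt.times - nxt.times[0]
                r_d = nxt.responses - last_baseline_offset
                i += 1
            cycles.append((step.concentration, t0, r, t_d, r_d))
        i += 1
    return cycles


def fit_kinetics(sensorgram: Sensorgram, config: AssayConfig | None = None) -> KineticFit:
    """Globally fit (k_on, k_dis, R_max) across a concentration series.

    Requires association phases at two or more distinct concentrations.  The
    modeled dissociation phase continues from the model's association
    endpoint, enforcing curve continuity.  Raises :class:`KineticFitError`
    when the optimizer does not converge.
    """
    config = config or AssayConfig()
    cycles = _zeroed_cycles(sensorgram)
    concentrations = {c for c, *_ in cycles if c > 0}
    if len(concentrations) < 2:
        raise KineticFitError(
            f"{sensorgram.ligand_id}: need association data at >=2 concentrations, "
            f"got {len(concentrations)}"
        )

    observed = np.concatenate(
        [np.concatenate([r, r_d]) for _, _, r, _, r_d in cycles]
    )

    def model(params: np.ndarray) -> np.ndarray:
        k_on, k_dis, r_max = params
        parts = []
        for c, t_a, _, t_d, _ in cycles:
            r_a = langmuir_response(t_a, c, k_on, k_dis, r_max, "association")
            parts.append(np.atleast_1d(r_a))
            if t_d.size:
                duration = t_a[-1] if t_a.size else 0.0
                r0 = float(
                    langmuir_response(duration, c, k_on, k_dis, r_max, "association")
                )
                parts.append(
                    np.atleast_1d(
                        langmuir_response(t_d, 0.0, k_on, k_dis, r_max, "dissociation", r0=r0)
                    )
                )
        return np.concatenate(parts)

    r_max0 = float(max(np.max(observed), 1e-3))
    x0 = np.array([*_FIT_X0, r_max0])
    result = least_squares(
        lambda p: model(p) - observed,
        x0=x0,
        bounds=(_FIT_BOUNDS_LO, _FIT_BOUNDS_HI),
        x_scale=np.abs(x0),
        method="trf",
        max_nfev=5000,
    )
    if not result.success:
        raise KineticFitError(f"{sensorgram.ligand_id}: fit did not converge ({result.message})")

    k_on, k_dis, r_max = (float(v) for v in result.x)
    residuals = model(result.x) - observed
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    reliable = r_squared >= config.r2_min
    if not reliable:
        logger.warning(
            "%s: fit R^2 = %.4f below reliability floor %.2f",
            sensorgram.ligand_id, r_squared, config.r2_min,
        )
    return KineticFit(
        k_on=k_on,
        k_dis=k_dis,
        k_d=compute_kd(k_on, k_dis),
        r_max=r_max,
        r_squared=r_squared,
        reliable=reliable,
    )


# -- decision rules ---------------------------------------------------------


def binding_call(step: SensorgramStep, config: AssayConfig | None = None) -> str:
    """'bound' iff the association step's maximum response meets the threshold.

    The threshold (default 0.02 nm) is inclusive.
    """
    config = config or AssayConfig()
    if step.phase != "association":
        raise ValueError(f"binding_call expects an association step, got {step.phase!r}")
    if step.responses.size == 0:
        raise ValueError("binding_call requires a non-empty association step")
    return "bound" if float(step.responses.max()) >= config.binding_call_threshold else "not_bound"


def competition_call(
    steps: Sequence[SensorgramStep], config: AssayConfig | None = None
) -> str:
    """Competition decision for a probe-capture-ligand step sequence.

    The last association step is the challenge (ssDNA ligand) step; the
    preceding association step is the antibody capture.  'competes' iff the
    challenge step's absolute signal change from its own starting level meets
    the binding threshold (extra binding or displacement); otherwise
    'no_competition' — the challenger shares the probe's binding site.
    """
    config = config or AssayConfig()
    assoc_indices = [i for i, s in enumerate(steps) if s.phase == "association"]
    if len(assoc_indices) < 2:
        raise ValueError(
            "competition_call needs a capture step followed by a challenge step"
        )
    challenge = steps[assoc_indices[-1]]
    if challenge.responses.size == 0:
        raise ValueError("challenge step is empty")
    delta = challenge.responses - challenge.responses[0]
    return (
        "competes"
        if float(np.max(np.abs(delta))) >= config.binding_call_threshold
        else "no_competition"
    )


# -- reference constants ----------------------------------------------------


def load_affinity_constants() -> pd.DataFrame:
    """Published per-ligand kinetic constants bundled with the package.

    Columns: table, ligand_id, group, k_on_per_M_s, k_dis_per_s,
    k_d_reported_M, r_squared.  Rows without numbers are 'No response'
    ligands.
    """
    with resources.files("fcscreen.data").joinpath("affinity_constants.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
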