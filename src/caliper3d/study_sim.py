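"""Simulated observer study: protocol, tool models, measurement records.

The protocol mirrors a multi-reader comparison of linear-measurement tools
on 3D echocardiography: each participant measures the horizontal and
vertical diameters of three calibration-phantom cysts (4, 6, 10 mm → 6
tasks) and five standard dimensions on each of four congenital-heart
patient datasets (20 tasks), 26 measurements in all.

Observer error is modelled at the *endpoints*: each caliper endpoint is
perturbed by isotropic Gaussian noise of the tool's sigma, because the
dominant human error is edge localisation when placing a marker.  The
perturbed chord length then gets the tool's additive bias and is quantized
to its display precision (0.1 mm for the MPR reference tool and the
immersive tool, 1 mm for the screen-based volume-rendering tool).
Endpoint noise induces the physically correct positive length bias for
short distances, which a length-level noise model would miss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rounding import round_to_multiple

__all__ = [
    "Task",
    "SessionPlan",
    "ToolModel",
    "MeasurementRecord",
    "build_session_plan",
    "default_tool_models",
    "default_truths",
    "quantize",
    "simulate_observer",
    "records_to_dataframe",
    "write_records",
    "read_records",
    "PATIENT_MEASUREMENTS",
    "PHANTOM_DIAMETERS_MM",
]

#: The five standard patient measurements: (name, view/window, cardiac phase).
PATIENT_MEASUREMENTS: tuple[tuple[str, str, str], ...] = (
    ("aortic valve hingepoint", "parasternal long axis view", "systole"),
    ("left atrial dimension", "parasternal long axis view", "systole"),
    ("left ventricular end diastolic dimension", "short axis view", "diastole"),
    ("left ventricular end systolic dimension", "short axis view",
     "end systolic MV closed"),
    ("aortic end systolic dimension", "short axis view",
     "end systolic MV closed"),
)

#: Cyst diameters of the calibration phantom, mm.
PHANTOM_DIAMETERS_MM: tuple[float, ...] = (4.0, 6.0, 10.0)

#: Default participant ids (five readers).
DEFAULT_PARTICIPANTS: tuple[str, ...] = tuple(f"user{i}" for i in range(1, 6))


@dataclass(frozen=True)
class Task:
    """One measurement task of the protocol."""

    dataset: str
    dataset_type: str  # "phantom" | "patient"
    view: str
    phase: str
    measurement: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.dataset, self.measurement)


@dataclass
class SessionPlan:
    """The ordered task list every participant works through."""

    tasks: list[Task]
    participants: list[str] = field(
        default_factory=lambda: list(DEFAULT_PARTICIPANTS))

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.tasks])


def build_session_plan(n_patients: int = 4, include_phantom: bool = True,
                       participants=DEFAULT_PARTICIPANTS) -> SessionPlan:
    """Enumerate the protocol tasks.

    Defaults give 26 tasks per participant: 6 phantom (3 cyst sizes x H/V)
    plus 5 dimensions on each of 4 patient datasets.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    tasks: list[Task] = []
    if include_phantom:
        for d in PHANTOM_DIAMETERS_MM:
            for axis in ("H", "V"):
                tasks.append(Task(
                    dataset="phantom", dataset_type="phantom",
                    view="N/A", phase="N/A",
                    measurement=f"cyst {d:g} mm {axis} diameter"))
    for p in range(1, n_patients + 1):
        for name, view, phase in PATIENT_MEASUREMENTS:
            tasks.append(Task(dataset=f"patient{p}", dataset_type="patient",
                              view=view, phase=phase, measurement=name))
    return SessionPlan(tasks=tasks, participants=list(participants))


@dataclass(frozen=True)
class ToolModel:
    """Error model of one measurement tool.

    ``endpoint_sigma_mm`` is the SD of the isotropic Gaussian perturbation
    applied to each caliper endpoint; ``display_precision_mm`` the rounding
    granularity of the reported value; ``bias_mm`` an additive systematic
    offset of the reported length.
    """

    name: str
    endpoint_sigma_mm: float
    display_precision_mm: float
    bias_mm: float = 0.0

    def __post_init__(self):
        if self.endpoint_sigma_mm < 0:
            raise ValueError("endpoint sigma must be non-negative")
        if self.display_precision_mm <= 0:
            raise ValueError("display precision must be positive")

    def with_bias(self, bias_mm: float) -> "ToolModel":
        return replace(self, bias_mm=bias_mm)


def default_tool_models() -> list[ToolModel]:
    """The three tools of the comparison.

    Display precisions are the tools' stated granularities.  Endpoint
    sigmas are calibrated so simulated per-task SDs across readers fall in
    the 0.2-1.9 mm range seen in practice (MPR reference most precise,
    immersive tool least); the screen-based 3D tool carries a -1.57 mm bias
    and the immersive tool a +0.36 mm bias, matching the systematic offsets
    such comparisons report.  These are emulation parameters, not
    ground-truth properties of any product.
    """
    return [
        ToolModel("QLAB", endpoint_sigma_mm=0.25, display_precision_mm=0.1),
        ToolModel("Tomtec", endpoint_sigma_mm=0.45, display_precision_mm=1.0,
                  bias_mm=-1.57),
        ToolModel("VR", endpoint_sigma_mm=0.70, display_precision_mm=0.1,
                  bias_mm=0.36),
    ]


# Plausible congenital-heart dimensions (mm) for four patients of
# increasing size, one value per patient measurement, in the order of
# PATIENT_MEASUREMENTS.  Chosen so the pooled patient truths have a mean
# near 28 mm with an SD near 13 mm, the scale typical of such studies.
_PATIENT_TRUTHS_MM: dict[str, tuple[float, ...]] = {
    "patient1": (14.2, 22.8, 24.5, 16.3, 13.1),
    "patient2": (17.6, 30.4, 38.2, 24.9, 18.7),
    "patient3": (21.3, 36.8, 46.9, 30.6, 22.4),
    "patient4": (24.8, 43.5, 54.6, 36.2, 26.9),
}


def default_truths(plan: SessionPlan) -> dict[tuple[str, str], float]:
    """True lengths (mm) for every task of a plan.

    Phantom truths are the nominal cyst diameters; patient truths come from
    a fixed table of plausible dimensions.  Patient datasets beyond the
    built-in four reuse the table cyclically.
    """
    truths: dict[tuple[str, str], float] = {}
    names = [m[0] for m in PATIENT_MEASUREMENTS]
    table = list(_PATIENT_TRUTHS_MM.values())
    for task in plan.tasks:
        if task.dataset_type == "phantom":
            # measurement text is "cyst <d> mm <axis> diameter"
            truths[task.key] = float(task.measurement.split()[1])
        else:
            p_index = int(task.dataset.removeprefix("patient")) - 1
            truths[task.key] = table[p_index % len(table)][
                names.index(task.measurement)]
    return truths


def quantize(value_mm: float, precision_mm: float) -> float:
    """Nearest multiple of the display precision, ties away from zero."""
    return round_to_multiple(value_mm, precision_mm)


@dataclass
class MeasurementRecord:
    """One recorded measurement: who, with what, on what, and the value."""

    user: str
    tool: str
    dataset: str
    measurement: str
    value_mm: float
    valid: bool = True


def simulate_observer(plan: SessionPlan,
                      truth: dict[tuple[str, str], float],
                      tools: list[ToolModel],
                      seed: int,
                      n_invalid: int = 0) -> list[MeasurementRecord]:
    """Simulate every (participant, tool, task) measurement.

    For each record a segment of the true length is laid out, both endpoints
    are perturbed by the tool's isotropic endpoint noise, the perturbed
    chord length gets the tool's bias and is quantized to its display
    precision.  ``n_invalid`` records are then marked invalid uniformly at
    random without replacement (incorrectly recorded observations that an
    analysis must drop).  Deterministic given ``seed``.
    """
    missing = [t.key for t in plan.tasks if t.key not in truth]
    if missing:
        raise ValueError(f"truth missing for tasks: {missing[:3]}...")
    rng = np.random.default_rng(seed)
    records: list[MeasurementRecord] = []
    for user in plan.participants:
        for tool in tools:
            for task in plan.tasks:
                length = truth[task.key]
                p1 = rng.normal(0.0, tool.endpoint_sigma_mm, 3)
                p2 = np.array([length, 0.0, 0.0]) + rng.normal(
                    0.0, tool.endpoint_sigma_mm, 3)
                value = float(np.linalg.norm(p2 - p1)) + tool.bias_mm
                if value < 0:
                    warnings.warn(
                        f"negative simulated length for {task.key}; clipped to 0",
                        stacklevel=2)
                    value = 0.0
                records.append(MeasurementRecord(
                    user=user, tool=tool.name, dataset=task.dataset,
                    measurement=task.measurement,
                    value_mm=quantize(value, tool.display_precision_mm)))
    if n_invalid:
        if n_invalid > len(records):
            raise ValueError("cannot invalidate more records than exist")
        for idx in rng.choice(len(records), size=n_invalid, replace=False):
            records[idx].valid = False
    return records


def records_to_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records],
                        columns=["user", "tool", "dataset", "measurement",
                                 "value_mm", "valid"])


def write_records(records, path) -> None:
    """Write records as a tab-delimited table (the eval-stats input format)."""
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"user", "tool", "dataset", "measurement", "value_mm", "valid"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"records table {path!r} missing columns {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df
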