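"""Synthetic three-level hierarchical data with a binary remission outcome.

Emulates a lung-cancer remission study in which patients are nested in
doctors and doctors are nested in hospitals.  The outcome is drawn from a
random-intercept logistic model

    logit P(remission=1) = intercept + sum_j beta_j (x_j - c_j)
                           + u_doctor + u_hospital,

with u_doctor ~ N(0, sd_doctor^2) and u_hospital ~ N(0, sd_hospital^2).
Covariates are centred at fixed nominal values ``c_j`` so that the
intercept controls prevalence independently of the covariate scales.

The default roster has 26 predictors: patient-level clinical measures,
doctor-level attributes (constant within doctor), one hospital-level
attribute, and the two cluster identifiers DID and HID, which are
legitimate candidate predictors here (the patient identifier ID never is).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableMeta",
    "HierarchyConfig",
    "EffectSpec",
    "Dataset",
    "roster_default",
    "default_effects",
    "generate_hierarchy",
]

OUTCOME = "remission"

VALID_KINDS = ("continuous", "binary", "ordinal", "categorical", "cluster-id")


@dataclass(frozen=True)
class VariableMeta:
    """Name, measurement kind, and (for discrete kinds) the level codes."""

    name: str
    kind: str
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")


@dataclass(frozen=True)
class HierarchyConfig:
    """Shape of the hospital -> doctor -> patient hierarchy."""

    n_hospitals: int = 35
    doctors_per_hospital: tuple[int, int] = (8, 15)
    patients_per_doctor: tuple[int, int] = (2, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        for lo, hi in (self.doctors_per_hospital, self.patients_per_doctor):
            if not (1 <= lo <= hi):
                raise ValueError("cluster-size interval must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class EffectSpec:
    """Fixed effects (logit scale) and random-intercept standard deviations."""

    fixed_effects: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    sd_doctor: float = 0.0
    sd_hospital: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_doctor < 0 or self.sd_hospital < 0:
            raise ValueError("random-intercept standard deviations must be >= 0")


def roster_default() -> list[VariableMeta]:
    """The 26-predictor roster (patient ID is excluded; DID/HID are kept)."""
    smoking = ("never", "former", "current")
    return [
        VariableMeta("tumorsize", "continuous"),
        VariableMeta("co2", "continuous"),
        VariableMeta("pain", "ordinal", tuple(range(1, 10))),
        VariableMeta("wound", "ordinal", tuple(range(1, 10))),
        VariableMeta("mobility", "ordinal", tuple(range(1, 10))),
        VariableMeta("ntumors", "ordinal", tuple(range(0, 10))),
        VariableMeta("nmorphine", "continuous"),
        VariableMeta("lungcapacity", "continuous"),
        VariableMeta("Age", "continuous"),
        VariableMeta("Married", "binary", (0, 1)),
        VariableMeta("FamilyHx", "binary", (0, 1)),
        VariableMeta("SmokingHx", "categorical", (1, 2, 3)),  # codes for never/former/current
        VariableMeta("Sex", "binary", (0, 1)),
        VariableMeta("CancerStage", "ordinal", (1, 2, 3, 4)),
        VariableMeta("LengthofStay", "continuous"),
        VariableMeta("WBC", "continuous"),
        VariableMeta("RBC", "continuous"),
        VariableMeta("BMI", "continuous"),
        VariableMeta("IL6", "continuous"),
        VariableMeta("CRP", "continuous"),
        VariableMeta("Experience", "continuous"),
        VariableMeta("School", "binary", (0, 1)),
        VariableMeta("Lawsuits", "ordinal", tuple(range(0, 10))),
        VariableMeta("Medicaid", "continuous"),
        VariableMeta("DID", "cluster-id"),
        VariableMeta("HID", "cluster-id"),
    ]


# Nominal centres used when applying fixed effects, so the intercept sets
# prevalence.  They match the marginal means of the sampling scheme below.
_CENTERS = {
    "tumorsize": 70.0, "co2": 1.6, "pain": 5.0, "wound": 5.0, "mobility": 5.0,
    "ntumors": 3.0, "nmorphine": 3.0, "lungcapacity": 0.75, "Age": 51.0,
    "Married": 0.6, "FamilyHx": 0.2, "SmokingHx": 1.8, "Sex": 0.5,
    "CancerStage": 2.3, "LengthofStay": 5.5, "WBC": 6.0, "RBC": 5.0,
    "BMI": 25.5, "IL6": 4.0, "CRP": 5.0, "Experience": 18.0, "School": 0.5,
    "Lawsuits": 1.8, "Medicaid": 0.5,
}


def default_effects() -> EffectSpec:
    """Default data-generating effects for the simulation study.

    Six predictors carry moderate fixed effects; the dominant source of
    outcome structure is the doctor-level random intercept (sd 2.0, with
    hospital sd 0.5 — the values multilevel fits of the well-known
    hospital-doctor-patient teaching dataset report), which makes the
    cluster identifiers and the doctor-level covariates genuinely
    informative.  Remission prevalence comes out near 0.30; see
    docs/methods.md for the calibration rationale.
    """
    return EffectSpec(
        fixed_effects={
            "CancerStage": -0.45,
            "Experience": 0.12,
            "mobility": -0.22,
            "FamilyHx": -0.9,
            "LengthofStay": -0.25,
            "SmokingHx": -0.45,
        },
        intercept=-1.3,
        sd_doctor=2.0,
        sd_hospital=0.5,
    )


@dataclass
class Dataset:
    """A subject-by-variable table plus variable metadata.

    ``frame`` holds one row per patient with an ``ID`` column (never a
    predictor), the predictor columns, and the binary outcome column.
    """

    frame: pd.DataFrame
    variables: list[VariableMeta]
    outcome_name: str = OUTCOME

    @property
    def predictor_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def n(self) -> int:
        return len(self.frame)

    def meta(self, name: str) -> VariableMeta:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def validate(self) -> None:
        names = self.predictor_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names")
        if "ID" in names:
            raise ValueError("patient identifier ID must not be a predictor")
        missing = [c for c in names + [self.outcome_name] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"columns missing from frame: {missing}")
        y = self.frame[self.outcome_name]
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("outcome must be coded 0/1")
        if y.nunique() < 2:
            raise ValueError("outcome must contain both classes")
        if {"DID", "HID"} <= set(self.frame.columns):
            per_doctor = self.frame.groupby("DID")["HID"].nunique()
            if (per_doctor > 1).any():
                raise ValueError("DID values must be nested within HID values")

    def subset_rows(self, index) -> "Dataset":
        return Dataset(self.frame.loc[index].copy(), list(self.variables), self.outcome_name)

    # -- plain-text round trip -------------------------------------------
    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        meta = {
            "outcome": self.outcome_name,
            "variables": [
                {"name": v.name, "kind": v.kind,
                 "levels": list(v.levels) if v.levels is not None else None}
                for v in self.variables
            ],
        }
        meta_path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, meta_path: str | Path | None = None) -> "Dataset":
        path = Path(path)
        frame = pd.read_csv(path)
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text())
        variables = [
            VariableMeta(d["name"], d["kind"],
                         tuple(d["levels"]) if d.get("levels") is not None else None)
            for d in meta["variables"]
        ]
        ds = cls(frame, variables, meta.get("outcome", OUTCOME))
        ds.validate()
        return ds


def _ordinal_scores(rng: np.random.Generator, n: int, levels: Sequence,
                    p: float) -> np.ndarray:
    """Symmetric-ish discrete scores over ``levels`` via a binomial draw."""
    k = len(levels)
    idx = rng.binomial(k - 1, p, size=n)
    return np.asarray(levels)[idx]


def _draw_predictors(rng: np.random.Generator, hid: np.ndarray, did: np.ndarray,
                     n: int) -> pd.DataFrame:
    """Draw the default roster's covariates at their proper hierarchy level."""
    hospitals = np.unique(hid)
    doctors = np.unique(did)

    # hospital-level: share of Medicaid patients
    medicaid = dict(zip(hospitals, rng.beta(4, 4, size=len(hospitals))))
    # doctor-level attributes, constant within doctor
    experience = dict(zip(doctors, np.round(rng.normal(18.0, 4.0, size=len(doctors)), 1)))
    school = dict(zip(doctors, rng.integers(0, 2, size=len(doctors))))
    lawsuits = dict(zip(doctors, np.minimum(rng.poisson(1.8, size=len(doctors)), 9)))

    cols = {
        "tumorsize": rng.normal(70.0, 10.0, n),
        "co2": rng.normal(1.6, 0.1, n),
        "pain": _ordinal_scores(rng, n, range(1, 10), 0.5),
        "wound": _ordinal_scores(rng, n, range(1, 10), 0.5),
        "mobility": _ordinal_scores(rng, n, range(1, 10), 0.5),
        "ntumors": _ordinal_scores(rng, n, range(0, 10), 1 / 3),
        "nmorphine": np.clip(np.round(rng.normal(3.0, 2.0, n)), 0, None),
        "lungcapacity": np.clip(rng.normal(0.75, 0.12, n), 0.05, 1.0),
        "Age": np.round(rng.normal(51.0, 6.0, n), 1),
        "Married": rng.binomial(1, 0.6, n),
        "FamilyHx": rng.binomial(1, 0.2, n),
        "SmokingHx": rng.choice([1, 2, 3], size=n, p=[0.5, 0.2, 0.3]),
        "Sex": rng.binomial(1, 0.5, n),
        "CancerStage": rng.choice([1, 2, 3, 4], size=n, p=[0.25, 0.35, 0.25, 0.15]),
        "LengthofStay": np.clip(np.round(rng.normal(5.5, 1.5, n)), 1, 10),
        "WBC": np.round(rng.normal(6.0, 1.0, n), 2),
        "RBC": np.round(rng.normal(5.0, 0.4, n), 2),
        "BMI": np.round(rng.normal(25.5, 2.0, n), 1),
        "IL6": np.round(rng.gamma(2.0, 2.0, n), 2),
        "CRP": np.round(rng.gamma(2.5, 2.0, n), 2),
        "Experience": np.array([experience[d] for d in did]),
        "School": np.array([school[d] for d in did]),
        "Lawsuits": np.array([lawsuits[d] for d in did]),
        "Medicaid": np.round(np.array([medicaid[h] for h in hid]), 3),
        "DID": did,
        "HID": hid,
    }
    return pd.DataFrame(cols)


def generate_hierarchy(config: HierarchyConfig, effects: EffectSpec,
                       max_attempts: int = 5) -> Dataset:
    """Generate one hierarchical dataset under the random-intercept model.

    Doctor counts per hospital and patient counts per doctor are uniform
    integer draws over the configured inclusive ranges.  A draw whose
    outcome is single-class is retried with a derived seed up to
    ``max_attempts`` times, then raises ``RuntimeError``.
    """
    roster = roster_default()
    roster_names = {v.name for v in roster}
    unknown = set(effects.fixed_effects) - roster_names
    if unknown:
        raise ValueError(f"fixed-effect names not in roster: {sorted(unknown)}")

    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, attempt)))
        lo_d, hi_d = config.doctors_per_hospital
        lo_p, hi_p = config.patients_per_doctor

        hid_of_doctor: list[int] = []
        for h in range(1, config.n_hospitals + 1):
            hid_of_doctor.extend([h] * int(rng.integers(lo_d, hi_d + 1)))
        patients = rng.integers(lo_p, hi_p + 1, size=len(hid_of_doctor))

        did = np.repeat(np.arange(1, len(hid_of_doctor) + 1), patients)
        hid = np.repeat(np.asarray(hid_of_doctor), patients)
        n = len(did)

        frame = _draw_predictors(rng, hid, did, n)

        eta = np.full(n, effects.intercept, dtype=float)
        for name, beta in effects.fixed_effects.items():
            eta += beta * (frame[name].to_numpy(dtype=float) - _CENTERS.get(name, 0.0))
        u_doc = rng.normal(0.0, effects.sd_doctor, size=len(hid_of_doctor) + 1)
        u_hos = rng.normal(0.0, effects.sd_hospital, size=config.n_hospitals + 1)
        eta += u_doc[did] + u_hos[hid]

        p = 1.0 / (1.0 + np.exp(-eta))
        y = rng.binomial(1, p)
        if y.min() == y.max():
            continue

        frame.insert(0, "ID", np.arange(1, n + 1))
        frame[OUTCOME] = y
        ds = Dataset(frame, roster)
        ds.validate()
        return ds

    raise RuntimeError(
        f"outcome degenerate (single class) in {max_attempts} attempts; "
        "check intercept/effect magnitudes"
    )


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-repetition seed below 2**31."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2**31))
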