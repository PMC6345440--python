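"""Synthetic patient cohorts with proportional-hazards survival structure.

Each patient carries a true nine-class tissue-activation vector drawn
from a Dirichlet prior, clinical covariates (UICC stage, sex, age), and
per-endpoint survival data generated from an exponential proportional-
hazards model whose log-hazard is linear in the activations and
covariates.  The planted coefficients are the ground truth that the
survival-recovery tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tissue import CLASS_CODES, N_CLASSES

ENDPOINTS = ("OS", "DSS", "RFS")

#: Activation column names in the fixed class order (a_ADI .. a_TUM).
ACTIVATION_COLUMNS = tuple(f"a_{c}" for c in CLASS_CODES)


@dataclass
class CohortConfig:
    """Ground-truth generative model of a synthetic cohort.

    ``beta`` maps class codes to log-hazard coefficients per unit
    activation; unmentioned classes get 0.  ``baseline_hazard`` is in
    events per month, ``censoring_horizon`` in months.
    """

    n_patients: int = 500
    regions_per_patient: int = 1
    activation_prior: tuple[float, ...] = (
        0.055, 0.03, 0.045, 0.06, 0.045, 0.055, 0.06, 0.085, 0.175
    )
    beta: dict[str, float] = field(default_factory=dict)
    beta_stage: float = 0.0
    beta_age: float = 0.0          # per decade of age
    beta_sex: float = 0.0
    baseline_hazard: float = 0.01  # events / month
    censoring_horizon: float = 120.0  # months
    endpoints: tuple[str, ...] = ("OS",)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 1 <= self.regions_per_patient <= 3:
            raise ValueError("regions_per_patient must be in {1, 2, 3}")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring_horizon must be > 0")
        prior = np.asarray(self.activation_prior, dtype=float)
        if prior.shape != (N_CLASSES,) or np.any(prior <= 0):
            raise ValueError(
                "activation_prior must be 9 strictly positive concentrations"
            )
        unknown = set(self.beta) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"beta for unknown classes: {sorted(unknown)}")
        bad = set(self.endpoints) - set(ENDPOINTS)
        if bad:
            raise ValueError(f"unknown endpoints: {sorted(bad)}")

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta.get(c, 0.0) for c in CLASS_CODES])


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Generate a cohort table, one row per patient.

    Columns: patient_id, stage, sex, age, a_ADI..a_TUM (true activations,
    each row on the simplex), and per requested endpoint time_<EP> /
    event_<EP> with observed time = min(event time, uniform censoring
    time on [0, censoring_horizon]).  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    n = cfg.n_patients

    activations = rng.dirichlet(np.asarray(cfg.activation_prior, float), size=n)
    stage = rng.integers(1, 5, size=n)
    sex = rng.integers(0, 2, size=n)
    age = np.clip(rng.normal(68.0, 10.0, size=n), 30.0, 95.0).round(1)

    lp = (
        activations @ cfg.beta_vector
        + cfg.beta_stage * stage
        + cfg.beta_sex * sex
        + cfg.beta_age * age / 10.0
    )
    hazard = cfg.baseline_hazard * np.exp(lp)

    data = {
        "patient_id": [f"SYN-{i:05d}" for i in range(n)],
        "stage": stage,
        "sex": sex,
        "age": age,
    }
    for j, col in enumerate(ACTIVATION_COLUMNS):
        data[col] = activations[:, j]

    for ep in cfg.endpoints:
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0.0, cfg.censoring_horizon, size=n)
        observed = np.minimum(t_event, t_cens)
        data[f"time_{ep}"] = np.maximum(observed, 1e-6)
        data[f"event_{ep}"] = (t_event <= t_cens).astype(int)

    return pd.DataFrame(data)


def region_compositions(
    cohort: pd.DataFrame, cfg: CohortConfig
) -> dict[str, list[dict[str, float]]]:
    """Per-patient region compositions for the imaging pipeline.

    Each patient gets ``regions_per_patient`` compositions: Dirichlet
    perturbations centered on the patient's true activation vector, so
    rendered regions agree with the survival-driving ground truth up to
    sampling noise.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed & 0x7FFFFFFF) + 7)
    out: dict[str, list[dict[str, float]]] = {}
    acts = cohort[list(ACTIVATION_COLUMNS)].to_numpy()
    for i, pid in enumerate(cohort["patient_id"]):
        comps = []
        for _ in range(cfg.regions_per_patient):
            conc = acts[i] * 150.0 + 0.05
            frac = rng.dirichlet(conc)
            comps.append({c: float(f) for c, f in zip(CLASS_CODES, frac)})
        out[pid] = comps
    return out
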