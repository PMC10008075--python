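"""Run and simulation configuration with YAML round-tripping.

The simulator defaults encode the published study conditions: a 48-patient,
38-descriptor cohort; the printed semantic correlation matrix; the printed
logistic mixed-model coefficients as generating slopes (on the 2-SD
standardized scale); and the reported missingness rates (~30% for subjective
impairment, 12.5% for BMI, 5% elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from parosim.types import SEMANTIC_VARIABLES, PARTICIPANT_MODEL_VARIABLES

#: Pearson correlations between the six semantic variables
#: (order oai, osi, valence, arousal, olfactory, gustatory).
SEMANTIC_CORRELATION_DEFAULT = [
    [1.000, 0.009, -0.044, -0.233, 0.311, -0.283],
    [0.009, 1.000, -0.327, -0.013, -0.246, -0.354],
    [-0.044, -0.327, 1.000, 0.144, -0.072, 0.639],
    [-0.233, -0.013, 0.144, 1.000, -0.027, 0.456],
    [0.311, -0.246, -0.072, -0.027, 1.000, -0.361],
    [-0.283, -0.354, 0.639, 0.456, -0.361, 1.000],
]

#: Generating slopes for the qualitatively-different linear predictor,
#: log-odds per 2-SD unit (per effect-code unit for sex).
SLOPES_QD_DEFAULT = {
    "age": 0.10, "bmi": -1.41, "sex": -0.83, "tdi": 0.33,
    "duration_months": -0.18, "parosmia_degree": -0.83,
    "parosmia_intensity": 1.84, "parosmia_valence": -0.16,
    "subjective_impairment": -0.16, "importance_olfaction": 0.23,
    "oai": -0.18, "osi": 0.16, "valence": -0.59, "arousal": 0.12,
    "olfactory": 0.95, "gustatory": -0.79,
}

#: Generating slopes for the odorless linear predictor.
SLOPES_OL_DEFAULT = {
    "age": -0.13, "bmi": 1.88, "sex": -0.64, "tdi": -3.13,
    "duration_months": -0.14, "parosmia_degree": 1.26,
    "parosmia_intensity": -1.66, "parosmia_valence": 1.39,
    "subjective_impairment": 0.62, "importance_olfaction": 1.02,
    "oai": 0.22, "osi": 0.41, "valence": 0.17, "arousal": 0.23,
    "olfactory": -1.03, "gustatory": 0.18,
}

SEMANTIC_MISSING_DEFAULT = {
    "oai": 0.0, "osi": 0.0,
    "valence": 0.10, "arousal": 0.10,
    "olfactory": 0.05, "gustatory": 0.05,
}

PARTICIPANT_MISSING_DEFAULT = {
    "age": 0.05, "bmi": 0.125, "tdi": 0.05, "threshold": 0.05,
    "duration_months": 0.05, "parosmia_intensity": 0.05,
    "parosmia_valence": 0.05, "subjective_impairment": 0.30,
    "importance_olfaction": 0.05, "depression_adsl": 0.05,
}


def _zero_slopes() -> dict:
    keys = list(PARTICIPANT_MODEL_VARIABLES) + list(SEMANTIC_VARIABLES)
    return {k: 0.0 for k in keys}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generator."""

    n_participants: int = 48
    n_descriptors: int = 38
    semantic_correlation: list = field(
        default_factory=lambda: [row[:] for row in SEMANTIC_CORRELATION_DEFAULT]
    )
    semantic_missing_rate: dict = field(
        default_factory=lambda: dict(SEMANTIC_MISSING_DEFAULT)
    )
    category_intercepts: tuple = (0.12, -1.90)  # (eta0_QD, eta0_OL), log-odds
    slopes_qd: dict = field(default_factory=lambda: dict(SLOPES_QD_DEFAULT))
    slopes_ol: dict = field(default_factory=lambda: dict(SLOPES_OL_DEFAULT))
    random_intercept_sd: float = 0.8
    unknown_rate: float = 0.02
    participant_missing_rates: dict = field(
        default_factory=lambda: dict(PARTICIPANT_MISSING_DEFAULT)
    )
    #: Strength (VAS points per SD of the severity latent u_i) of the link
    #: from the random intercept to subjective impairment, so that a more
    #: severely affected patient also reports higher impairment.
    impairment_coupling: float = 2.0
    repair_psd: bool = False

    def validate(self) -> "SimulationConfig":
        if self.n_participants < 1 or self.n_descriptors < 1:
            raise ValueError("cohort dimensions must be positive")
        R = np.asarray(self.semantic_correlation, dtype=float)
        if R.shape != (6, 6):
            raise ValueError("semantic_correlation must be 6x6")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("semantic_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("semantic_correlation must have unit diagonal")
        for name, p in {
            "unknown_rate": self.unknown_rate,
            **{f"semantic_missing_rate[{k}]": v for k, v in self.semantic_missing_rate.items()},
            **{f"participant_missing_rates[{k}]": v
               for k, v in self.participant_missing_rates.items()},
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        return self

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A null-effect configuration: all slopes 0, no severity coupling,
        no missingness, symmetric intercepts.  Used for calibration studies."""
        cfg = cls(
            slopes_qd=_zero_slopes(),
            slopes_ol=_zero_slopes(),
            category_intercepts=(0.0, 0.0),
            impairment_coupling=0.0,
            unknown_rate=0.0,
            semantic_missing_rate={k: 0.0 for k in SEMANTIC_MISSING_DEFAULT},
            participant_missing_rates={k: 0.0 for k in PARTICIPANT_MISSING_DEFAULT},
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg.validate()


@dataclass
class RunConfig:
    """Analysis-run parameters (PC count, imputation, CI level, seed)."""

    n_pcs: int = 3
    n_boot_impute: int = 10
    ci_level: float = 0.95
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> "RunConfig":
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be a positive integer")
        if self.n_boot_impute < 1:
            raise ValueError("n_boot_impute must be a positive integer")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        self.simulation.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["category_intercepts"] = list(
            self.simulation.category_intercepts
        )
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {}) or {}
        sim = dict(sim)
        if "category_intercepts" in sim:
            sim["category_intercepts"] = tuple(sim["category_intercepts"])
        cfg = cls(**d, simulation=SimulationConfig(**sim))
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
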