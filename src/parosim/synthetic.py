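"""Synthetic parosmia-cohort generator.

Emulates a 48-patient, 38-descriptor odor-classification study: descriptor
semantic norms drawn from a multivariate normal with the published
correlation structure, patient covariates from documented clinical ranges,
and responses from a trinomial (normal / qualitatively-different /
odorless) multinomial-logit mechanism with a shared per-patient random
intercept.  The published binary mixed-model coefficients serve as default
multinomial slopes — an acknowledged approximation that keeps categories
mutually exclusive by construction.

Every stage takes an independent sub-seed derived from the master seed via
a fixed splitting scheme, so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import softmax

from parosim.config import SimulationConfig
from parosim.types import Cohort, SEMANTIC_VARIABLES, PARTICIPANT_MODEL_VARIABLES
from parosim.preprocess import compute_parosmia_degree, effect_code

#: Affine map (center, scale, clip_lo, clip_hi) from latent standard normal
#: onto each rating scale.  Scales are small enough that clipping is a
#: > 3-sigma event and barely perturbs the correlation structure.
SEMANTIC_SCALE_MAPS = {
    "oai": (0.0, 1.0, None, None),
    "osi": (0.0, 1.0, None, None),
    "valence": (5.0, 1.3, 1.0, 9.0),
    "arousal": (4.5, 1.2, 1.0, 9.0),
    "olfactory": (2.5, 0.8, 0.0, 5.0),
    "gustatory": (2.5, 0.9, 0.0, 5.0),
}


@dataclass
class TrueParameters:
    """Ground truth stored alongside a simulated cohort for recovery tests."""

    u: np.ndarray = None  # per-participant random intercepts
    latent_participants: pd.DataFrame = None  # covariates before missingness
    latent_descriptors: pd.DataFrame = None  # semantic values before missingness
    slopes_qd: dict = field(default_factory=dict)
    slopes_ol: dict = field(default_factory=dict)
    category_intercepts: tuple = (0.0, 0.0)
    eta_qd: np.ndarray = None  # participants x descriptors linear predictors
    eta_ol: np.ndarray = None

    def to_jsonable(self) -> dict:
        return {
            "u": None if self.u is None else list(map(float, self.u)),
            "slopes_qd": {k: float(v) for k, v in self.slopes_qd.items()},
            "slopes_ol": {k: float(v) for k, v in self.slopes_ol.items()},
            "category_intercepts": list(map(float, self.category_intercepts)),
            "latent_participants": (
                None
                if self.latent_participants is None
                else self.latent_participants.to_dict(orient="list")
            ),
            "latent_descriptors": (
                None
                if self.latent_descriptors is None
                else self.latent_descriptors.to_dict(orient="list")
            ),
        }


def _subseed(seed, stage: int) -> np.random.SeedSequence:
    """Fixed splitting scheme: stage k of master seed s."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(entropy=seed.entropy, spawn_key=(stage,))
    return np.random.SeedSequence(entropy=seed, spawn_key=(stage,))


def _correlation_factor(R: np.ndarray, repair: bool) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        if not repair:
            raise ValueError(
                "semantic_correlation is not positive semidefinite; set "
                "repair_psd=True to clip negative eigenvalues to the nearest "
                "PSD matrix"
            ) from None
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 0.0, None)
        A = V * np.sqrt(w)
        # renormalize rows so the implied diagonal stays 1
        norms = np.sqrt((A**2).sum(axis=1))
        return A / norms[:, None]


def simulate_semantics(
    config: SimulationConfig, seed, return_latent: bool = False
):
    """Draw a descriptor table with the target semantic correlations.

    A latent 6-variate normal with the configured correlation matrix is
    mapped affinely onto each variable's rating scale (with clipping), then
    completely-at-random missingness is applied per variable.
    """
    config.validate()
    rng = np.random.default_rng(_subseed(seed, 0))
    n = config.n_descriptors
    R = np.asarray(config.semantic_correlation, dtype=float)
    L = _correlation_factor(R, config.repair_psd)
    Z = rng.standard_normal((n, 6)) @ L.T

    ids = [f"d{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame({"descriptor_id": ids, "label": [f"odor {i + 1}" for i in range(n)]})
    for j, var in enumerate(SEMANTIC_VARIABLES):
        center, scale, lo, hi = SEMANTIC_SCALE_MAPS[var]
        x = center + scale * Z[:, j]
        if lo is not None:
            x = np.clip(x, lo, hi)
        df[var] = x
    latent = df.copy()

    for var in SEMANTIC_VARIABLES:
        rate = config.semantic_missing_rate.get(var, 0.0)
        if rate > 0:
            miss = rng.random(n) < rate
            df.loc[miss, var] = np.nan

    if return_latent:
        return df, latent
    return df


def simulate_participants(config: SimulationConfig, seed):
    """Draw the participant covariate table and its ground truth.

    Age is truncated normal(45, 12) on [21, 70]; sex is Bernoulli with
    P(F) = 30/48; the remaining covariates use plausible clinical ranges.
    Subjective impairment is coupled to the severity latent u_i with
    strength ``impairment_coupling`` (VAS points per SD of u).  Missingness
    is applied after the latent values are stored.
    """
    config.validate()
    rng = np.random.default_rng(_subseed(seed, 1))
    n = config.n_participants

    a, b = (21.0 - 45.0) / 12.0, (70.0 - 45.0) / 12.0
    age = stats.truncnorm.rvs(a, b, loc=45.0, scale=12.0, size=n, random_state=rng)
    sex = np.where(rng.random(n) < 30.0 / 48.0, "F", "M")
    bmi = np.clip(rng.normal(26.0, 4.0, n), 16.0, 45.0)
    tdi = np.clip(rng.normal(20.0, 8.0, n), 1.0, 48.0)
    threshold = np.clip(rng.normal(4.0, 2.5, n), 1.0, 16.0)
    duration = rng.uniform(1.0, 36.0, n)
    intensity = rng.uniform(0.0, 10.0, n)
    frequency = np.where(rng.random(n) < 0.6, "daily", "not_daily")
    consequences = (rng.random(n) < 0.4).astype(float)
    parosmia_valence = np.clip(rng.normal(-2.5, 1.5, n), -5.0, 5.0)
    importance = np.clip(rng.normal(20.0, 6.0, n), 0.0, 60.0)
    adsl = np.clip(rng.normal(15.0, 9.0, n), 0.0, 60.0)

    sd = config.random_intercept_sd
    u = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    u_std = u / sd if sd > 0 else np.zeros(n)
    impairment = np.clip(
        5.0 + config.impairment_coupling * u_std + rng.normal(0.0, 1.5, n), 0.0, 10.0
    )

    df = pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "tdi": tdi,
            "threshold": threshold,
            "duration_months": duration,
            "parosmia_intensity": intensity,
            "parosmia_frequency": frequency,
            "parosmia_consequences": consequences,
            "parosmia_valence": parosmia_valence,
            "subjective_impairment": impairment,
            "importance_olfaction": importance,
            "depression_adsl": adsl,
        }
    )
    truth = TrueParameters(
        u=u,
        latent_participants=df.copy(),
        slopes_qd=dict(config.slopes_qd),
        slopes_ol=dict(config.slopes_ol),
        category_intercepts=tuple(config.category_intercepts),
    )

    for var, rate in config.participant_missing_rates.items():
        if rate > 0 and var in df.columns:
            miss = rng.random(n) < rate
            df.loc[miss, var] = np.nan
    return df, truth


def _standardized_participant_design(latent: pd.DataFrame) -> pd.DataFrame:
    """2-SD standardized model covariates from latent (complete) values,
    matching the analysis-side transforms so slopes are on the same scale."""
    out = pd.DataFrame(index=latent.index)
    degree = compute_parosmia_degree(
        latent["parosmia_intensity"],
        latent["parosmia_frequency"],
        latent["parosmia_consequences"],
    )
    cols = {
        "age": latent["age"],
        "bmi": latent["bmi"],
        "tdi": latent["tdi"],
        "duration_months": latent["duration_months"],
        "parosmia_degree": degree,
        "parosmia_intensity": latent["parosmia_intensity"],
        "parosmia_valence": latent["parosmia_valence"],
        "subjective_impairment": latent["subjective_impairment"],
        "importance_olfaction": latent["importance_olfaction"],
    }
    for name, x in cols.items():
        x = np.asarray(x, dtype=float)
        s = np.std(x, ddof=1)
        out[name] = np.zeros_like(x) if s == 0 else (x - x.mean()) / (2.0 * s)
    out["sex"] = effect_code(latent["sex"])
    return out[list(PARTICIPANT_MODEL_VARIABLES)]


def _standardized_semantic_design(latent: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=latent.index)
    for var in SEMANTIC_VARIABLES:
        x = np.asarray(latent[var], dtype=float)
        s = np.std(x, ddof=1)
        out[var] = np.zeros_like(x) if s == 0 else (x - x.mean()) / (2.0 * s)
    return out


def simulate_responses(
    descriptors: pd.DataFrame,
    participants: pd.DataFrame,
    true_params: TrueParameters,
    config: SimulationConfig,
    seed,
) -> pd.DataFrame:
    """Draw the long response table from the trinomial mixed mechanism.

    For each (participant, descriptor) pair the category is drawn from the
    3-class softmax of (0, eta_QD, eta_OL) where
    ``eta_c = intercept_c + x' beta_c + u_i`` on standardized predictors;
    the drawn label is then replaced by "unknown" with probability
    ``unknown_rate``.
    """
    config.validate()
    rng = np.random.default_rng(_subseed(seed, 2))
    latent_p = (
        true_params.latent_participants
        if true_params.latent_participants is not None
        else participants
    )
    latent_d = (
        true_params.latent_descriptors
        if true_params.latent_descriptors is not None
        else descriptors
    )
    Xp = _standardized_participant_design(latent_p)
    Xd = _standardized_semantic_design(latent_d)

    def eta(slopes: dict, intercept: float) -> np.ndarray:
        bp = np.array([slopes.get(v, 0.0) for v in Xp.columns])
        bd = np.array([slopes.get(v, 0.0) for v in Xd.columns])
        return (
            intercept
            + (Xp.values @ bp)[:, None]
            + (Xd.values @ bd)[None, :]
            + true_params.u[:, None]
        )

    eta_qd = eta(true_params.slopes_qd, true_params.category_intercepts[0])
    eta_ol = eta(true_params.slopes_ol, true_params.category_intercepts[1])
    true_params.eta_qd, true_params.eta_ol = eta_qd, eta_ol

    n_p, n_d = eta_qd.shape
    logits = np.stack([np.zeros_like(eta_qd), eta_qd, eta_ol], axis=-1)
    probs = softmax(logits, axis=-1)
    cum = probs.cumsum(axis=-1)
    draw = rng.random((n_p, n_d, 1))
    cat = (draw > cum).sum(axis=-1)  # 0=normal, 1=QD, 2=OL
    labels = np.array(["normal", "qualitatively_different", "odorless"])[cat]
    unknown = rng.random((n_p, n_d)) < config.unknown_rate
    labels = np.where(unknown, "unknown", labels)

    pid = np.repeat(participants["participant_id"].to_numpy(), n_d)
    did = np.tile(descriptors["descriptor_id"].to_numpy(), n_p)
    return pd.DataFrame(
        {"participant_id": pid, "descriptor_id": did, "response": labels.ravel()}
    )


def simulate_cohort(config: SimulationConfig = None, seed=0):
    """Compose the three generators into a full (Cohort, TrueParameters)."""
    config = (config or SimulationConfig()).validate()
    descriptors, latent_d = simulate_semantics(config, seed, return_latent=True)
    participants, truth = simulate_participants(config, seed)
    truth.latent_descriptors = latent_d
    responses = simulate_responses(descriptors, participants, truth, config, seed)
    cohort = Cohort(responses, descriptors, participants).validate()
    return cohort, truth
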