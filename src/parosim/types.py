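"""Domain containers and schema validation for cohort tables.

Tables are plain :class:`pandas.DataFrame` objects with fixed column
schemas; the :class:`Cohort` dataclass bundles the three tables and
enforces the cross-table invariants (referential integrity, one response
per participant-descriptor pair).  Ordering everywhere follows first
appearance in the descriptor / participant files, never lexicographic
sorting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four admissible answers to "does this odor smell normal?".
RESPONSE_CATEGORIES = ("normal", "qualitatively_different", "odorless", "unknown")

#: Descriptor-level semantic variables, in canonical (printed-table) order.
SEMANTIC_VARIABLES = ("oai", "osi", "valence", "arousal", "olfactory", "gustatory")

#: The ten participant variables entering every mixed model, in table order.
#: ``parosmia_degree`` is derived (weighted sum of intensity, frequency,
#: consequences); ``sex`` is effect-coded, the rest 2-SD standardized.
PARTICIPANT_MODEL_VARIABLES = (
    "age",
    "bmi",
    "sex",
    "tdi",
    "duration_months",
    "parosmia_degree",
    "parosmia_intensity",
    "parosmia_valence",
    "subjective_impairment",
    "importance_olfaction",
)

RESPONSE_COLUMNS = ("participant_id", "descriptor_id", "response")
DESCRIPTOR_COLUMNS = ("descriptor_id", "label") + SEMANTIC_VARIABLES
PARTICIPANT_COLUMNS = (
    "participant_id",
    "age",
    "sex",
    "bmi",
    "tdi",
    "threshold",
    "duration_months",
    "parosmia_intensity",
    "parosmia_frequency",
    "parosmia_consequences",
    "parosmia_valence",
    "subjective_impairment",
    "importance_olfaction",
    "depression_adsl",
)

#: Closed ranges for rated fields; values outside are schema violations.
FIELD_RANGES = {
    "valence": (1.0, 9.0),
    "arousal": (1.0, 9.0),
    "olfactory": (0.0, 5.0),
    "gustatory": (0.0, 5.0),
    "parosmia_intensity": (0.0, 10.0),
    "parosmia_valence": (-5.0, 5.0),
    "subjective_impairment": (0.0, 10.0),
    "depression_adsl": (0.0, 60.0),
}


class SchemaError(ValueError):
    """A table violated its declared schema.

    Carries the offending source (file or table name), row index and the
    rule that failed, so a clinic-side user can locate the bad cell.
    """

    def __init__(self, source: str, row, rule: str):
        self.source = source
        self.row = row
        self.rule = rule
        loc = f"{source}" if row is None else f"{source}, row {row}"
        super().__init__(f"schema violation in {loc}: {rule}")


def _require_columns(df: pd.DataFrame, expected, source: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(source, None, f"missing column(s) {missing}")


def _check_range(df: pd.DataFrame, column: str, source: str) -> None:
    lo, hi = FIELD_RANGES[column]
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[vals.notna() & ((vals < lo) | (vals > hi))]
    if len(bad):
        raise SchemaError(
            source, int(bad[0]), f"{column}={df.loc[bad[0], column]!r} outside [{lo}, {hi}]"
        )


def validate_responses(df: pd.DataFrame, source: str = "responses") -> pd.DataFrame:
    _require_columns(df, RESPONSE_COLUMNS, source)
    for col in ("participant_id", "descriptor_id"):
        ids = df[col].astype(str)
        empty = df.index[(ids.str.len() == 0) | df[col].isna()]
        if len(empty):
            raise SchemaError(source, int(empty[0]), f"empty {col}")
    bad = df.index[~df["response"].isin(RESPONSE_CATEGORIES)]
    if len(bad):
        raise SchemaError(
            source,
            int(bad[0]),
            f"response {df.loc[bad[0], 'response']!r} not in {list(RESPONSE_CATEGORIES)}",
        )
    dup = df.duplicated(subset=["participant_id", "descriptor_id"])
    if dup.any():
        i = int(df.index[dup][0])
        pair = (df.loc[i, "participant_id"], df.loc[i, "descriptor_id"])
        raise SchemaError(source, i, f"duplicate (participant, descriptor) pair {pair}")
    out = df.loc[:, list(RESPONSE_COLUMNS)].copy()
    out["participant_id"] = out["participant_id"].astype(str)
    out["descriptor_id"] = out["descriptor_id"].astype(str)
    return out.reset_index(drop=True)


def validate_descriptors(df: pd.DataFrame, source: str = "descriptors") -> pd.DataFrame:
    _require_columns(df, DESCRIPTOR_COLUMNS, source)
    ids = df["descriptor_id"].astype(str)
    empty = df.index[(ids.str.len() == 0) | df["descriptor_id"].isna()]
    if len(empty):
        raise SchemaError(source, int(empty[0]), "empty descriptor_id")
    dup = df.duplicated(subset=["descriptor_id"])
    if dup.any():
        i = int(df.index[dup][0])
        raise SchemaError(source, i, f"duplicate descriptor_id {df.loc[i, 'descriptor_id']!r}")
    out = df.loc[:, list(DESCRIPTOR_COLUMNS)].copy()
    out["descriptor_id"] = out["descriptor_id"].astype(str)
    for col in SEMANTIC_VARIABLES:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[coerced.isna() & out[col].notna() & (out[col].astype(str) != "NA")]
        if len(bad):
            raise SchemaError(source, int(bad[0]), f"non-numeric {col}={out.loc[bad[0], col]!r}")
        out[col] = coerced
        if col in FIELD_RANGES:
            _check_range(out, col, source)
    return out.reset_index(drop=True)


def validate_participants(df: pd.DataFrame, source: str = "participants") -> pd.DataFrame:
    _require_columns(df, PARTICIPANT_COLUMNS, source)
    ids = df["participant_id"].astype(str)
    empty = df.index[(ids.str.len() == 0) | df["participant_id"].isna()]
    if len(empty):
        raise SchemaError(source, int(empty[0]), "empty participant_id")
    dup = df.duplicated(subset=["participant_id"])
    if dup.any():
        i = int(df.index[dup][0])
        raise SchemaError(source, i, f"duplicate participant_id {df.loc[i, 'participant_id']!r}")
    out = df.loc[:, list(PARTICIPANT_COLUMNS)].copy()
    out["participant_id"] = out["participant_id"].astype(str)
    bad = out.index[out["sex"].notna() & ~out["sex"].isin(["F", "M"])]
    if len(bad):
        raise SchemaError(source, int(bad[0]), f"sex {out.loc[bad[0], 'sex']!r} not in {{F, M}}")
    bad = out.index[
        out["parosmia_frequency"].notna()
        & ~out["parosmia_frequency"].isin(["daily", "not_daily"])
    ]
    if len(bad):
        raise SchemaError(
            source,
            int(bad[0]),
            f"parosmia_frequency {out.loc[bad[0], 'parosmia_frequency']!r} "
            "not in {daily, not_daily}",
        )
    numeric = [
        c
        for c in PARTICIPANT_COLUMNS
        if c not in ("participant_id", "sex", "parosmia_frequency")
    ]
    for col in numeric:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[coerced.isna() & out[col].notna() & (out[col].astype(str) != "NA")]
        if len(bad):
            raise SchemaError(source, int(bad[0]), f"non-numeric {col}={out.loc[bad[0], col]!r}")
        out[col] = coerced
        if col in FIELD_RANGES:
            _check_range(out, col, source)
    bad = out.index[out["parosmia_consequences"].notna() & ~out["parosmia_consequences"].isin([0, 1])]
    if len(bad):
        raise SchemaError(
            source, int(bad[0]),
            f"parosmia_consequences {out.loc[bad[0], 'parosmia_consequences']!r} not binary",
        )
    return out.reset_index(drop=True)


@dataclass
class Cohort:
    """A validated study cohort: responses, descriptor norms, covariates."""

    responses: pd.DataFrame
    descriptors: pd.DataFrame
    participants: pd.DataFrame

    def validate(self) -> "Cohort":
        self.responses = validate_responses(self.responses)
        self.descriptors = validate_descriptors(self.descriptors)
        self.participants = validate_participants(self.participants)
        known_d = set(self.descriptors["descriptor_id"])
        known_p = set(self.participants["participant_id"])
        bad = self.responses.index[~self.responses["descriptor_id"].isin(known_d)]
        if len(bad):
            raise SchemaError(
                "responses", int(bad[0]),
                f"descriptor_id {self.responses.loc[bad[0], 'descriptor_id']!r} "
                "not in descriptor table",
            )
        bad = self.responses.index[~self.responses["participant_id"].isin(known_p)]
        if len(bad):
            raise SchemaError(
                "responses", int(bad[0]),
                f"participant_id {self.responses.loc[bad[0], 'participant_id']!r} "
                "not in participant table",
            )
        return self

    @property
    def descriptor_ids(self) -> list:
        return list(self.descriptors["descriptor_id"])

    @property
    def participant_ids(self) -> list:
        return list(self.participants["participant_id"])

    def equals(self, other: "Cohort") -> bool:
        def _eq(a: pd.DataFrame, b: pd.DataFrame) -> bool:
            if list(a.columns) != list(b.columns) or a.shape != b.shape:
                return False
            for c in a.columns:
                x, y = a[c], b[c]
                if x.dtype.kind == "f" or y.dtype.kind == "f":
                    xf = pd.to_numeric(x, errors="coerce")
                    yf = pd.to_numeric(y, errors="coerce")
                    if not ((xf.isna() == yf.isna()).all()
                            and np.allclose(xf.dropna(), yf.dropna(), rtol=0, atol=1e-9)):
                        return False
                else:
                    if not (x.fillna("<NA>").astype(str) == y.fillna("<NA>").astype(str)).all():
                        return False
            return True

        return (
            _eq(self.responses, other.responses)
            and _eq(self.descriptors, other.descriptors)
            and _eq(self.participants, other.participants)
        )


@dataclass
class CodedResponses:
    """Binary indicator matrices (participants x descriptors).

    ``qd[i, d] = 1`` iff participant i called descriptor d qualitatively
    different, ``ol`` likewise for odorless; ``observed[i, d] = 1`` iff the
    pair was classified at all (unknown answers count as missing).  A cell
    is never both QD and OL.
    """

    qd: pd.DataFrame
    ol: pd.DataFrame
    observed: pd.DataFrame

    @property
    def participant_ids(self) -> list:
        return list(self.qd.index)

    @property
    def descriptor_ids(self) -> list:
        return list(self.qd.columns)


@dataclass
class MixedModelResult:
    """Wald summary of one random-intercept logistic fit."""

    outcome: str
    model: str
    terms: pd.DataFrame  # term, estimate, std_error, z, p
    random_intercept_sd: float
    converged: bool
    n_obs: int
    n_participants: int
    loglik: float = float("nan")
    method: str = "gauss-hermite"
    message: str = ""


@dataclass
class PCAModel:
    """Correlation-matrix PCA of descriptor variables.

    ``variance_fraction`` is over *all* components (sums to 1); ``scores``
    keeps only the retained ``n_pcs`` columns.
    """

    variables: list
    loadings: pd.DataFrame  # variable x PC
    scores: pd.DataFrame  # descriptor x PC
    variance_fraction: np.ndarray  # retained PCs only
    all_variance_fractions: np.ndarray
    n_pcs: int
    imputed_cells: list = field(default_factory=list)
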