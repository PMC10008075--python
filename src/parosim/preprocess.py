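"""Response coding, derived scores, standardization and imputation.

Implements the analysis-side data preparation: the two binary response
factors (qualitatively-different vs rest, odorless vs rest) with unknown
answers treated as missing; the parosmia-degree composite; Gelman-Hill
2-SD standardization; effect coding of sex; and a bootstrap-additive
multiple-imputation scheme (additive spline regressions fit on bootstrap
resamples, missing entries imputed by the mean of the bootstrap
predictions).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from parosim.types import (
    Cohort,
    CodedResponses,
    PARTICIPANT_MODEL_VARIABLES,
)

_CONTINUOUS_PARTICIPANT_VARS = (
    "age",
    "bmi",
    "tdi",
    "threshold",
    "duration_months",
    "parosmia_intensity",
    "parosmia_valence",
    "subjective_impairment",
    "importance_olfaction",
    "depression_adsl",
)


def code_responses(responses, descriptor_order=None, participant_order=None) -> CodedResponses:
    """Binary indicator matrices from the long response table.

    normal -> (QD=0, OL=0, observed); qualitatively_different -> (1, 0,
    observed); odorless -> (0, 1, observed); unknown -> unobserved cell.
    Row/column order follows first appearance unless an explicit order (or
    a :class:`Cohort`, whose tables fix the order) is given.
    """
    if isinstance(responses, Cohort):
        cohort = responses
        responses = cohort.responses
        descriptor_order = cohort.descriptor_ids
        participant_order = cohort.participant_ids
    if participant_order is None:
        participant_order = list(dict.fromkeys(responses["participant_id"]))
    if descriptor_order is None:
        descriptor_order = list(dict.fromkeys(responses["descriptor_id"]))

    shape = (len(participant_order), len(descriptor_order))
    qd = np.zeros(shape, dtype=int)
    ol = np.zeros(shape, dtype=int)
    observed = np.zeros(shape, dtype=int)
    p_index = {p: i for i, p in enumerate(participant_order)}
    d_index = {d: j for j, d in enumerate(descriptor_order)}

    pi = responses["participant_id"].map(p_index).to_numpy()
    di = responses["descriptor_id"].map(d_index).to_numpy()
    resp = responses["response"].to_numpy()
    keep = resp != "unknown"
    observed[pi[keep], di[keep]] = 1
    qd[pi[resp == "qualitatively_different"], di[resp == "qualitatively_different"]] = 1
    ol[pi[resp == "odorless"], di[resp == "odorless"]] = 1

    kw = dict(index=pd.Index(participant_order, name="participant_id"),
              columns=pd.Index(descriptor_order, name="descriptor_id"))
    return CodedResponses(
        qd=pd.DataFrame(qd, **kw), ol=pd.DataFrame(ol, **kw),
        observed=pd.DataFrame(observed, **kw),
    )


def compute_parosmia_degree(intensity, frequency, consequences, weights=(1.0, 1.0, 1.0)):
    """Weighted sum of parosmia intensity, frequency and consequences.

    ``frequency`` accepts the category labels (daily=1, not_daily=0) or a
    numeric 0/1 coding.  A missing component makes the result missing, so
    the composite flows into imputation like any other incomplete variable.
    """
    w1, w2, w3 = weights
    scalar = np.isscalar(intensity) or intensity is None
    intensity = pd.to_numeric(
        pd.Series(np.atleast_1d(np.asarray(intensity, dtype=object))), errors="coerce"
    )
    freq = pd.Series(np.atleast_1d(np.asarray(frequency, dtype=object)))
    freq = freq.map({"daily": 1.0, "not_daily": 0.0}).where(
        freq.isin(["daily", "not_daily"]), pd.to_numeric(freq, errors="coerce")
    )
    cons = pd.to_numeric(
        pd.Series(np.atleast_1d(np.asarray(consequences, dtype=object))), errors="coerce"
    )
    out = w1 * intensity.to_numpy() + w2 * freq.to_numpy(dtype=float) + w3 * cons.to_numpy()
    return float(out[0]) if scalar else out


def standardize_2sd(column, name=None):
    """Center and divide by twice the sample SD (n-1 denominator).

    Returns ``(standardized, record)`` where the record holds the name,
    center and scale, enabling exact inversion.  The resulting column has
    SD exactly 0.5, putting continuous coefficients on a scale comparable
    to a +/-1 coded binary predictor.
    """
    x = pd.Series(column).astype(float)
    if name is None:
        name = getattr(column, "name", None) or "column"
    obs = x.dropna()
    if len(obs) < 2:
        raise ValueError(f"standardize_2sd({name!r}): need >= 2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError(f"standardize_2sd({name!r}): zero standard deviation")
    center = obs.mean()
    record = {"name": name, "center": float(center), "scale": float(2.0 * sd)}
    return (x - center) / (2.0 * sd), record


def unstandardize_2sd(column, record):
    """Invert :func:`standardize_2sd` from its transform record."""
    return pd.Series(column).astype(float) * record["scale"] + record["center"]


def effect_code(sex, positive: str = "F"):
    """Effect-code a two-level sex factor as +/-1 (default F=+1, M=-1)."""
    s = pd.Series(sex)
    bad = s.dropna()[~s.dropna().isin(["F", "M"])]
    if len(bad):
        raise ValueError(f"effect_code: unexpected level {bad.iloc[0]!r} (expected F/M)")
    negative = "M" if positive == "F" else "F"
    coded = s.map({positive: 1.0, negative: -1.0})
    if coded.dropna().nunique() == 1:
        warnings.warn(
            "effect_code: single sex level present; its coefficient is "
            "inestimable downstream",
            stacklevel=2,
        )
    return coded.to_numpy() if not isinstance(sex, pd.Series) else coded


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form), linear beyond the
    boundary knots; returns columns beyond the linear term."""
    kmax = knots[-1]
    km1 = knots[-2]

    def d(k):
        return (np.clip(x - k, 0, None) ** 3 - np.clip(x - kmax, 0, None) ** 3) / (kmax - k)

    dm1 = d(km1)
    return np.column_stack([d(k) - dm1 for k in knots[:-2]])


def _additive_design(df: pd.DataFrame, predictors, spline_meta: dict) -> np.ndarray:
    cols = [np.ones(len(df))]
    for p in predictors:
        x = df[p].to_numpy(dtype=float)
        cols.append(x)
        knots = spline_meta.get(p)
        if knots is not None:
            cols.append(_natural_spline_basis(x, knots))
    return np.column_stack(cols)


def impute_missing(participants: pd.DataFrame, n_boot: int = 10, seed=None):
    """Bootstrap-additive multiple imputation of participant covariates.

    For each incomplete numeric variable an additive regression (linear
    terms plus a natural-spline basis on continuous predictors) is fit on
    ``n_boot`` bootstrap resamples of the rows complete for that model;
    each missing entry is imputed by the mean of the bootstrap
    predictions.  Observed cells are never modified.  Returns the
    completed table and a report listing every imputed cell with its
    across-bootstrap prediction spread.

    A variable that is entirely missing raises; a variable whose model has
    fewer than 10 complete training rows falls back to mean imputation
    with a warning.
    """
    rng = np.random.default_rng(seed)
    df = participants.copy().reset_index(drop=True)
    report_rows = []

    numeric = [c for c in _CONTINUOUS_PARTICIPANT_VARS if c in df.columns]
    for col in numeric:
        if df[col].notna().sum() == 0:
            raise ValueError(f"impute_missing: variable {col!r} has no observed values")
        frac = df[col].notna().mean()
        if frac < 0.6:
            warnings.warn(
                f"impute_missing: only {frac:.0%} of {col!r} observed "
                "(below the 60% design floor); proceeding",
                stacklevel=2,
            )

    sex_code = None
    if "sex" in df.columns and df["sex"].notna().all():
        levels = df["sex"].dropna().unique()
        if len(levels) == 2:
            sex_code = effect_code(df["sex"])

    for target in numeric:
        miss = df[target].isna()
        if not miss.any():
            continue
        predictors = [c for c in numeric if c != target]
        model = df[predictors].copy()
        if sex_code is not None:
            model["sex_code"] = np.asarray(sex_code, dtype=float)
            predictors = predictors + ["sex_code"]
        complete = (~miss) & model.notna().all(axis=1)
        y = df.loc[complete, target].to_numpy(dtype=float)
        n_complete = int(complete.sum())

        if n_complete < 10:
            warnings.warn(
                f"impute_missing: {n_complete} complete rows for {target!r}; "
                "falling back to mean imputation",
                stacklevel=2,
            )
            mean_val = float(df[target].mean())
            for i in df.index[miss]:
                df.loc[i, target] = mean_val
                report_rows.append(
                    (target, df.loc[i, "participant_id"], mean_val, 0.0, "mean")
                )
            continue

        spline_meta = {}
        for p in predictors:
            xs = model.loc[complete, p].to_numpy(dtype=float)
            if len(np.unique(xs)) >= 8:
                knots = np.quantile(xs, [0.05, 0.35, 0.65, 0.95])
                if len(np.unique(knots)) == 4:
                    spline_meta[p] = knots

        train = model.loc[complete]
        pred_rows = model.loc[miss].copy()
        # predictors can themselves be missing on rows needing imputation
        for p in predictors:
            pred_rows[p] = pred_rows[p].fillna(train[p].mean())
        Xtrain_full = _additive_design(train, predictors, spline_meta)
        Xpred = _additive_design(pred_rows, predictors, spline_meta)

        preds = np.empty((n_boot, int(miss.sum())))
        idx = np.arange(n_complete)
        for b in range(n_boot):
            boot = rng.choice(idx, size=n_complete, replace=True)
            beta, *_ = np.linalg.lstsq(Xtrain_full[boot], y[boot], rcond=None)
            preds[b] = Xpred @ beta
        imputed = preds.mean(axis=0)
        spread = preds.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(preds.shape[1])
        for j, i in enumerate(df.index[miss]):
            df.loc[i, target] = imputed[j]
            report_rows.append(
                (target, df.loc[i, "participant_id"], float(imputed[j]), float(spread[j]),
                 "bootstrap")
            )

    report = pd.DataFrame(
        report_rows,
        columns=["variable", "participant_id", "imputed_value", "prediction_sd", "method"],
    )
    return df, report


def build_design(
    participants: pd.DataFrame,
    degree_weights=(1.0, 1.0, 1.0),
    impute: bool = True,
    n_boot: int = 10,
    seed=None,
    sex_positive: str = "F",
):
    """Assemble the standardized participant predictor matrix.

    Imputes missing covariates (optional), derives the parosmia-degree
    composite, 2-SD standardizes the continuous model variables and
    effect-codes sex.  Returns ``(design, transforms, imputation_report)``
    where ``design`` is indexed by participant_id with the ten model
    columns and ``transforms`` records every center/scale applied.
    """
    df = participants.copy()
    report = pd.DataFrame(
        columns=["variable", "participant_id", "imputed_value", "prediction_sd", "method"]
    )
    if impute:
        df, report = impute_missing(df, n_boot=n_boot, seed=seed)
    # frequency/consequences may still be missing (categorical, not imputed);
    # fill with the modal value so the composite is defined
    for col, fill in (("parosmia_frequency", None), ("parosmia_consequences", None)):
        if df[col].isna().any():
            mode = df[col].mode()
            df[col] = df[col].fillna(mode.iloc[0] if len(mode) else 0)
    df["parosmia_degree"] = compute_parosmia_degree(
        df["parosmia_intensity"],
        df["parosmia_frequency"],
        df["parosmia_consequences"],
        weights=degree_weights,
    )

    design = pd.DataFrame(index=pd.Index(df["participant_id"], name="participant_id"))
    transforms = {}
    for var in PARTICIPANT_MODEL_VARIABLES:
        if var == "sex":
            design["sex"] = np.asarray(effect_code(df["sex"], positive=sex_positive))
            transforms["sex"] = {"name": "sex", "coding": {sex_positive: 1.0}}
        else:
            std, rec = standardize_2sd(df[var], name=var)
            design[var] = std.to_numpy()
            transforms[var] = rec
    return design, transforms, report
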