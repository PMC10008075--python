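"""Descriptor affectedness statistics, semantic correlations and the
random-intercept logistic model suite.

Mirrors the printed-table layout of the analysis: by-descriptor QD/OL
percentages with normal-approximation CIs; pairwise-complete Pearson
correlations between descriptor semantic variables and those percentages
(with significance stars at p < 0.05, uncorrected); and, per outcome, one
baseline model on the ten participant variables plus one model per
semantic variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from parosim.glmm import fit_logistic_random_intercept
from parosim.preprocess import standardize_2sd
from parosim.types import (
    CodedResponses,
    MixedModelResult,
    SEMANTIC_VARIABLES,
)


def descriptor_percentages(coded: CodedResponses, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-descriptor % of QD and OL responses with normal-approximation CIs.

    ``pct = 100 k/n`` over observed (classified) cells and
    ``CI = pct +/- z_{1-alpha/2} * 100 * sqrt(p(1-p)/n)``, clipped to
    [0, 100].  A descriptor nobody classified yields a missing row.
    """
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    n = coded.observed.sum(axis=0).to_numpy(dtype=float)
    rows = {"descriptor_id": coded.descriptor_ids, "n_observed": n.astype(int)}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, mat in (("qd", coded.qd), ("ol", coded.ol)):
            k = mat.sum(axis=0).to_numpy(dtype=float)
            phat = np.where(n > 0, k / np.where(n > 0, n, 1.0), np.nan)
            pct = 100.0 * phat
            half = z * 100.0 * np.sqrt(phat * (1.0 - phat) / np.where(n > 0, n, np.nan))
            rows[f"pct_{name}"] = pct
            rows[f"ci_{name}_low"] = np.clip(pct - half, 0.0, 100.0)
            rows[f"ci_{name}_high"] = np.clip(pct + half, 0.0, 100.0)
    return pd.DataFrame(rows)


def pearson_with_p(x, y):
    """Pairwise-complete Pearson r with a two-sided t-test p-value.

    Returns ``(n, r, p)``.  With fewer than 3 complete pairs or a
    zero-variance vector, r and p are NaN (undefined, flagged by the
    caller's table).  ``p`` comes from ``t = r sqrt((n-2)/(1-r^2))`` on
    n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return n, float("nan"), float("nan")
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return n, float("nan"), float("nan")
    xc, yc = xs - xs.mean(), ys - ys.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return n, r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return n, r, p


def semantic_correlation_table(
    summary: pd.DataFrame, descriptors: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Correlate each semantic variable with the QD and OL percentages.

    One row per variable x target with the pairwise-complete n; the
    ``significant`` star marks p < alpha (no multiplicity correction,
    matching the printed table)."""
    merged = summary.merge(descriptors, on="descriptor_id", how="inner")
    rows = []
    for var in SEMANTIC_VARIABLES:
        for target in ("pct_qd", "pct_ol"):
            n, r, p = pearson_with_p(merged[var], merged[target])
            rows.append(
                {
                    "variable": var,
                    "target": target,
                    "n": n,
                    "r": r,
                    "p": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


def _long_observations(coded: CodedResponses, outcome: str):
    """Flatten one indicator matrix to (y, participant index, descriptor index)
    over observed cells."""
    mat = coded.qd if outcome == "qd" else coded.ol
    obs = coded.observed.to_numpy(dtype=bool)
    pi, di = np.nonzero(obs)
    y = mat.to_numpy(dtype=float)[pi, di]
    return y, pi, di


def fit_glmm(
    coded: CodedResponses,
    design: pd.DataFrame,
    outcome: str,
    semantic_values=None,
    semantic_name: str = None,
    n_quad: int = 15,
) -> MixedModelResult:
    """One random-intercept logistic model for QD or OL responses.

    ``design`` holds the standardized participant predictors (indexed by
    participant_id, aligned with ``coded``); ``semantic_values``, when
    given, is one descriptor-level column (aligned with the coded
    descriptor order) that is 2-SD standardized and broadcast to the long
    table; observations with a missing semantic value are dropped for
    that model only.  Non-convergence is flagged on the result, not
    raised.
    """
    if outcome not in ("qd", "ol"):
        raise ValueError("outcome must be 'qd' or 'ol'")
    design = design.loc[coded.participant_ids]
    y, pi, di = _long_observations(coded, outcome)
    X = design.to_numpy(dtype=float)[pi]
    names = ["(Intercept)"] + list(design.columns)
    X = np.column_stack([np.ones(len(y)), X])

    if semantic_values is not None:
        sem = np.asarray(semantic_values, dtype=float)
        std, _ = standardize_2sd(pd.Series(sem), name=semantic_name or "semantic")
        sem_long = std.to_numpy()[di]
        keep = ~np.isnan(sem_long)
        y, pi, X = y[keep], pi[keep], X[keep]
        X = np.column_stack([X, sem_long[keep]])
        names = names + [semantic_name or "semantic"]

    fit = fit_logistic_random_intercept(y, X, pi, term_names=names, n_quad=n_quad)
    terms = pd.DataFrame(
        {
            "term": fit.term_names,
            "estimate": fit.beta,
            "std_error": fit.beta_se,
            "z": fit.z,
            "p": fit.p_values,
        }
    )
    return MixedModelResult(
        outcome=outcome,
        model="baseline" if semantic_values is None else (semantic_name or "semantic"),
        terms=terms,
        random_intercept_sd=fit.sigma,
        converged=fit.converged,
        n_obs=fit.n_obs,
        n_participants=fit.n_groups,
        loglik=fit.loglik,
        method=f"gauss-hermite({fit.n_quad})",
        message=fit.message,
    )


def semantic_model_suite(
    coded: CodedResponses,
    design: pd.DataFrame,
    descriptors: pd.DataFrame,
    n_quad: int = 15,
):
    """The full model suite: per outcome, a baseline participant-variable
    model plus one model per semantic variable (14 fits for 6 variables).

    Returns ``(results, tables)`` where ``results`` is the list of
    :class:`MixedModelResult` and ``tables`` maps ``glmm_qd``/``glmm_ol``
    to printed-table-layout DataFrames: participant terms from the
    baseline model, one row per semantic variable from its own model.
    """
    descriptors = descriptors.set_index("descriptor_id").loc[coded.descriptor_ids]
    results = []
    tables = {}
    for outcome in ("qd", "ol"):
        baseline = fit_glmm(coded, design, outcome, n_quad=n_quad)
        results.append(baseline)
        rows = baseline.terms.copy()
        rows.insert(0, "block", "participant")
        sem_rows = []
        for var in SEMANTIC_VARIABLES:
            m = fit_glmm(
                coded,
                design,
                outcome,
                semantic_values=descriptors[var].to_numpy(dtype=float),
                semantic_name=var,
                n_quad=n_quad,
            )
            results.append(m)
            row = m.terms.iloc[[-1]].copy()
            row.insert(0, "block", "semantic")
            row["converged"] = m.converged
            sem_rows.append(row)
        rows["converged"] = baseline.converged
        table = pd.concat([rows] + sem_rows, ignore_index=True)
        table["outcome"] = outcome
        tables[f"glmm_{outcome}"] = table
    return results, tables
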