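"""The parosmia severity index.

The index rests on the idea that odors which are *rarely* affected across
patients are the ones affected last, so reporting them as distorted or
odorless signals more severe disease.  Descriptor weights are derived from
a PCA over the six semantic variables plus the descriptor-level QD and OL
percentages:

* scores ``s_{p,d}`` on PC p are multiplied by the PC's Pearson correlation
  with the OL (or QD) percentage vector, giving weighted scores
  ``OLs_{p,d} = s_{p,d} rho(s_p, ol)`` (QD analogous);
* each PC's weighted scores are min-max normalized across descriptors,
  inverted (1 - normalized) and combined with the PC's explained-variance
  fraction ``v_p``:  ``OLw_d = sum_p (1 - norm(OLs)_{p,d}) v_p``;
* a participant's severity is the weight-sum of their affected descriptors
  over the maximal attainable weight-sum on the descriptors they
  classified:

      ps_i = sum_{d in D_i} (OL_{i,d} OLw_d + QD_{i,d} QDw_d)
             / sum_{d in D_i} max(OLw_d, QDw_d),

  which lies in [0, 1], is invariant to PC sign flips and to rescaling all
  weights, and increases when a normal response turns into an affected one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from parosim.association import pearson_with_p
from parosim.types import CodedResponses, PCAModel, SEMANTIC_VARIABLES


def build_pca_input(descriptors: pd.DataFrame, summary: pd.DataFrame) -> pd.DataFrame:
    """Descriptor x 8 matrix: the six semantic variables plus pct_qd, pct_ol."""
    merged = descriptors.merge(
        summary[["descriptor_id", "pct_qd", "pct_ol"]], on="descriptor_id", how="inner"
    )
    cols = list(SEMANTIC_VARIABLES) + ["pct_qd", "pct_ol"]
    return merged.set_index("descriptor_id")[cols]


def run_pca(descriptor_matrix: pd.DataFrame, n_pcs: int = 3) -> PCAModel:
    """Correlation-matrix PCA of the descriptor variable matrix.

    Columns are z-standardized (unit SD, n-1 denominator); missing cells
    are mean-imputed for this step only and recorded on the model.  Scores
    are the projections of the standardized rows onto the eigenvectors;
    the sign of each component is fixed so its largest-magnitude loading
    is positive.  Variance fractions are reported over *all* components.
    """
    M = descriptor_matrix.copy().astype(float)
    if M.shape[0] < 3:
        raise ValueError("run_pca: need at least 3 descriptors")
    if not 1 <= n_pcs <= M.shape[1]:
        raise ValueError(f"run_pca: n_pcs must be in [1, {M.shape[1]}]")

    imputed_cells = []
    for col in M.columns:
        if M[col].isna().all():
            raise ValueError(f"run_pca: column {col!r} entirely missing")
        if M[col].isna().any():
            mean = M[col].mean()
            for idx in M.index[M[col].isna()]:
                imputed_cells.append((idx, col))
            M[col] = M[col].fillna(mean)
        if M[col].std(ddof=1) == 0:
            raise ValueError(f"run_pca: column {col!r} is constant")

    Z = (M - M.mean()) / M.std(ddof=1)
    corr = np.dot(Z.T, Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]
    # deterministic sign: largest-|loading| entry positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    fractions = eigval / eigval.sum()
    pcs = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=M.columns, columns=pcs)
    scores = pd.DataFrame(Z.values @ eigvec, index=M.index, columns=pcs)
    return PCAModel(
        variables=list(M.columns),
        loadings=loadings.iloc[:, :n_pcs],
        scores=scores.iloc[:, :n_pcs],
        variance_fraction=fractions[:n_pcs],
        all_variance_fractions=fractions,
        n_pcs=n_pcs,
        imputed_cells=imputed_cells,
    )


@dataclass
class PCResponseCorrelations:
    """Per-PC Pearson correlations of scores with the OL/QD percentages."""

    rho_ol: np.ndarray
    rho_qd: np.ndarray


def pc_response_correlations(pca: PCAModel, summary: pd.DataFrame) -> PCResponseCorrelations:
    """Correlate each retained PC's scores with the percentage vectors."""
    s = summary.set_index("descriptor_id").loc[pca.scores.index]
    for col in ("pct_ol", "pct_qd"):
        if np.std(s[col].to_numpy(dtype=float)) == 0:
            raise ValueError(
                f"pc_response_correlations: zero-variance {col} vector; "
                "the index is undefined"
            )
    rho_ol, rho_qd = [], []
    for pc in pca.scores.columns:
        _, r_ol, _ = pearson_with_p(pca.scores[pc], s["pct_ol"])
        _, r_qd, _ = pearson_with_p(pca.scores[pc], s["pct_qd"])
        rho_ol.append(r_ol)
        rho_qd.append(r_qd)
    return PCResponseCorrelations(rho_ol=np.array(rho_ol), rho_qd=np.array(rho_qd))


def compute_weights(
    pca: PCAModel, rho: PCResponseCorrelations, per_pc_minmax: bool = True
) -> pd.DataFrame:
    """Inverted, variance-weighted normalized scores per descriptor.

    ``per_pc_minmax`` (default) normalizes each PC's weighted scores to
    [0, 1] before applying the variance fractions, so every PC contributes
    on a common scale; the alternative normalizes with the global min/max
    across all retained PCs.  A degenerate PC (max == min) contributes the
    neutral 0.5 * v_p to every descriptor.
    """
    S = pca.scores.to_numpy(dtype=float)  # (d, P)
    v = np.asarray(pca.variance_fraction, dtype=float)
    out = pd.DataFrame({"descriptor_id": list(pca.scores.index)})
    for label, rho_vec in (("ol", rho.rho_ol), ("qd", rho.rho_qd)):
        W = S * np.asarray(rho_vec)[None, :]  # weighted scores, (d, P)
        if per_pc_minmax:
            lo, hi = W.min(axis=0), W.max(axis=0)
        else:
            lo = np.full(W.shape[1], W.min())
            hi = np.full(W.shape[1], W.max())
        span = hi - lo
        norm = np.empty_like(W)
        for p in range(W.shape[1]):
            if span[p] == 0:
                warnings.warn(
                    f"compute_weights: PC{p + 1} weighted {label} scores are "
                    "constant; contributing neutral 0.5 per descriptor",
                    stacklevel=2,
                )
                norm[:, p] = 0.5
            else:
                norm[:, p] = (W[:, p] - lo[p]) / span[p]
        out[f"{label}w"] = ((1.0 - norm) * v[None, :]).sum(axis=1)
        for p in range(W.shape[1]):
            out[f"{label}s_pc{p + 1}"] = W[:, p]
            out[f"{label}s_pc{p + 1}_min"] = lo[p]
            out[f"{label}s_pc{p + 1}_max"] = hi[p]
    return out


def severity_scores(coded: CodedResponses, weights: pd.DataFrame) -> pd.DataFrame:
    """Per-participant parosmia severity scores.

    ``ps_i`` is the weight-sum of the participant's affected descriptors
    divided by the maximal weight-sum attainable on the descriptors they
    classified (unknown-coded cells are excluded from D_i).  Participants
    with no classified descriptor, or a zero denominator, get a missing
    score with a warning.
    """
    w = weights.set_index("descriptor_id").loc[coded.descriptor_ids]
    olw = w["olw"].to_numpy(dtype=float)
    qdw = w["qdw"].to_numpy(dtype=float)
    obs = coded.observed.to_numpy(dtype=float)
    qd = coded.qd.to_numpy(dtype=float)
    ol = coded.ol.to_numpy(dtype=float)

    numer = (obs * (ol * olw[None, :] + qd * qdw[None, :])).sum(axis=1)
    denom = (obs * np.maximum(olw, qdw)[None, :]).sum(axis=1)
    n_classified = obs.sum(axis=1).astype(int)
    n_affected = (obs * (qd + ol)).sum(axis=1).astype(int)

    ps = np.full(len(numer), np.nan)
    ok = (n_classified > 0) & (denom > 0)
    ps[ok] = numer[ok] / denom[ok]
    if (~ok).any():
        warnings.warn(
            f"severity_scores: {int((~ok).sum())} participant(s) without a "
            "defined score (no classified descriptors or zero denominator)",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "participant_id": coded.participant_ids,
            "ps": ps,
            "n_classified": n_classified,
            "n_affected": n_affected,
        }
    )


#: Participant variables the index is evaluated against.
EVALUATION_VARIABLES = (
    "pct_affected",
    "subjective_impairment",
    "depression_adsl",
    "tdi",
    "threshold",
    "importance_olfaction",
)


def evaluate_severity(
    scores: pd.DataFrame, participants: pd.DataFrame, coded: CodedResponses
) -> pd.DataFrame:
    """Correlate the severity index with external participant variables.

    ``pct_affected`` (the share of classified descriptors reported QD or
    OL) is computed from the coded responses; the remaining variables come
    from the participant table.  Degenerate (constant) pairs yield NaN
    rows, flagged in the ``defined`` column.
    """
    df = scores.merge(participants, on="participant_id", how="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pct_affected"] = 100.0 * df["n_affected"] / df["n_classified"].replace(0, np.nan)
    rows = []
    for var in EVALUATION_VARIABLES:
        n, r, p = pearson_with_p(df["ps"], df[var])
        rows.append(
            {"variable": var, "n": n, "r": r, "p": p, "defined": bool(np.isfinite(r))}
        )
    return pd.DataFrame(rows)
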