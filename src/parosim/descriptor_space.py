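"""Even-dispersion descriptor subset selection in embedding space.

Given word-embedding vectors for candidate odor descriptors, selects k of
them by greedy farthest-point (maximin) sampling so the chosen words cover
the olfactory-semantic space evenly.  The greedy rule carries the
classical k-center guarantee: its minimum pairwise distance is at least
half the exhaustive optimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from parosim.types import SchemaError


def load_embeddings(path) -> pd.DataFrame:
    """Read ``descriptor_id,e1,...,eD`` CSV; unit-normalizes each vector."""
    df = pd.read_csv(path)
    if "descriptor_id" not in df.columns:
        raise SchemaError(str(path), None, "missing column(s) ['descriptor_id']")
    vec_cols = [c for c in df.columns if c != "descriptor_id"]
    if not vec_cols:
        raise SchemaError(str(path), None, "no embedding columns")
    X = df[vec_cols].to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if len(zero):
        raise SchemaError(str(path), int(zero[0]), "zero embedding vector")
    df[vec_cols] = X / norms[:, None]
    return df


def _distance_matrix(X: np.ndarray, distance: str) -> np.ndarray:
    if distance == "cosine":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if (norms == 0).any():
            raise ValueError("cosine distance undefined for zero vectors")
        U = X / norms
        return np.clip(1.0 - U @ U.T, 0.0, None)
    if distance == "euclidean":
        sq = (X**2).sum(axis=1)
        D2 = np.clip(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0, None)
        return np.sqrt(D2)
    raise ValueError(f"distance must be 'cosine' or 'euclidean', got {distance!r}")


def select_dispersed(embeddings, k: int, distance: str = "cosine", seed=None) -> list:
    """Greedy maximin selection of k descriptors.

    ``embeddings`` is a DataFrame with a ``descriptor_id`` column plus
    numeric vector columns (or a bare matrix with integer ids).  The seed
    is accepted for interface symmetry; the procedure is deterministic,
    with ties broken by input order: start from the maximum-distance pair,
    then repeatedly add the point whose minimum distance to the selected
    set is largest.
    """
    if isinstance(embeddings, pd.DataFrame):
        ids = list(embeddings["descriptor_id"])
        X = embeddings[[c for c in embeddings.columns if c != "descriptor_id"]].to_numpy(
            dtype=float
        )
    else:
        X = np.asarray(embeddings, dtype=float)
        ids = list(range(len(X)))
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"select_dispersed: k={k} outside [1, {n}]")
    if k == n:
        return list(ids)

    D = _distance_matrix(X, distance)
    if k == 1:
        return [ids[0]]
    # seed pair: maximum distance, first occurrence in row-major order
    flat = np.argmax(D)
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    mind = np.minimum(D[selected[0]], D[selected[1]])
    mind[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(mind))
        selected.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    return [ids[s] for s in selected]
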