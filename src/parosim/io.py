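"""Readers and writers for the cohort CSV schemas and result bundles.

Missing numeric cells are written as empty strings; the literal ``NA`` is
also accepted on input.  ``write_results`` emits one CSV per table plus a
``run.json`` with the config echo, seed and package versions, so a run can
be audited later.
"""

from __future__ import annotations

import json
import os
from dataclasses import is_dataclass

import numpy as np
import pandas as pd

from parosim.types import (
    Cohort,
    SchemaError,
    RESPONSE_CATEGORIES,
    validate_responses,
    validate_descriptors,
    validate_participants,
)

_NA_VALUES = ["", "NA"]


def _read_csv(path, source: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"{source} file not found: {path}")
    return pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=_NA_VALUES, skipinitialspace=True
    )


def load_cohort(responses_path, descriptors_path, participants_path) -> Cohort:
    """Read and validate the three cohort tables.

    Raises :class:`FileNotFoundError` for an absent file and
    :class:`~parosim.types.SchemaError` (naming file, row and rule) for any
    malformed cell; no silent coercion is performed.
    """
    responses = validate_responses(
        _read_csv(responses_path, "responses"), source=str(responses_path)
    )
    descriptors = validate_descriptors(
        _read_csv(descriptors_path, "descriptors"), source=str(descriptors_path)
    )
    participants = validate_participants(
        _read_csv(participants_path, "participants"), source=str(participants_path)
    )
    return Cohort(responses, descriptors, participants).validate()


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a cohort's three tables as CSV; returns {name: path}."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in (
        ("responses", cohort.responses),
        ("descriptors", cohort.descriptors),
        ("participants", cohort.participants),
    ):
        p = os.path.join(out_dir, f"{name}.csv")
        df.to_csv(p, index=False, na_rep="")
        paths[name] = p
    return paths


def responses_wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Convert one-row-per-patient questionnaire sheets to the long schema.

    The wide form has ``participant_id`` plus one column per descriptor id;
    cells hold response categories, empty cells are dropped (no response
    recorded for that odor).
    """
    if "participant_id" not in wide.columns:
        raise SchemaError("wide responses", None, "missing column(s) ['participant_id']")
    long = wide.melt(
        id_vars=["participant_id"], var_name="descriptor_id", value_name="response"
    )
    long = long[long["response"].notna() & (long["response"].astype(str) != "")]
    bad = long.index[~long["response"].isin(RESPONSE_CATEGORIES)]
    if len(bad):
        raise SchemaError(
            "wide responses", int(bad[0]),
            f"response {long.loc[bad[0], 'response']!r} not in {list(RESPONSE_CATEGORIES)}",
        )
    return long.reset_index(drop=True)


def _versions() -> dict:
    import scipy
    import statsmodels
    import parosim

    return {
        "parosim": parosim.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


#: Canonical file names for known result tables.
_RESULT_FILES = {
    "descriptor_summary": "descriptor_summary.csv",
    "correlations": "correlations.csv",
    "glmm_qd": "glmm_qd.csv",
    "glmm_ol": "glmm_ol.csv",
    "pca": "pca.csv",
    "weights": "weights.csv",
    "severity": "severity.csv",
    "severity_evaluation": "severity_evaluation.csv",
    "imputation_report": "imputation_report.csv",
}


def write_results(results_bundle: dict, out_dir, config=None, seed=None) -> list:
    """Write each table of the bundle as CSV plus a ``run.json`` manifest.

    ``results_bundle`` maps table names (see keys of the bundle contract:
    descriptor_summary, correlations, glmm_qd, glmm_ol, pca, weights,
    severity, severity_evaluation, imputation_report) to DataFrames.
    Returns the list of written paths; ``run.json`` is always written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, table in results_bundle.items():
        if table is None:
            continue
        fname = _RESULT_FILES.get(name, f"{name}.csv")
        path = os.path.join(out_dir, fname)
        # round-trip floats at full precision so reruns are byte-identical
        table.to_csv(path, index=False, na_rep="", float_format="%.12g")
        written.append(path)
    meta = {
        "seed": seed,
        "config": (config.to_dict() if is_dataclass(config) else config),
        "versions": _versions(),
        "tables": sorted(os.path.basename(p) for p in written),
    }
    run_path = os.path.join(out_dir, "run.json")
    with open(run_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    written.append(run_path)
    return written
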