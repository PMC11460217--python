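"""Readers and writers for the delimited-text interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_severity_csv",
    "read_covariates_csv",
    "write_severity_csv",
    "write_network_json",
    "write_json",
]


def read_severity_csv(path: str | Path) -> pd.DataFrame:
    """Patient-by-symptom severity matrix; first column is the patient id.

    Cells must be integers 0-4 or empty; out-of-range cells fail loudly with
    their row/column.
    """
    df = pd.read_csv(path, index_col=0)
    for col in df.columns:
        vals = df[col]
        bad = vals.dropna().loc[lambda s: ~s.isin([0, 1, 2, 3, 4])]
        if len(bad):
            rid = bad.index[0]
            raise ValueError(
                f"severity value {bad.iloc[0]!r} out of range 0-4 at row {rid!r}, column {col!r}"
            )
    return df


def read_covariates_csv(path: str | Path, severity: pd.DataFrame | None = None) -> pd.DataFrame:
    """Patient covariate table aligned with the severity matrix ids."""
    df = pd.read_csv(path, index_col=0)
    if severity is not None:
        missing = severity.index.difference(df.index)
        if len(missing):
            raise ValueError(f"covariate file missing patient ids: {sorted(missing)[:10]}")
        df = df.loc[severity.index]
    return df


def write_severity_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="patient_id")


def write_network_json(network, path: str | Path) -> None:
    payload = {
        "nodes": network.nodes,
        "weights": np.asarray(network.weights).tolist(),
        "lambda_selected": network.lambda_selected,
        "gamma": network.gamma,
        "n_used": network.n_used,
    }
    write_json(payload, path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
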