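"""Plain-text (TSV) readers and writers for the pipeline's tables.

Conventions: expression matrices have a ``feature_id`` first column and one
column per sample; sample tables are indexed by ``sample_id`` with columns
``os_years, os_event, subgroup`` plus optional clinical covariates; arm-call
matrices are ``sample_id`` x arm labels with values in {-1, 0, 1}. Reals are
written with 6 decimals.
"""

from __future__ import annotations

import pandas as pd

from .preprocess import ExpressionMatrix

_FLOAT_FMT = "%.6f"


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression_tsv(path, scale: str = "log2") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return ExpressionMatrix(values=df, scale=scale)


def write_sample_tsv(samples: pd.DataFrame, path) -> None:
    df = samples.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_sample_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("os_years", "os_event", "subgroup"):
        if col not in df.columns:
            raise ValueError(f"sample table missing required column {col!r}")
    return df


def write_arm_calls_tsv(calls: pd.DataFrame, path) -> None:
    df = calls.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_arm_calls_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    bad = ~df.isin([-1, 0, 1]).all(axis=None)
    if bad:
        raise ValueError("arm-call matrix must contain only -1, 0, 1")
    return df.astype(int)


def write_probe_map_tsv(probe_map: pd.Series, path) -> None:
    df = probe_map.rename("gene").to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def read_probe_map_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    if df.index.duplicated().any():
        raise ValueError("a probe maps to more than one gene")
    return df["gene"]
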