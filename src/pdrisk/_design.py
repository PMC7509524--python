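"""Shared design-matrix encoding for the regression modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_PRS_COVARIATES = ("age", "sex", "townsend", "pc1", "pc2", "pc3", "pc4")


def encode_column(df: pd.DataFrame, col: str) -> pd.DataFrame:
    """Encode one cohort column as numeric regressor(s).

    ``sex`` becomes a male indicator; other non-numeric columns are dummy
    coded against their first level; numeric columns pass through.
    """
    s = df[col]
    if col == "sex":
        return pd.DataFrame({"sex_male": (s == "male").astype(float)}, index=df.index)
    if not pd.api.types.is_numeric_dtype(s):
        return pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
    return pd.DataFrame({col: s.astype(float)}, index=df.index)


def design_matrix(
    df: pd.DataFrame, cols: tuple[str, ...] | list[str], add_const: bool = True
) -> pd.DataFrame:
    parts = [encode_column(df, c) for c in cols]
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    if add_const:
        X.insert(0, "const", 1.0)
    return X


def complete_cases(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return df.dropna(subset=[c for c in cols if c in df.columns])


def rank_deficient(X: np.ndarray) -> bool:
    X = np.asarray(X, dtype=float)
    return np.linalg.matrix_rank(X) < X.shape[1]
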