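"""Design-matrix construction shared by the longitudinal, survival and joint models.

Categorical covariates are expanded into treatment (dummy) contrasts against a
declared reference level; the reference levels follow the conventions of the
hypertension-cohort study variables (e.g. "No", "Normal", "Good", "Negative").
Numeric covariates enter as-is.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

#: Reference category per study covariate. Unknown categoricals fall back to the
#: first level in sorted order.
CATEGORICAL_REFERENCES: dict[str, str] = {
    "gender": "Male",
    "residence": "Rural",
    "age_group": "<=50",
    "alcohol": "No",
    "khat": "No",
    "smoking": "No",
    "stress": "No",
    "stage": "Normal",
    "lifestyle_change": "No",
    "cholesterol": "Normal",
    "adherence": "Good",
    "related_disease": "None",
    "family_history": "Negative",
    "diabetes": "No",
}


def _levels(series: pd.Series, name: str) -> list[str]:
    present = sorted(str(v) for v in series.dropna().unique())
    ref = CATEGORICAL_REFERENCES.get(name)
    if ref is None or ref not in present:
        ref = present[0]
    return [ref] + [lev for lev in present if lev != ref]


def is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series)


def term_columns(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    """Expand one model term into design columns (without intercept)."""
    if term not in df.columns:
        raise KeyError(f"term {term!r} not found in data columns")
    s = df[term]
    if is_numeric(s):
        return np.asarray(s, dtype=float)[:, None], [term]
    levels = _levels(s, term)
    vals = s.astype(str).to_numpy()
    cols = [(vals == lev).astype(float) for lev in levels[1:]]
    names = [f"{term}[{lev}]" for lev in levels[1:]]
    if not cols:  # single observed level: constant covariate
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names


def build_design(
    df: pd.DataFrame,
    terms: tuple[str, ...] | list[str],
    intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Build (X, column_names) for the given terms.

    Raises ValueError naming the aliased column if X is rank deficient.
    """
    blocks = []
    names: list[str] = []
    if intercept:
        blocks.append(np.ones((len(df), 1)))
        names.append("intercept")
    for term in terms:
        cols, cnames = term_columns(df, term)
        blocks.append(cols)
        names.extend(cnames)
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    if X.shape[1]:
        # QR with column pivoting to locate aliased columns
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            _, R, piv = _qr_pivot(X)
            bad = sorted(piv[r:])
            bad_names = [names[j] for j in bad]
            raise ValueError(
                f"design matrix is rank deficient; aliased column(s): {bad_names}"
            )
    return X, names


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def linear_predictor(df: pd.DataFrame, coeffs: dict[str, float]) -> np.ndarray:
    """Evaluate sum of coefficient * column for coefficient keys of the form
    ``"name[level]"`` (categorical indicator), ``"name"`` (numeric column),
    ``"intercept"`` or ``"time"`` (handled by callers)."""
    out = np.full(len(df), float(coeffs.get("intercept", 0.0)))
    for key, val in coeffs.items():
        if key in ("intercept", "time") or val == 0.0:
            continue
        if "[" in key:
            name, level = key[:-1].split("[", 1)
            if name not in df.columns:
                raise KeyError(f"coefficient {key!r}: covariate {name!r} missing")
            out += val * (df[name].astype(str).to_numpy() == level)
        else:
            if key not in df.columns:
                raise KeyError(f"coefficient {key!r}: covariate missing")
            out += val * np.asarray(df[key], dtype=float)
    return out
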