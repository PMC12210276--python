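"""Design matrices for the accessibility models.

The base model is a cell-means coding of the cell type x diagnosis interaction
(one indicator per combination, no intercept) plus a sex indicator — four
interaction levels and two sex levels, five estimated coefficients. The
case-vs-control contrast within a cell type is the difference of the two
corresponding cell-means columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import SampleSheet, ValidationError

__all__ = ["base_design", "contrast_vector"]


def base_design(sheet: SampleSheet) -> pd.DataFrame:
    """Cell-means design: one column per (cell_type, diagnosis) combination
    plus sex_male; rows indexed by sample id."""
    df = sheet.data
    combos = sorted(
        {(ct, dx) for ct, dx in zip(df["cell_type"], df["diagnosis"])}
    )
    X = pd.DataFrame(index=df["sample_id"])
    for ct, dx in combos:
        X[f"{ct}:{dx}"] = (
            ((df["cell_type"] == ct) & (df["diagnosis"] == dx)).astype(float).to_numpy()
        )
    X["sex_male"] = (df["sex"] == "male").astype(float).to_numpy()
    return X


def contrast_vector(design_columns, cell_type: str) -> np.ndarray:
    """case minus control within ``cell_type`` over the given design columns."""
    cols = list(design_columns)
    case = f"{cell_type}:case"
    ctrl = f"{cell_type}:control"
    if case not in cols or ctrl not in cols:
        raise ValidationError(
            f"design has no case/control pair for cell type {cell_type!r}"
        )
    c = np.zeros(len(cols))
    c[cols.index(case)] = 1.0
    c[cols.index(ctrl)] = -1.0
    return c
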