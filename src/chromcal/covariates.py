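"""BIC covariate ledger.

Candidate sample-level covariates (library QC metrics and the like) are
screened for inclusion in the differential model by asking, region by region,
whether appending the candidate to the base design improves the Bayesian
Information Criterion. A candidate joins the model only if at least
``min_fraction`` of regions improve by at least ``delta_bic`` (default 4,
conventional "positive" evidence). The ledger also reports the improved-minus-
worse region counts and a sensitivity grid over delta_bic in {2, 4, 10} and
min_fraction in {0.02, 0.05}.

Ledger fits are plain OLS under a Gaussian likelihood of the normalized
values; the subject random intercept of the final model is deliberately absent
here — the ledger is a screening heuristic, not the inference model. Technical
covariates are median-centered within cell type before screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SampleSheet, ValidationError
from .design import base_design

__all__ = ["LedgerConfig", "LedgerReport", "region_bic", "bic_ledger"]

RSS_FLOOR = 1e-12


@dataclass
class LedgerConfig:
    candidates: list[str] = field(default_factory=list)
    delta_bic: float = 4.0
    min_fraction: float = 0.05
    delta_bic_grid: tuple[float, ...] = (2.0, 4.0, 10.0)
    min_fraction_grid: tuple[float, ...] = (0.02, 0.05)
    center_within: str | None = "cell_type"

    def validate(self, sheet: SampleSheet) -> None:
        if self.delta_bic <= 0:
            raise ValidationError("delta_bic must be > 0")
        if not 0 < self.min_fraction < 1:
            raise ValidationError("min_fraction must be in (0, 1)")
        for c in self.candidates:
            if c not in sheet.data.columns:
                raise ValidationError(f"candidate {c!r} not a sample-sheet column")
            if c in SampleSheet.REQUIRED:
                raise ValidationError(f"candidate {c!r} is a base design term")


@dataclass
class LedgerReport:
    """Per-candidate screening outcome plus the sensitivity grid."""

    table: pd.DataFrame  # n_improved, n_worse, net, frac_exceeding, included,
    #                      collinear
    grid: pd.DataFrame  # candidate x (delta_bic, min_fraction) -> included
    config: LedgerConfig

    @property
    def included(self) -> list[str]:
        return list(self.table.index[self.table["included"]])


def region_bic(values: np.ndarray, design_matrix: np.ndarray) -> float:
    """BIC of an OLS fit of one region's normalized values on the design.

    BIC = n * ln(RSS / n) + k * ln(n) with k counting all coefficients plus
    the residual variance. RSS is floored at 1e-12 (perfect fits would send
    the criterion to -inf).
    """
    y = np.asarray(values, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValidationError("need n_samples > n_parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError(
            f"rank-deficient design: rank {rank} < {p} columns "
            "(collinear columns present)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    if rss < RSS_FLOOR:
        warnings.warn("RSS below floor; BIC computed at the floor value")
        rss = RSS_FLOOR
    k = p + 1
    return n * np.log(rss / n) + k * np.log(n)


def _batch_rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """RSS of every row of Y regressed on X (full-rank), via QR projection."""
    Q, _ = np.linalg.qr(X)
    resid = Y - (Y @ Q) @ Q.T
    return np.einsum("ij,ij->i", resid, resid)


def bic_ledger(
    normalized: pd.DataFrame,
    sheet: SampleSheet,
    config: LedgerConfig,
) -> LedgerReport:
    """Screen every candidate covariate against the base design.

    improvement[r] = BIC_base[r] - BIC_extended[r]; with one extra coefficient
    this equals n * ln(RSS0/RSS1) - ln(n). The candidate evaluation order does
    not affect results (each candidate is screened independently against the
    same base)."""
    config.validate(sheet)
    sheet = sheet.aligned_to(normalized.columns)
    X0 = base_design(sheet).to_numpy()
    n, p0 = X0.shape
    if np.linalg.matrix_rank(X0) < p0:
        raise ValidationError("base design is rank deficient")
    Y = normalized.to_numpy().astype(float)
    n_regions = Y.shape[0]
    if n <= p0 + 1:
        raise ValidationError("too few samples for ledger fits")

    rss0 = np.maximum(_batch_rss(Y, X0), RSS_FLOOR)

    rows = []
    grid_rows = []
    for cand in config.candidates:
        x = sheet.data[cand].to_numpy().astype(float)
        if config.center_within is not None:
            grp = sheet.data[config.center_within]
            x = x - pd.Series(x).groupby(grp.to_numpy()).transform("median").to_numpy()
        X1 = np.column_stack([X0, x])
        collinear = np.linalg.matrix_rank(X1) < p0 + 1
        if collinear:
            improvement = np.full(n_regions, -np.log(n))  # extra param, no fit gain
        else:
            rss1 = np.maximum(_batch_rss(Y, X1), RSS_FLOOR)
            improvement = n * np.log(rss0 / rss1) - np.log(n)
        n_improved = int((improvement > 0).sum())
        n_worse = int((improvement < 0).sum())
        frac_exceeding = float((improvement >= config.delta_bic).mean())
        rows.append(
            {
                "candidate": cand,
                "n_improved": n_improved,
                "n_worse": n_worse,
                "net": n_improved - n_worse,
                "frac_exceeding": frac_exceeding,
                "included": (not collinear)
                and frac_exceeding >= config.min_fraction,
                "collinear": collinear,
            }
        )
        for db in config.delta_bic_grid:
            for mf in config.min_fraction_grid:
                frac = float((improvement >= db).mean())
                grid_rows.append(
                    {
                        "candidate": cand,
                        "delta_bic": db,
                        "min_fraction": mf,
                        "frac_exceeding": frac,
                        "included": (not collinear) and frac >= mf,
                    }
                )

    table = pd.DataFrame(rows).set_index("candidate") if rows else pd.DataFrame(
        columns=[
            "n_improved",
            "n_worse",
            "net",
            "frac_exceeding",
            "included",
            "collinear",
        ]
    )
    grid = pd.DataFrame(grid_rows)
    return LedgerReport(table=table, grid=grid, config=config)
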