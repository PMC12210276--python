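"""Count filtering and two-stage normalization.

Pipeline order: low-signal regions are removed by the CPM >= 1 in >= 10% of
samples rule, counts are scaled between samples with trimmed-mean-of-M-values
(TMM) effective library sizes, converted to log2 CPM with a prior count, and
finally quantile-normalized within groups of samples of the same cell type so
that per-group column distributions agree exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import RegionCountMatrix, SampleSheet, ValidationError

__all__ = [
    "NormalizationParams",
    "cpm_transform",
    "filter_low_signal",
    "tmm_factors",
    "quantile_normalize_within_group",
    "normalize_pipeline",
]


@dataclass
class NormalizationParams:
    """Filtering and normalization knobs.

    cpm_threshold / min_fraction implement the "CPM >= 1 in at least 10% of
    samples" retention rule; tmm_trim_M and tmm_trim_A are the two-sided trim
    fractions of the M-value (log-ratio) and A-value (log-abundance) tails;
    quantile normalization is grouped by ``quantile_group_key``; ``prior_count``
    stabilizes log2 CPM at low counts.
    """

    cpm_threshold: float = 1.0
    min_fraction: float = 0.10
    tmm_trim_M: float = 0.30
    tmm_trim_A: float = 0.05
    quantile_group_key: str = "cell_type"
    prior_count: float = 0.5

    def validate(self) -> None:
        if self.cpm_threshold <= 0:
            raise ValidationError("cpm_threshold must be > 0")
        if not 0 < self.min_fraction <= 0.5:
            raise ValidationError("min_fraction must be in (0, 0.5]")
        for name in ("tmm_trim_M", "tmm_trim_A"):
            v = getattr(self, name)
            if not 0 < v <= 0.5:
                raise ValidationError(f"{name} must be in (0, 0.5]")
        if self.prior_count <= 0:
            raise ValidationError("prior_count must be > 0")


def cpm_transform(matrix: RegionCountMatrix) -> pd.DataFrame:
    """Counts per million: counts[r, s] / library_size[s] * 1e6."""
    libs = matrix.library_sizes
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValidationError(f"zero/negative library size for samples: {bad}")
    return matrix.counts / libs * 1e6


def filter_low_signal(
    matrix: RegionCountMatrix, params: NormalizationParams | None = None
) -> tuple[RegionCountMatrix, list[str]]:
    """Keep regions with CPM >= threshold in at least ceil(min_fraction * n)
    samples; returns (filtered matrix, removed region ids) in original order."""
    params = params or NormalizationParams()
    params.validate()
    cpm = cpm_transform(matrix)
    min_samples = math.ceil(params.min_fraction * matrix.n_samples)
    n_passing = (cpm >= params.cpm_threshold).sum(axis=1)
    keep_mask = n_passing >= min_samples
    kept = list(matrix.counts.index[keep_mask])
    removed = list(matrix.counts.index[~keep_mask])
    if not kept:
        raise ValidationError(
            "all regions removed by the CPM filter; lower cpm_threshold or "
            "min_fraction"
        )
    return matrix.subset_regions(kept), removed


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference.

    M/A values are computed on regions nonzero in both samples, doubly trimmed
    (trim_m of the M tails, trim_a of the A tails, rank-based), and averaged
    with inverse asymptotic-variance (delta-method binomial) weights.
    """
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValidationError("no regions nonzero in both sample and reference")
    o, r = obs[both].astype(float), ref[both].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def tmm_factors(
    matrix: RegionCountMatrix,
    params: NormalizationParams | None = None,
    reference: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose 75th-percentile CPM is closest
    to the mean of those percentiles. The factor multiplies the library size:
    effective library = library_size * factor.
    """
    params = params or NormalizationParams()
    params.validate()
    if matrix.n_samples < 2:
        raise ValidationError("TMM needs >= 2 samples")
    counts = matrix.counts.to_numpy().astype(float)
    libs = matrix.library_sizes.to_numpy().astype(float)
    if (counts.sum(axis=0) == 0).any():
        raise ValidationError("sample with all-zero counts")

    if reference is None:
        f75 = np.array(
            [np.quantile(counts[:, j] / libs[j], 0.75) for j in range(len(libs))]
        )
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = matrix.samples.index(reference)

    log_f = np.array(
        [
            _tmm_pair(
                counts[:, j],
                counts[:, ref_idx],
                libs[j],
                libs[ref_idx],
                params.tmm_trim_M,
                params.tmm_trim_A,
            )
            for j in range(counts.shape[1])
        ]
    )
    factors = np.exp2(log_f)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.samples, name="tmm_factor")


def quantile_normalize_within_group(
    values: pd.DataFrame, groups: pd.Series | dict, ties: str = "order"
) -> pd.DataFrame:
    """Within each sample group, force every column to the cross-sample mean of
    order statistics.

    ``ties="order"`` (default) breaks tied values deterministically by their
    original row order, so every column receives exactly the target multiset
    and per-group distributions agree bit-for-bit. ``ties="average"`` instead
    assigns tied values the mean of their target quantiles (rank-average
    convention); distributions then agree only up to the within-tie spread of
    the target."""
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        bad = list(groups.index[groups.isna()])
        raise ValidationError(f"no group for samples: {bad}")
    out = values.copy().astype(float)
    for _group, cols in groups.groupby(groups).groups.items():
        cols = list(cols)
        if len(cols) == 1:
            warnings.warn(f"group {_group!r} has a single sample; passthrough")
            continue
        block = values[cols].to_numpy().astype(float)
        target = np.sort(block, axis=0).mean(axis=1)
        for j, c in enumerate(cols):
            out[c] = _assign_quantiles(block[:, j], target, ties)
    return out


def _assign_quantiles(col: np.ndarray, target: np.ndarray, ties: str) -> np.ndarray:
    """Map a column onto the target order statistics with the chosen tie
    policy (stable original-order assignment or rank-average)."""
    if ties not in ("order", "average"):
        raise ValidationError(f"unknown tie policy {ties!r}")
    order = np.argsort(col, kind="mergesort")
    result = np.empty_like(target)
    result[order] = target
    if ties == "average":
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(col)]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                result[order[s:e]] = target[s:e].mean()
    return result


def normalize_pipeline(
    matrix: RegionCountMatrix,
    sheet: SampleSheet,
    params: NormalizationParams | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """TMM-adjusted log2 CPM followed by within-cell-type quantile
    normalization; returns (normalized matrix, TMM factors).

    log2 CPM uses effective library sizes (library * TMM factor) and the
    configured prior count: log2((count + prior) / effective_library * 1e6).
    """
    params = params or NormalizationParams()
    params.validate()
    sheet = sheet.aligned_to(matrix.samples)
    factors = tmm_factors(matrix, params)
    eff_lib = matrix.library_sizes * factors
    logcpm = np.log2(
        (matrix.counts + params.prior_count) / eff_lib.to_numpy()[None, :] * 1e6
    )
    groups = sheet.data.set_index("sample_id")[params.quantile_group_key]
    normalized = quantile_normalize_within_group(logcpm, groups)
    return normalized, factors
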