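"""Core data containers.

All downstream statistics operate on these validated containers rather than on
raw files: a region-by-sample count matrix with BED-convention coordinates, a
per-sample design sheet, a genotype call table, a calcium-imaging session, and
a named gene-set collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromcalError",
    "ValidationError",
    "RegionCountMatrix",
    "SampleSheet",
    "GenotypeTable",
    "CalciumSession",
    "GeneSetCollection",
]


class ChromcalError(Exception):
    """Base class for package errors."""


class ValidationError(ChromcalError):
    """An input object violated a documented invariant."""


@dataclass
class RegionCountMatrix:
    """Integer read counts over genomic regions x samples.

    ``regions`` is a DataFrame with columns chrom/start/end indexed by region
    id (BED half-open, 0-based). ``counts`` is a regions x samples DataFrame of
    nonnegative integers. ``library_sizes`` defaults to column sums.
    """

    regions: pd.DataFrame
    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not {"chrom", "start", "end"}.issubset(self.regions.columns):
            raise ValidationError("regions must have chrom/start/end columns")
        if self.regions.index.duplicated().any():
            dups = self.regions.index[self.regions.index.duplicated()].tolist()
            raise ValidationError(f"duplicate region ids: {dups[:5]}")
        if (self.regions["start"] >= self.regions["end"]).any():
            bad = self.regions.index[self.regions["start"] >= self.regions["end"]]
            raise ValidationError(f"regions with start >= end: {list(bad[:5])}")
        if not self.counts.index.equals(self.regions.index):
            raise ValidationError("counts rows do not match region ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise ValidationError("library_sizes missing for some samples")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0].tolist()
            raise ValidationError(f"nonpositive library size for samples: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_regions(self, region_ids) -> "RegionCountMatrix":
        """Row subset preserving library sizes (library size is a sample-level
        quantity; it does not shrink when regions are dropped)."""
        region_ids = list(region_ids)
        return RegionCountMatrix(
            regions=self.regions.loc[region_ids],
            counts=self.counts.loc[region_ids],
            library_sizes=self.library_sizes.copy(),
        )


@dataclass
class SampleSheet:
    """Per-sample design factors and candidate nuisance covariates.

    Required columns: sample_id, subject_id, cell_type, diagnosis
    ({case, control}), sex ({male, female, unknown}). Any additional numeric
    columns are treated as candidate covariates.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "cell_type", "diagnosis", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sheet")
        bad_dx = set(self.data["diagnosis"]) - {"case", "control"}
        if bad_dx:
            raise ValidationError(f"unknown diagnosis levels: {sorted(bad_dx)}")
        bad_sex = set(self.data["sex"]) - {"male", "female", "unknown"}
        if bad_sex:
            raise ValidationError(f"unknown sex levels: {sorted(bad_sex)}")
        self.data = self.data.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def covariate_names(self) -> list[str]:
        extra = [c for c in self.data.columns if c not in self.REQUIRED]
        return [c for c in extra if pd.api.types.is_numeric_dtype(self.data[c])]

    def aligned_to(self, samples) -> "SampleSheet":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from sheet: {missing}")
        return SampleSheet(self.data.loc[samples].reset_index(drop=True))


#: missing genotype code in GenotypeTable.calls
MISSING = -1


@dataclass
class GenotypeTable:
    """Variant x sample genotype calls in {0, 1, 2, MISSING}.

    ``variants``: DataFrame with chrom, pos (1-based), maf, is_par columns.
    ``calls``: int array (n_variants x n_samples), -1 for missing.
    """

    variants: pd.DataFrame
    calls: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "maf", "is_par"}
        if not need.issubset(self.variants.columns):
            raise ValidationError(f"variants must have columns {sorted(need)}")
        if ((self.variants["maf"] < 0) | (self.variants["maf"] > 0.5)).any():
            raise ValidationError("maf outside [0, 0.5]")
        if (self.variants["pos"] < 1).any():
            raise ValidationError("positions must be 1-based (>= 1)")
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        ok = np.isin(self.calls, [MISSING, 0, 1, 2])
        if not ok.all():
            raise ValidationError("genotype calls must be in {-1, 0, 1, 2}")

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ValidationError(f"unknown sample: {sample}") from None


@dataclass
class CalciumSession:
    """Cells x time dF/F traces at a fixed sampling rate with event intervals.

    ``events`` is a list of (start_s, end_s) occupancy intervals; interval
    starts serve as entry-event timestamps for peri-event statistics.
    """

    cell_ids: list[str]
    rate_hz: float
    traces: np.ndarray
    events: list[tuple[float, float]] = field(default_factory=list)
    session_id: str = "session"

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be > 0")
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2 or self.traces.shape[0] != len(self.cell_ids):
            raise ValidationError("traces must be (n_cells, n_timepoints)")
        if not np.isfinite(self.traces).all():
            bad = [
                self.cell_ids[i]
                for i in np.where(~np.isfinite(self.traces).all(axis=1))[0]
            ]
            raise ValidationError(f"non-finite trace values for cells: {bad}")
        dur = self.duration_s
        for s, e in self.events:
            if not (0 <= s < e <= dur + 1e-9):
                raise ValidationError(f"event ({s}, {e}) outside [0, {dur:.3f}]")
        for (s0, e0), (s1, e1) in zip(self.events, self.events[1:]):
            if s1 < e0:
                raise ValidationError(f"overlapping events ({s0},{e0}) and ({s1},{e1})")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.rate_hz

    @property
    def entry_times(self) -> np.ndarray:
        return np.array([s for s, _ in self.events])


@dataclass
class GeneSetCollection:
    """Named gene sets over a common gene universe."""

    universe: set[str]
    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        for name, genes in self.sets.items():
            extra = set(genes) - self.universe
            if extra:
                raise ValidationError(
                    f"set {name!r} has genes outside universe: {sorted(extra)[:5]}"
                )
            self.sets[name] = set(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)
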