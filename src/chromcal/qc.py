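"""Sample-identity and library-quality metrics.

Genetic sex is inferred from three signals — chromosome-X heterozygosity
outside the pseudoautosomal regions, summed CPM in female-marker regions
(peaks adjacent to genes such as XIST/FIRRE that are predominantly accessible
in females), and summed CPM in non-PAR chromosome-Y regions — combined by
majority vote, each binarized by a data-driven two-means split (the study
design reports no numeric cutoffs). Sample identity is checked with the
fraction of concordant genotype calls over common variants (MAF >= 25%).
PBC and FRiP are the usual enrichment/complexity ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    GenotypeTable,
    RegionCountMatrix,
    ValidationError,
)
from .normalize import cpm_transform

__all__ = [
    "SexQCReport",
    "chrx_het_rate",
    "marker_region_cpm",
    "infer_sex",
    "genotype_concordance",
    "pbc",
    "frip",
    "two_means_threshold",
]


def chrx_het_rate(
    genotypes: GenotypeTable, sample: str, maf_min: float = 0.05
) -> float:
    """Heterozygous / nonmissing calls among chrX non-PAR variants with
    MAF >= maf_min. High rates in an annotated male indicate contamination or
    a sex mismatch."""
    j = genotypes.sample_index(sample)
    mask = (
        (genotypes.variants["chrom"] == "chrX")
        & (~genotypes.variants["is_par"])
        & (genotypes.variants["maf"] >= maf_min)
    ).to_numpy()
    calls = genotypes.calls[mask, j]
    nonmiss = calls != MISSING
    if not mask.any() or not nonmiss.any():
        raise ValidationError(
            f"no eligible chrX non-PAR variants for sample {sample!r}"
        )
    return float((calls[nonmiss] == 1).sum() / nonmiss.sum())


def marker_region_cpm(matrix: RegionCountMatrix, marker_region_ids) -> pd.Series:
    """Per-sample summed CPM over a marker region set (female markers or
    non-PAR chrY regions)."""
    marker_region_ids = list(marker_region_ids)
    unknown = [r for r in marker_region_ids if r not in matrix.counts.index]
    if unknown:
        raise ValidationError(f"unknown marker region ids: {unknown[:5]}")
    cpm = cpm_transform(matrix)
    return cpm.loc[marker_region_ids].sum(axis=0)


def two_means_threshold(values: np.ndarray) -> float | None:
    """Optimal 1-D two-cluster split (exact 2-means on sorted values); returns
    the midpoint of the two cluster means, or None if the values do not
    separate (fewer than 2 distinct values)."""
    x = np.asarray(values, dtype=float)
    x = np.sort(x[~np.isnan(x)])
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return None
    csum = np.cumsum(x)
    total = csum[-1]
    best_ss, best_k = np.inf, None
    for k in range(1, n):  # left cluster = x[:k]
        m1 = csum[k - 1] / k
        m2 = (total - csum[k - 1]) / (n - k)
        ss = np.sum((x[:k] - m1) ** 2) + np.sum((x[k:] - m2) ** 2)
        if ss < best_ss:
            best_ss, best_k = ss, k
    m1 = csum[best_k - 1] / best_k
    m2 = (total - csum[best_k - 1]) / (n - best_k)
    return float((m1 + m2) / 2)


@dataclass
class SexQCReport:
    """Per-sample sex metrics, inferred sex and annotation mismatch flags."""

    table: pd.DataFrame  # chrx_het_rate, female_marker_cpm, chry_cpm,
    #                      inferred_sex, annotated_sex, mismatch_flag
    thresholds: dict

    def mismatched_samples(self) -> list[str]:
        return list(self.table.index[self.table["mismatch_flag"]])


def infer_sex(
    metrics: pd.DataFrame,
    annotated_sex: pd.Series | None = None,
    thresholds: dict | None = None,
) -> SexQCReport:
    """Majority vote over three binarized metrics.

    ``metrics`` columns: chrx_het_rate, female_marker_cpm, chry_cpm (rows =
    samples). High chrX heterozygosity -> female vote; high female-marker
    CPM -> female vote; high chrY CPM -> male vote. Thresholds default to
    two-means splits across the cohort and may be overridden per metric.
    2-1 votes yield the majority; a metric without a usable threshold
    abstains; no usable metric (or a tie) -> ambiguous.
    """
    need = {"chrx_het_rate", "female_marker_cpm", "chry_cpm"}
    if not need.issubset(metrics.columns):
        raise ValidationError(f"metrics must have columns {sorted(need)}")
    thresholds = dict(thresholds or {})
    for col in need:
        if col not in thresholds:
            thresholds[col] = two_means_threshold(metrics[col].to_numpy())

    female_if_high = {"chrx_het_rate": True, "female_marker_cpm": True, "chry_cpm": False}
    inferred = []
    for sample, row in metrics.iterrows():
        votes = 0  # +1 female, -1 male
        n_votes = 0
        for col in ("chrx_het_rate", "female_marker_cpm", "chry_cpm"):
            thr = thresholds[col]
            if thr is None or pd.isna(row[col]):
                continue
            high = row[col] > thr
            is_female = high if female_if_high[col] else not high
            votes += 1 if is_female else -1
            n_votes += 1
        if n_votes == 0 or votes == 0:
            inferred.append("ambiguous")
        else:
            inferred.append("female" if votes > 0 else "male")

    table = metrics.copy()
    table["inferred_sex"] = inferred
    if annotated_sex is not None:
        table["annotated_sex"] = annotated_sex.reindex(metrics.index)
        table["mismatch_flag"] = (
            (table["inferred_sex"] != "ambiguous")
            & table["annotated_sex"].isin(["male", "female"])
            & (table["inferred_sex"] != table["annotated_sex"])
        )
    else:
        table["annotated_sex"] = "unknown"
        table["mismatch_flag"] = False
    return SexQCReport(table=table, thresholds=thresholds)


def genotype_concordance(
    genotypes: GenotypeTable,
    sample_a: str,
    sample_b: str,
    maf_min: float = 0.25,
) -> float:
    """Fraction of matching genotype calls between two samples over variants
    with MAF >= maf_min, restricted to calls nonmissing in both."""
    ia, ib = genotypes.sample_index(sample_a), genotypes.sample_index(sample_b)
    eligible = (genotypes.variants["maf"] >= maf_min).to_numpy()
    a = genotypes.calls[eligible, ia]
    b = genotypes.calls[eligible, ib]
    shared = (a != MISSING) & (b != MISSING)
    if not shared.any():
        raise ValidationError(
            f"no shared nonmissing variants with MAF >= {maf_min} between "
            f"{sample_a!r} and {sample_b!r}"
        )
    return float((a[shared] == b[shared]).sum() / shared.sum())


def pbc(uniquely_mapped: int, nonredundant: int) -> float:
    """PCR bottleneck coefficient: nonredundant / uniquely mapped reads."""
    if uniquely_mapped <= 0:
        raise ValidationError("uniquely_mapped must be > 0")
    if not 0 <= nonredundant <= uniquely_mapped:
        raise ValidationError("need 0 <= nonredundant <= uniquely_mapped")
    return nonredundant / uniquely_mapped


def frip(reads_in_peaks: int, total_reads: int) -> float:
    """Fraction of reads in peaks."""
    if total_reads <= 0:
        raise ValidationError("total_reads must be > 0")
    if not 0 <= reads_in_peaks <= total_reads:
        raise ValidationError("need 0 <= reads_in_peaks <= total_reads")
    return reads_in_peaks / total_reads
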