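"""Readers and writers for the standard on-disk formats.

Counts travel as TSV (regions x samples) or MatrixMarket plus a BED file of
region coordinates (0-based, half-open) and a CSV sample sheet; genotypes as
minimal VCF v4.2 with a GT-only FORMAT; calcium traces as wide CSV with a
time_s column; events as (start_s, end_s) CSV; gene sets as GMT. Every writer
has a loader that round-trips to an equal object.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .datamodel import (
    MISSING,
    CalciumSession,
    GenotypeTable,
    GeneSetCollection,
    RegionCountMatrix,
    SampleSheet,
    ValidationError,
)
from .simulate import DEFAULT_PAR_INTERVALS

logger = logging.getLogger(__name__)

__all__ = [
    "write_counts_tsv",
    "write_counts_mtx",
    "write_bed",
    "write_sample_sheet",
    "load_counts",
    "write_vcf",
    "load_genotypes",
    "write_calcium",
    "load_calcium",
    "write_gmt",
    "load_gmt",
]


# ---------------------------------------------------------------- count matrix

def write_counts_tsv(matrix: RegionCountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="region_id")


def write_counts_mtx(matrix: RegionCountMatrix, path) -> None:
    """MatrixMarket sparse counts; row/column ids live in the BED/sheet."""
    mmwrite(str(path), csr_matrix(matrix.counts.to_numpy()))


def write_bed(matrix: RegionCountMatrix, path) -> None:
    bed = matrix.regions[["chrom", "start", "end"]].copy()
    bed["name"] = matrix.regions.index
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index=False)


def load_counts(path, bed_path, sheet_path) -> tuple[RegionCountMatrix, SampleSheet]:
    """Load counts (TSV or MatrixMarket), BED regions and the sample sheet into
    cross-validated objects; library sizes are column sums."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    if bed["name"].isna().any():
        raise ValidationError("BED file must carry region ids in column 4")
    regions = bed.set_index("name")[["chrom", "start", "end"]]
    regions.index.name = None

    sheet_df = pd.read_csv(sheet_path)
    sheet = SampleSheet(sheet_df)

    path = Path(path)
    if path.suffix in (".mtx", ".mm"):
        mat = np.asarray(mmread(str(path)).todense())
        if mat.shape[0] != len(regions):
            raise ValidationError(
                f"matrix rows ({mat.shape[0]}) != BED regions ({len(regions)})"
            )
        if mat.shape[1] != len(sheet.sample_ids):
            raise ValidationError(
                f"matrix columns ({mat.shape[1]}) != sheet samples "
                f"({len(sheet.sample_ids)})"
            )
        counts = pd.DataFrame(
            mat.astype(np.int64), index=regions.index, columns=sheet.sample_ids
        )
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = None
        if not counts.index.equals(regions.index):
            raise ValidationError("count matrix region ids do not match BED ids")

    missing = [s for s in counts.columns if s not in sheet.data.index]
    if missing:
        raise ValidationError(f"samples in counts but not in sheet: {missing}")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative counts in matrix file")

    sheet = sheet.aligned_to(counts.columns)
    matrix = RegionCountMatrix(regions=regions, counts=counts)
    return matrix, sheet


# ----------------------------------------------------------------------- VCF

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path) -> None:
    """Minimal VCF v4.2, GT-only FORMAT, diploid coding (0/0, 0/1, 1/1, ./.)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(table.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for v, (vid, row) in enumerate(table.variants.iterrows()):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in table.calls[v])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _in_intervals(chrom: str, pos: int, intervals: dict) -> bool:
    for lo, hi in intervals.get(chrom, []):
        if lo <= pos <= hi:
            return True
    return False


def load_genotypes(vcf_path, par_intervals: dict | None = None) -> GenotypeTable:
    """Read a VCF with a GT field into 0/1/2/missing calls.

    Calls are coded by ALT allele count; "/" and "|" separators are treated
    identically; "./." is missing and excluded from MAF denominators. PAR
    flags come from ``par_intervals`` (chrom -> [(lo, hi)] 1-based inclusive).
    MAF is computed from nonmissing calls.
    """
    from cyvcf2 import VCF

    par_intervals = DEFAULT_PAR_INTERVALS if par_intervals is None else par_intervals
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    chroms, poss, ids, mafs, pars, rows = [], [], [], [], [], []
    for var in vcf:
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = np.asarray(var.gt_types)
        calls = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        nonmiss = calls != MISSING
        if not nonmiss.any():
            warnings.warn(f"variant {var.CHROM}:{var.POS} has no usable GT; skipped")
            continue
        af = calls[nonmiss].sum() / (2 * nonmiss.sum())
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        mafs.append(min(af, 1 - af))
        pars.append(_in_intervals(var.CHROM, var.POS, par_intervals))
        rows.append(calls.astype(np.int8))
    if not rows:
        raise ValidationError(f"no usable variant records in {vcf_path}")
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "maf": mafs, "is_par": pars}, index=ids
    )
    return GenotypeTable(variants=variants, calls=np.vstack(rows), samples=samples)


# ------------------------------------------------------------------- calcium

def write_calcium(session: CalciumSession, traces_path, events_path) -> None:
    """Traces as wide CSV (time_s column then one column per cell); events as
    (start_s, end_s) CSV."""
    t = np.arange(session.n_timepoints) / session.rate_hz
    df = pd.DataFrame({"time_s": t})
    for i, cid in enumerate(session.cell_ids):
        df[cid] = session.traces[i]
    df.to_csv(traces_path, index=False)
    pd.DataFrame(session.events, columns=["start_s", "end_s"]).to_csv(
        events_path, index=False
    )


def load_calcium(traces_path, events_path, rate_hz: float) -> CalciumSession:
    if rate_hz <= 0:
        raise ValidationError("rate_hz must be > 0")
    df = pd.read_csv(traces_path)
    if "time_s" not in df.columns:
        raise ValidationError("traces CSV must have a time_s column")
    cell_ids = [c for c in df.columns if c != "time_s"]
    traces = df[cell_ids].to_numpy().T
    if np.isnan(traces).any():
        bad = [cell_ids[i] for i in np.where(np.isnan(traces).any(axis=1))[0]]
        raise ValidationError(f"NaN in traces for cells: {bad}")
    ev = pd.read_csv(events_path)
    events = [(float(s), float(e)) for s, e in zip(ev["start_s"], ev["end_s"])]
    for s, e in events:
        if e <= s:
            raise ValidationError(f"event end {e} not after start {s}")
    if any(b[0] < a[1] for a, b in zip(events, events[1:])):
        raise ValidationError("overlapping events in events file")
    return CalciumSession(
        cell_ids=cell_ids, rate_hz=rate_hz, traces=traces, events=events
    )


# ----------------------------------------------------------------------- GMT

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def load_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    """GMT lines: name <tab> description <tab> gene1 <tab> ... If no universe
    is given, the union of all sets is used."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            if name in sets:
                raise ValidationError(f"duplicate gene-set name: {name}")
            sets[name] = set(g for g in genes if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(universe=universe, sets=sets)
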