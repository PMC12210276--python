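"""Synthetic-data generators with planted ground truth.

Every downstream stage (filtering, normalization, covariate screening,
differential testing, QC, peri-event classification, gene-set pruning) is
exercised on data produced here, so each simulator emits a ``TruthLabels``
record describing exactly what was planted.

The ATAC simulator emulates a paired case/control cohort in which every
subject contributes one library per cell type (e.g. sorted neuronal and
non-neuronal nuclear fractions), with negative-binomial counts, log-normal
region weights, sample-level nuisance covariates, and sex-linked marker
regions. The calcium simulator produces stationary AR(1) dF/F noise with
exponentially decaying event-locked transients added to planted cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    CalciumSession,
    GenotypeTable,
    GeneSetCollection,
    RegionCountMatrix,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "AtacSimSpec",
    "CalciumSimSpec",
    "TruthLabels",
    "simulate_atac_counts",
    "simulate_genotypes",
    "simulate_calcium_session",
    "simulate_gene_sets",
    "DEFAULT_PAR_INTERVALS",
]

#: Pseudoautosomal intervals (1-based, inclusive) used by the genotype
#: simulator and as the default for VCF loading; hg19-like coordinates.
DEFAULT_PAR_INTERVALS = {
    "chrX": [(60_001, 2_699_520), (154_931_044, 155_260_560)],
    "chrY": [(10_001, 2_649_520), (59_034_050, 59_363_566)],
}


@dataclass
class TruthLabels:
    """Planted ground truth emitted by the simulators."""

    differential_regions: set[str] = field(default_factory=set)
    differential_directions: dict[str, int] = field(default_factory=dict)
    informative_covariates: set[str] = field(default_factory=set)
    sex_by_sample: dict[str, str] = field(default_factory=dict)
    modulated_cells: dict[str, str] = field(default_factory=dict)


@dataclass
class AtacSimSpec:
    """Parameters of the paired case/control ATAC count simulation.

    ``covariates`` entries are (name, effect_lfc, frac_affected_regions);
    a covariate with effect_lfc > 0 and frac > 0 is planted as informative.
    ``sex_region_fractions`` = (female-marker, chrY, autosomal) region shares.
    """

    n_subjects: int = 20
    case_fraction: float = 0.5
    cell_types: int = 2
    n_regions: int = 1000
    frac_differential: float = 0.1
    effect_lfc: float = 1.0
    dispersion: float = 0.1
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    covariates: list[tuple[str, float, float]] = field(default_factory=list)
    sex_region_fractions: tuple[float, float, float] = (0.01, 0.01, 0.98)
    differential_cell_type: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not 0 <= self.case_fraction <= 1:
            raise ValidationError("case_fraction must be in [0, 1]")
        if self.cell_types < 1:
            raise ValidationError("cell_types must be >= 1")
        if self.n_regions < 1:
            raise ValidationError("n_regions must be >= 1")
        if not 0 <= self.frac_differential <= 1:
            raise ValidationError("frac_differential must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("library_size_range must be positive and ordered")
        for name, _lfc, frac in self.covariates:
            if not 0 <= frac <= 1:
                raise ValidationError(f"covariate {name!r} frac_affected outside [0,1]")
        fr = self.sex_region_fractions
        if any(f < 0 for f in fr) or sum(fr) > 1 + 1e-9:
            raise ValidationError("sex_region_fractions must be >= 0 and sum <= 1")
        if not 0 <= self.differential_cell_type < self.cell_types:
            raise ValidationError("differential_cell_type out of range")


_CELL_TYPE_NAMES = ["nonneuronal", "neuronal"]


def _cell_type_name(i: int) -> str:
    return _CELL_TYPE_NAMES[i] if i < len(_CELL_TYPE_NAMES) else f"celltype{i}"


def simulate_atac_counts(
    spec: AtacSimSpec,
) -> tuple[RegionCountMatrix, SampleSheet, TruthLabels]:
    """Draw a region x sample negative-binomial count matrix with planted
    case/control, covariate, and sex-linked effects.

    Counts[r, s] ~ NB(mean = L_s * w_r * 2^(design effects), dispersion) with
    Var = mu + dispersion * mu^2. Exactly floor(frac_differential * n_regions)
    regions carry the case/control effect in one cell type, half up / half
    down.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_sub, n_ct, n_reg = spec.n_subjects, spec.cell_types, spec.n_regions

    n_cases = int(round(spec.case_fraction * n_sub))
    diagnosis_by_subject = np.array(
        ["case"] * n_cases + ["control"] * (n_sub - n_cases)
    )
    rng.shuffle(diagnosis_by_subject)
    sex_by_subject = rng.choice(["male", "female"], size=n_sub)
    if n_sub >= 2 and len(set(sex_by_subject)) == 1:
        sex_by_subject[0] = "male" if sex_by_subject[0] == "female" else "female"

    subjects = [f"subj{i:03d}" for i in range(n_sub)]
    rows = []
    for i, subj in enumerate(subjects):
        for ct in range(n_ct):
            ct_name = _cell_type_name(ct)
            rows.append(
                {
                    "sample_id": f"{subj}_{ct_name}",
                    "subject_id": subj,
                    "cell_type": ct_name,
                    "diagnosis": diagnosis_by_subject[i],
                    "sex": sex_by_subject[i],
                }
            )
    sheet_df = pd.DataFrame(rows)
    n_samples = len(sheet_df)

    # region annotation: female-marker (chrX), chrY, then autosomes round-robin
    f_x, f_y, _ = spec.sex_region_fractions
    n_x = int(round(f_x * n_reg))
    n_y = int(round(f_y * n_reg))
    region_ids = [f"region{r:06d}" for r in range(n_reg)]
    chroms = (
        ["chrX"] * n_x
        + ["chrY"] * n_y
        + [f"chr{(r % 22) + 1}" for r in range(n_reg - n_x - n_y)]
    )
    starts = np.arange(n_reg) * 1000 + 10_000
    regions = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + 500}, index=region_ids
    )
    x_marker_ids = set(region_ids[:n_x])
    y_ids = set(region_ids[n_x : n_x + n_y])

    # log-normal region weights (nontrivial CPM filtering), normalized to sum 1
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=n_reg)
    weights /= weights.sum()

    lib_sizes = rng.integers(
        spec.library_size_range[0], spec.library_size_range[1] + 1, size=n_samples
    )

    # planted differential regions, restricted to autosomal regions
    autosomal = [r for r in region_ids if r not in x_marker_ids and r not in y_ids]
    n_diff = math.floor(spec.frac_differential * n_reg)
    if n_diff > len(autosomal):
        raise ValidationError("frac_differential too large for autosomal share")
    diff_ids = list(rng.choice(autosomal, size=n_diff, replace=False))
    directions = {
        rid: (1 if k < (n_diff + 1) // 2 else -1) for k, rid in enumerate(diff_ids)
    }

    log2fc = np.zeros((n_reg, n_samples))
    ridx = {rid: i for i, rid in enumerate(region_ids)}
    target_ct = _cell_type_name(spec.differential_cell_type)
    is_target = (
        (sheet_df["cell_type"] == target_ct) & (sheet_df["diagnosis"] == "case")
    ).to_numpy()
    for rid in diff_ids:
        log2fc[ridx[rid], is_target] += directions[rid] * spec.effect_lfc

    # sex-linked effects: female-marker regions depleted in males, chrY regions
    # depleted in females
    is_male = (sheet_df["sex"] == "male").to_numpy()
    for rid in x_marker_ids:
        log2fc[ridx[rid], is_male] += np.log2(0.1)
    for rid in y_ids:
        log2fc[ridx[rid], ~is_male] += np.log2(0.01)

    # sample-level nuisance covariates
    informative: set[str] = set()
    for name, cov_lfc, frac_affected in spec.covariates:
        values = rng.normal(size=n_samples)
        sheet_df[name] = values
        n_aff = int(round(frac_affected * n_reg))
        affected = rng.choice(n_reg, size=n_aff, replace=False)
        log2fc[affected, :] += cov_lfc * values[None, :]
        if cov_lfc != 0 and n_aff > 0:
            informative.add(name)

    mu = lib_sizes[None, :] * weights[:, None] * np.exp2(log2fc)
    r = 1.0 / spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(
        counts, index=region_ids, columns=sheet_df["sample_id"].tolist()
    )
    matrix = RegionCountMatrix(
        regions=regions,
        counts=counts_df,
        library_sizes=pd.Series(lib_sizes, index=counts_df.columns),
    )
    sheet = SampleSheet(sheet_df)
    truth = TruthLabels(
        differential_regions=set(diff_ids),
        differential_directions=directions,
        informative_covariates=informative,
        sex_by_sample={
            row["sample_id"]: row["sex"] for _, row in sheet_df.iterrows()
        },
    )
    return matrix, sheet, truth


def simulate_genotypes(
    n_subjects: int,
    n_variants: int,
    sex_by_subject: dict[str, str],
    duplicate_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
    missing_rate: float = 0.01,
    duplicate_flip_rate: float = 0.002,
) -> GenotypeTable:
    """Simulate autosomal, chrX and chrY genotype calls honoring sex.

    Males are hemizygous on non-PAR chrX/chrY (coded as homozygous diploid
    calls, so heterozygosity is 0 by construction) and carry chrY calls;
    females have missing non-PAR chrY calls. PAR variants behave autosomally
    in both sexes. Autosomal MAF is drawn in [0.05, 0.5] so downstream
    MAF >= 25% filtering retains a nonempty set. ``duplicate_pairs`` (a, b)
    copy a's calls into b with a small flip rate (concordance >= 99%).
    """
    if not sex_by_subject:
        raise ValidationError("sex_by_subject must be nonempty")
    if len(sex_by_subject) != n_subjects:
        raise ValidationError("sex_by_subject size must equal n_subjects")
    duplicate_pairs = duplicate_pairs or []
    samples = list(sex_by_subject)
    for a, b in duplicate_pairs:
        if a not in sex_by_subject or b not in sex_by_subject:
            raise ValidationError(f"duplicate pair ({a}, {b}) not in sex map")

    n_x = max(20, n_variants // 5)
    n_y = max(20, n_variants // 5)
    n_aut = n_variants - n_x - n_y
    if n_aut < 20:
        raise ValidationError(
            "n_variants too small: need >= 20 variants per chromosome class"
        )
    n_x_par = max(3, n_x // 10)  # a few PAR variants to exercise exclusion

    rng = np.random.default_rng(seed)
    recs = []
    par_x_lo, par_x_hi = DEFAULT_PAR_INTERVALS["chrX"][0]
    for i in range(n_aut):
        recs.append((f"chr{(i % 22) + 1}", 1_000_000 + i * 997, "autosome"))
    for i in range(n_x):
        if i < n_x_par:
            pos = par_x_lo + 1000 + i * 797  # inside PAR1
            recs.append(("chrX", pos, "par"))
        else:
            pos = par_x_hi + 5_000_000 + i * 997
            recs.append(("chrX", pos, "x_nonpar"))
    par_y_hi = DEFAULT_PAR_INTERVALS["chrY"][0][1]
    for i in range(n_y):
        recs.append(("chrY", par_y_hi + 5_000_000 + i * 997, "y_nonpar"))

    n_var = len(recs)
    maf = rng.uniform(0.05, 0.5, size=n_var)
    calls = np.full((n_var, len(samples)), -1, dtype=np.int8)
    is_male = np.array([sex_by_subject[s] == "male" for s in samples])

    for v, (_chrom, _pos, cls) in enumerate(recs):
        p = maf[v]
        if cls in ("autosome", "par"):
            g = rng.binomial(1, p, size=(len(samples), 2)).sum(axis=1)
            calls[v] = g
        elif cls == "x_nonpar":
            # females diploid HWE; males hemizygous -> 0 or 2
            g_f = rng.binomial(1, p, size=(len(samples), 2)).sum(axis=1)
            g_m = rng.binomial(1, p, size=len(samples)) * 2
            calls[v] = np.where(is_male, g_m, g_f)
        else:  # y_nonpar: males hemizygous, females missing
            g_m = rng.binomial(1, p, size=len(samples)) * 2
            calls[v] = np.where(is_male, g_m, -1)

    # duplicates: copy then flip a tiny fraction of nonmissing calls
    for a, b in duplicate_pairs:
        ia, ib = samples.index(a), samples.index(b)
        calls[:, ib] = calls[:, ia]
        flip = (rng.random(n_var) < duplicate_flip_rate) & (calls[:, ib] >= 0)
        calls[flip, ib] = (calls[flip, ib] + rng.integers(1, 3, flip.sum())) % 3

    # random missingness on top of structural missingness
    miss = rng.random(calls.shape) < missing_rate
    calls[miss] = -1

    variants = pd.DataFrame(
        {
            "chrom": [c for c, _, _ in recs],
            "pos": [p for _, p, _ in recs],
            "maf": maf,
            "is_par": [cls == "par" for _, _, cls in recs],
        },
        index=[f"var{v:06d}" for v in range(n_var)],
    )
    return GenotypeTable(variants=variants, calls=calls, samples=samples)


@dataclass
class CalciumSimSpec:
    """Parameters of the peri-event calcium trace simulation.

    Non-modulated cells are stationary AR(1) Gaussian noise with unit marginal
    SD; modulated cells add transients of ``transient_amplitude`` dF/F decaying
    with time constant ``transient_decay_s`` at each event entry. 10 Hz is the
    processed sampling rate of downsampled microendoscopy recordings.
    """

    n_cells: int = 50
    duration_s: float = 600.0
    rate_hz: float = 10.0
    ar_coefficient: float = 0.8
    n_events: int = 10
    frac_up: float = 0.0
    frac_down: float = 0.0
    transient_amplitude: float = 2.0
    transient_decay_s: float = 1.5
    min_spacing_s: float = 6.0
    event_duration_s: float = 2.0
    edge_margin_s: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be > 0")
        if not -1 < self.ar_coefficient < 1:
            raise ValidationError("ar_coefficient must be in (-1, 1)")
        if self.frac_up < 0 or self.frac_down < 0 or self.frac_up + self.frac_down > 1:
            raise ValidationError("frac_up/frac_down must be >= 0 and sum <= 1")
        if self.duration_s * self.rate_hz < 10 * max(self.n_events, 1):
            raise ValidationError("recording too short for requested n_events")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")


def _draw_spaced_times(
    rng: np.random.Generator, n: int, t_min: float, t_max: float, spacing: float
) -> np.ndarray:
    """n sorted times in [t_min, t_max] with pairwise gaps > spacing."""
    slack = (t_max - t_min) - (n - 1) * spacing
    if slack <= 0:
        raise ValidationError("cannot place events with requested spacing")
    u = np.sort(rng.uniform(0, slack, size=n))
    return t_min + u + np.arange(n) * spacing


def simulate_calcium_session(
    spec: CalciumSimSpec,
) -> tuple[CalciumSession, TruthLabels]:
    """AR(1) dF/F traces with event-locked transients in planted cells."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.duration_s * spec.rate_hz))
    phi = spec.ar_coefficient

    # stationary AR(1) with unit marginal variance
    innov_sd = math.sqrt(1 - phi**2)
    eps = rng.normal(scale=innov_sd, size=(spec.n_cells, n_t))
    traces = np.empty_like(eps)
    traces[:, 0] = rng.normal(scale=1.0, size=spec.n_cells)
    for t in range(1, n_t):
        traces[:, t] = phi * traces[:, t - 1] + eps[:, t]

    entry = _draw_spaced_times(
        rng,
        spec.n_events,
        spec.edge_margin_s,
        spec.duration_s - spec.edge_margin_s - spec.event_duration_s,
        spec.min_spacing_s,
    )
    events = [(float(s), float(s + spec.event_duration_s)) for s in entry]

    n_up = int(round(spec.frac_up * spec.n_cells))
    n_down = int(round(spec.frac_down * spec.n_cells))
    labels = ["up"] * n_up + ["down"] * n_down + ["none"] * (
        spec.n_cells - n_up - n_down
    )
    rng.shuffle(labels)
    if spec.transient_amplitude == 0:
        labels = ["none"] * spec.n_cells

    tgrid = np.arange(n_t) / spec.rate_hz
    kernel = np.zeros(n_t)
    for t0 in entry:
        dt = tgrid - t0
        mask = (dt >= 0) & (dt <= 5 * spec.transient_decay_s)
        kernel[mask] += np.exp(-dt[mask] / spec.transient_decay_s)
    for i, lab in enumerate(labels):
        if lab == "up":
            traces[i] += spec.transient_amplitude * kernel
        elif lab == "down":
            traces[i] -= spec.transient_amplitude * kernel

    cell_ids = [f"cell{i:04d}" for i in range(spec.n_cells)]
    session = CalciumSession(
        cell_ids=cell_ids, rate_hz=spec.rate_hz, traces=traces, events=events
    )
    truth = TruthLabels(modulated_cells=dict(zip(cell_ids, labels)))
    return session, truth


def simulate_gene_sets(
    n_sets: int,
    universe_size: int,
    overlap_profile: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    set_sizes: list[int] | None = None,
) -> GeneSetCollection:
    """Generate overlapping gene sets hitting pairwise Jaccard targets.

    ``overlap_profile`` entries are (i, j, target_jaccard) with i < j indexing
    sets. Each constrained pair shares round(J * (|A| + |B|) / (1 + J)) genes;
    realized Jaccard must land within +/-0.05 of the target or the profile is
    rejected as infeasible.
    """
    overlap_profile = overlap_profile or []
    rng = np.random.default_rng(seed)
    if set_sizes is None:
        set_sizes = [20] * n_sets
    if len(set_sizes) != n_sets:
        raise ValidationError("set_sizes length must equal n_sets")
    for i, j, t in overlap_profile:
        if not (0 <= i < j < n_sets):
            raise ValidationError(f"bad profile pair ({i}, {j})")
        if not 0 <= t <= 1:
            raise ValidationError("Jaccard targets must be in [0, 1]")
    if sum(set_sizes) > universe_size:
        raise ValidationError("universe too small for requested set sizes")

    universe = [f"gene{g:05d}" for g in range(universe_size)]
    pool = list(universe)
    rng.shuffle(pool)
    sets: list[set[str]] = []
    cursor = 0
    for k in range(n_sets):
        size = set_sizes[k]
        genes: set[str] = set()
        for i, j, t in overlap_profile:
            if j != k:
                continue
            sa, sb = set_sizes[i], set_sizes[j]
            inter = int(round(t * (sa + sb) / (1 + t)))
            if inter > min(sa, sb):
                raise ValidationError(
                    f"infeasible Jaccard target {t} for sizes ({sa}, {sb})"
                )
            donors = sorted(sets[i] - genes)
            genes |= set(donors[:inter])
        if len(genes) > size:
            raise ValidationError("conflicting overlap constraints (set overfull)")
        need = size - len(genes)
        genes |= set(pool[cursor : cursor + need])
        cursor += need
        sets.append(genes)

    for i, j, t in overlap_profile:
        inter = len(sets[i] & sets[j])
        union = len(sets[i] | sets[j])
        realized = inter / union if union else 0.0
        if abs(realized - t) > 0.05:
            raise ValidationError(
                f"infeasible profile: pair ({i}, {j}) realized J={realized:.3f}, "
                f"target {t:.3f}"
            )
    return GeneSetCollection(
        universe=set(universe),
        sets={f"set{k:03d}": sets[k] for k in range(n_sets)},
    )
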