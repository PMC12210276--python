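"""Peri-event calcium-imaging statistics.

Social-zone occupancy intervals separated by less than 2 s are merged into
single bouts; each bout's entry time is an event. A cell's peri-event
statistic is the mean over events of (mean dF/F in a post-entry window minus
mean dF/F in a pre-entry window). The null distribution is built by circularly
permuting the event times relative to the trace (one common uniform offset per
shuffle, 1000 shuffles), and cells are classified two-tailed at alpha = 0.05:
up-modulated if the bootstrap probability is below alpha/2, down-modulated if
above 1 - alpha/2, non-modulated otherwise.

Also here: full-session z-scoring of traces, state-restricted mean activity,
pairwise in-zone synchrony (Pearson), and the paired pre/post-session change
in rescaled in-zone activity per registered neuron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CalciumSession, ValidationError

__all__ = [
    "merge_bouts",
    "rescale_traces",
    "perievent_statistic",
    "circular_null",
    "classify_modulation",
    "classify_session",
    "state_mean_activity",
    "pairwise_synchrony",
    "paired_session_change",
    "ModulationResult",
]

#: peri-event windows in seconds relative to the event (half-open on the right)
POST_WINDOW_S = (1.0, 3.0)
PRE_WINDOW_S = (-3.0, -1.0)


def _round_half_up(x: np.ndarray | float) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def merge_bouts(
    intervals: list[tuple[float, float]], min_gap_s: float = 2.0
) -> list[tuple[float, float]]:
    """Merge consecutive intervals whose gap is below ``min_gap_s``
    (transitively); input must be sorted by start time."""
    if any(b[0] < a[0] for a, b in zip(intervals, intervals[1:])):
        raise ValidationError("intervals must be sorted by start time")
    for s, e in intervals:
        if e <= s:
            raise ValidationError(f"interval end {e} not after start {s}")
    merged: list[list[float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < min_gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def rescale_traces(session: CalciumSession) -> CalciumSession:
    """Per-cell standardization to mean 0, SD 1 over the full session
    (population SD), removing baseline and scale differences between cells."""
    sd = session.traces.std(axis=1)
    if (sd == 0).any():
        bad = [session.cell_ids[i] for i in np.where(sd == 0)[0]]
        raise ValidationError(f"constant trace for cells: {bad}")
    traces = (session.traces - session.traces.mean(axis=1, keepdims=True)) / sd[:, None]
    return CalciumSession(
        cell_ids=list(session.cell_ids),
        rate_hz=session.rate_hz,
        traces=traces,
        events=list(session.events),
        session_id=session.session_id,
    )


def _doubled_cumsum(trace: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.concatenate([trace, trace]))])


def _window_mean(
    trace: np.ndarray, lo_idx: np.ndarray, hi_idx: np.ndarray, circular: bool,
    csum2: np.ndarray | None = None,
) -> np.ndarray:
    """Mean of trace over [lo, hi) sample windows; circular indexing wraps
    windows modulo the trace length. ``csum2`` lets callers reuse the doubled
    cumulative sum across many window sets."""
    n = trace.shape[-1]
    if circular:
        csum = _doubled_cumsum(trace) if csum2 is None else csum2
        lo = np.mod(lo_idx, n)
        hi = lo + (hi_idx - lo_idx)
        return (csum[hi] - csum[lo]) / (hi_idx - lo_idx)
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    return (csum[hi_idx] - csum[lo_idx]) / (hi_idx - lo_idx)


def perievent_statistic(
    trace: np.ndarray,
    event_times: np.ndarray,
    rate_hz: float,
    post_window_s: tuple[float, float] = POST_WINDOW_S,
    pre_window_s: tuple[float, float] = PRE_WINDOW_S,
    circular: bool = False,
) -> float:
    """Mean over events of (post-window mean - pre-window mean) dF/F.

    Windows are discretized as round(t * rate) with half-up rounding, half-open
    on the right. With ``circular=False`` events whose windows leave the
    recording are dropped with a warning (all dropped -> error); with
    ``circular=True`` windows wrap around the trace end, which is the
    convention used when building circular-permutation nulls.
    """
    trace = np.asarray(trace, dtype=float)
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    if event_times.size == 0:
        raise ValidationError("no event times supplied")
    n = trace.shape[0]
    pre_lo = _round_half_up((event_times + pre_window_s[0]) * rate_hz)
    pre_hi = _round_half_up((event_times + pre_window_s[1]) * rate_hz)
    post_lo = _round_half_up((event_times + post_window_s[0]) * rate_hz)
    post_hi = _round_half_up((event_times + post_window_s[1]) * rate_hz)
    if (pre_hi <= pre_lo).any() or (post_hi <= post_lo).any():
        raise ValidationError("degenerate (empty) peri-event window")

    if not circular:
        ok = (pre_lo >= 0) & (post_hi <= n)
        if not ok.all():
            warnings.warn(
                f"dropped {(~ok).sum()} event(s) with windows outside the recording"
            )
        if not ok.any():
            raise ValidationError("all events have windows outside the recording")
        pre_lo, pre_hi = pre_lo[ok], pre_hi[ok]
        post_lo, post_hi = post_lo[ok], post_hi[ok]

    post = _window_mean(trace, post_lo, post_hi, circular)
    pre = _window_mean(trace, pre_lo, pre_hi, circular)
    return float(np.mean(post - pre))


def circular_null(
    trace: np.ndarray,
    event_times: np.ndarray,
    rate_hz: float,
    n_shuffles: int = 1000,
    seed: int = 0,
    post_window_s: tuple[float, float] = POST_WINDOW_S,
    pre_window_s: tuple[float, float] = PRE_WINDOW_S,
) -> np.ndarray:
    """Null peri-event statistics from circular permutations of the event
    times: per shuffle one uniform offset in [0, T) is added to every event
    time modulo the recording length (inter-event structure preserved; the
    trace itself is untouched)."""
    trace = np.asarray(trace, dtype=float)
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    n = trace.shape[0]
    duration = n / rate_hz
    span = max(abs(pre_window_s[0]), abs(post_window_s[1]))
    if duration <= 2 * span:
        raise ValidationError("trace shorter than the peri-event window span")
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(0, duration, size=n_shuffles)
    shifted = np.mod(event_times[None, :] + offsets[:, None], duration)
    # vectorized over shuffles: same discretization as perievent_statistic
    pre_lo = _round_half_up((shifted + pre_window_s[0]) * rate_hz)
    pre_hi = _round_half_up((shifted + pre_window_s[1]) * rate_hz)
    post_lo = _round_half_up((shifted + post_window_s[0]) * rate_hz)
    post_hi = _round_half_up((shifted + post_window_s[1]) * rate_hz)
    csum2 = _doubled_cumsum(trace)
    post = _window_mean(trace, post_lo, post_hi, True, csum2)
    pre = _window_mean(trace, pre_lo, pre_hi, True, csum2)
    return np.mean(post - pre, axis=1)


@dataclass
class ModulationResult:
    observed: float
    bootstrap_probability: float
    label: str  # up | down | non
    n_shuffles: int
    alpha: float


def classify_modulation(
    observed: float, null: np.ndarray, alpha: float = 0.05
) -> ModulationResult:
    """Two-tailed classification against the circular null.

    bootstrap probability = (1 + #{null > observed} + 0.5 #{null == observed})
    / (n_shuffles + 1): the add-one convention keeps the probability strictly
    inside (0, 1), ties split evenly between the tails (a degenerate all-tie
    null yields ~0.5, i.e. non-modulated), and for continuous statistics the
    value coincides with the plain #{null >= observed} rule. Up if below
    alpha/2, down if above 1 - alpha/2, non otherwise; the label is invariant
    to adding a constant to both observed and null statistics.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValidationError("empty null distribution")
    n = null.size
    prob = (
        1 + int((null > observed).sum()) + 0.5 * int((null == observed).sum())
    ) / (n + 1)
    if prob < alpha / 2:
        label = "up"
    elif prob > 1 - alpha / 2:
        label = "down"
    else:
        label = "non"
    return ModulationResult(
        observed=float(observed),
        bootstrap_probability=prob,
        label=label,
        n_shuffles=n,
        alpha=alpha,
    )


def classify_session(
    session: CalciumSession,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    merge_gap_s: float = 2.0,
    post_window_s: tuple[float, float] = POST_WINDOW_S,
    pre_window_s: tuple[float, float] = PRE_WINDOW_S,
) -> pd.DataFrame:
    """Classify every cell of a session; returns a per-cell table with the
    observed statistic, bootstrap probability and up/down/non label. Each cell
    gets its own seeded shuffle stream derived from ``seed``."""
    bouts = merge_bouts(list(session.events), min_gap_s=merge_gap_s)
    entries = np.array([s for s, _ in bouts])
    if entries.size == 0:
        raise ValidationError("session has no events")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(session.n_cells)]
    rows = []
    for i, cid in enumerate(session.cell_ids):
        obs = perievent_statistic(
            session.traces[i],
            entries,
            session.rate_hz,
            post_window_s=post_window_s,
            pre_window_s=pre_window_s,
            circular=True,
        )
        null = circular_null(
            session.traces[i],
            entries,
            session.rate_hz,
            n_shuffles=n_shuffles,
            seed=child_seeds[i],
            post_window_s=post_window_s,
            pre_window_s=pre_window_s,
        )
        res = classify_modulation(obs, null, alpha=alpha)
        rows.append(
            {
                "cell_id": cid,
                "statistic": res.observed,
                "bootstrap_probability": res.bootstrap_probability,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def _interval_mask(session: CalciumSession, intervals) -> np.ndarray:
    mask = np.zeros(session.n_timepoints, dtype=bool)
    for s, e in intervals:
        lo = max(_round_half_up(s * session.rate_hz), 0)
        hi = min(_round_half_up(e * session.rate_hz), session.n_timepoints)
        if hi > session.n_timepoints or s < 0:
            raise ValidationError(f"interval ({s}, {e}) outside the session")
        mask[lo:hi] = True
    return mask


def state_mean_activity(
    session: CalciumSession, intervals: list[tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Per-cell mean dF/F inside the union of occupancy intervals and over its
    complement (columns in_zone / out_zone)."""
    intervals = session.events if intervals is None else intervals
    mask = _interval_mask(session, intervals)
    if not mask.any():
        raise ValidationError("empty interval union")
    inside = session.traces[:, mask].mean(axis=1)
    outside = (
        session.traces[:, ~mask].mean(axis=1)
        if (~mask).any()
        else np.full(session.n_cells, np.nan)
    )
    return pd.DataFrame(
        {"in_zone": inside, "out_zone": outside}, index=session.cell_ids
    )


def pairwise_synchrony(
    session: CalciumSession, intervals: list[tuple[float, float]] | None = None
) -> tuple[pd.DataFrame, float]:
    """Cell x cell Pearson correlation restricted to in-zone samples, plus the
    mean off-diagonal summary. Zero-variance cells get NaN rows/columns and
    are excluded from the summary."""
    intervals = session.events if intervals is None else intervals
    mask = _interval_mask(session, intervals)
    if mask.sum() < 2:
        raise ValidationError("need >= 2 in-zone samples")
    sub = session.traces[:, mask]
    sd = sub.std(axis=1)
    ok = sd > 0
    corr = np.full((session.n_cells, session.n_cells), np.nan)
    if ok.sum() >= 1:
        c = np.corrcoef(sub[ok])
        c = np.atleast_2d(c)
        corr[np.ix_(ok, ok)] = c
    mat = pd.DataFrame(corr, index=session.cell_ids, columns=session.cell_ids)
    off = corr[np.ix_(ok, ok)]
    if ok.sum() >= 2:
        iu = np.triu_indices(ok.sum(), k=1)
        summary = float(off[iu].mean())
    else:
        summary = float("nan")
    return mat, summary


def paired_session_change(
    pre_session: CalciumSession,
    post_session: CalciumSession,
    cell_registry: dict[str, str],
) -> pd.DataFrame:
    """Per-neuron difference (post - pre) of rescaled mean in-zone activity.

    Each session is z-scored independently, mean activity is taken over that
    session's occupancy intervals, and the difference is reported per
    registered pre->post cell pair. Unregistered cells are excluded and
    listed in the ``excluded`` attribute of the returned frame.
    """
    missing = [
        (a, b)
        for a, b in cell_registry.items()
        if a not in pre_session.cell_ids or b not in post_session.cell_ids
    ]
    if missing:
        raise ValidationError(f"registry pairs not found in sessions: {missing[:5]}")
    pre_r = rescale_traces(pre_session)
    post_r = rescale_traces(post_session)
    pre_mean = state_mean_activity(pre_r)["in_zone"]
    post_mean = state_mean_activity(post_r)["in_zone"]
    rows = []
    for pre_id, post_id in cell_registry.items():
        rows.append(
            {
                "pre_cell": pre_id,
                "post_cell": post_id,
                "pre_mean": float(pre_mean[pre_id]),
                "post_mean": float(post_mean[post_id]),
                "change": float(post_mean[post_id] - pre_mean[pre_id]),
            }
        )
    out = pd.DataFrame(rows).set_index("pre_cell")
    excluded = [c for c in pre_session.cell_ids if c not in cell_registry]
    out.attrs["excluded"] = excluded
    return out
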