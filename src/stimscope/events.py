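"""Downstream statistics on extracted calcium activity.

Covers the paper-style analysis chain for stimulation/behavior experiments:

* calcium event detection on temporal traces (median/MAD threshold with a
  refractory period);
* the population instantaneous event rate (events summed over cells per
  frame) and its binning by locomotor velocity, with rest defined as
  velocity < 0.5 cm/s and rates normalized to the animal's mean rate at rest
  during unstimulated periods;
* activated-cell counting per stimulation epoch (epoch mean exceeding the
  pre-epoch baseline by k MADs);
* nonparametric group comparison: tie-corrected Kruskal-Wallis and Dunn's
  post-hoc z tests with family-wise adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .sim import BehaviorTrace, StimSchedule

__all__ = [
    "EventRaster",
    "VelocityBinnedRates",
    "StatResult",
    "DEFAULT_VELOCITY_EDGES",
    "REST_VELOCITY_CMPS",
    "detect_events",
    "event_rate_timeseries",
    "bin_rates_by_velocity",
    "rest_mean_rate",
    "normalize_to_rest",
    "fit_velocity_gain",
    "count_activated_cells",
    "kruskal_wallis",
    "dunn_posthoc",
    "suppression_ratio",
]

REST_VELOCITY_CMPS = 0.5

# finer bins at low velocity, coarser at high; widths between 0.5 and 2.5 cm/s
DEFAULT_VELOCITY_EDGES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.5, 5.0, 7.5, 10.0)


@dataclass
class EventRaster:
    events: np.ndarray       # (n_cells, T) nonnegative integers
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        if self.events.ndim != 2:
            raise ValueError("events must be (n_cells, T)")
        if np.any(self.events < 0):
            raise ValueError("event counts must be nonnegative")


@dataclass
class VelocityBinnedRates:
    """Mean (optionally rest-normalized) event rate per velocity bin."""

    bin_edges_cmps: np.ndarray   # internal edges; rest bin is [0, edges[0])
    rate: np.ndarray             # per bin, len(edges) + 1 with overflow bin
    n_frames: np.ndarray
    normalized: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        """Representative velocity per bin (rest bin at half the rest edge;
        overflow bin at its lower edge plus the last regular width)."""
        e = np.concatenate([[0.0], self.bin_edges_cmps])
        centers = 0.5 * (e[:-1] + e[1:])
        last_width = e[-1] - e[-2] if len(e) > 1 else 1.0
        return np.concatenate([centers, [e[-1] + last_width / 2.0]])

    def to_frame(self) -> pd.DataFrame:
        e = np.concatenate([[0.0], self.bin_edges_cmps, [np.inf]])
        return pd.DataFrame({
            "v_low_cmps": e[:-1],
            "v_high_cmps": e[1:],
            "rate": self.rate,
            "n_frames": self.n_frames,
        })


@dataclass
class StatResult:
    statistic: float
    p_value: float
    df: int
    pairwise: list[dict] = field(default_factory=list)


# --------------------------------------------------------------------------
# event detection

def detect_events(traces: np.ndarray, frame_rate_hz: float,
                  threshold_mads: float = 3.0,
                  refractory_frames: int | None = None) -> EventRaster:
    """Detect calcium events as thresholded local maxima of each trace.

    Per cell the baseline is the median and the scale the MAD (with an
    epsilon floor so constant traces yield zero events); an event is marked
    at every local maximum exceeding ``baseline + threshold_mads * MAD``,
    with at most one event per ``refractory_frames`` (default: half a
    second).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be (n_cells, T)")
    if not np.isfinite(traces).all():
        raise ValueError("traces contain non-finite values")
    n, T = traces.shape
    if refractory_frames is None:
        refractory_frames = int(np.ceil(0.5 * frame_rate_hz))
    events = np.zeros((n, T), dtype=np.int64)
    for i in range(n):
        x = traces[i]
        if np.ptp(x) == 0:
            continue
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        # epsilon floor: a sparse noise-free trace has (near-)zero MAD, so
        # floor the scale at a small fraction of the trace's dynamic range
        scale = max(mad, 1e-6 * np.ptp(x))
        height = med + threshold_mads * scale
        peaks, _ = signal.find_peaks(x, height=height,
                                     distance=max(refractory_frames, 1))
        events[i, peaks] = 1
    return EventRaster(events=events, frame_rate_hz=frame_rate_hz)


def event_rate_timeseries(raster: EventRaster, per_second: bool = False) -> np.ndarray:
    """Population instantaneous event rate: total events per frame."""
    rate = raster.events.sum(axis=0).astype(float)
    if per_second:
        rate = rate * raster.frame_rate_hz
    return rate


# --------------------------------------------------------------------------
# velocity binning and normalization

def bin_rates_by_velocity(
    rate: np.ndarray,
    behavior: BehaviorTrace,
    edges: np.ndarray | tuple = DEFAULT_VELOCITY_EDGES,
    frame_mask: np.ndarray | None = None,
) -> VelocityBinnedRates:
    """Bin the per-frame rate by locomotor velocity.

    Bins are half-open: rest is ``[0, edges[0])`` (so exactly 0.5 cm/s counts
    as ambulation), then ``[edges[k], edges[k+1])``, with frames above the
    last edge pooled into an overflow bin.  ``frame_mask`` restricts the
    analysis to a subset of frames (e.g. unstimulated periods).
    """
    rate = np.asarray(rate, dtype=float)
    v = behavior.velocity_cmps
    if rate.shape[0] != v.shape[0]:
        raise ValueError("rate and behavior must have equal length")
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or np.any(np.diff(edges) <= 0) or edges[0] <= 0:
        raise ValueError("edges must be strictly ascending and positive")
    if frame_mask is not None:
        rate = rate[frame_mask]
        v = v[frame_mask]
    idx = np.searchsorted(edges, v, side="right")   # 0 = rest bin
    n_bins = len(edges) + 1
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=rate, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return VelocityBinnedRates(bin_edges_cmps=edges, rate=means,
                               n_frames=counts.astype(int))


def rest_mean_rate(rate: np.ndarray, behavior: BehaviorTrace,
                   frame_mask: np.ndarray | None = None,
                   rest_velocity: float = REST_VELOCITY_CMPS) -> float:
    """Mean event rate over rest frames (velocity < 0.5 cm/s)."""
    rate = np.asarray(rate, dtype=float)
    v = behavior.velocity_cmps
    mask = v < rest_velocity
    if frame_mask is not None:
        mask &= frame_mask
    if not mask.any():
        raise ValueError("no rest frames available for normalization")
    return float(rate[mask].mean())


def normalize_to_rest(binned: VelocityBinnedRates,
                      rest_mean: float) -> VelocityBinnedRates:
    """Divide every bin by the animal's mean rate at (unstimulated) rest."""
    if rest_mean <= 0:
        raise ValueError("rest mean rate must be positive "
                         "(no rest frames or silent recording)")
    return VelocityBinnedRates(
        bin_edges_cmps=binned.bin_edges_cmps,
        rate=binned.rate / rest_mean,
        n_frames=binned.n_frames,
        normalized=True,
    )


def fit_velocity_gain(binned: VelocityBinnedRates) -> float:
    """Recover the velocity gain beta of the rate law
    ``lambda(v) = lambda0 * (1 + beta * v)`` from a binned curve.

    A normalized curve is ``a * (1 + beta * v)`` for some positive ``a``
    (normalization divides by the rest-frame mean, which sits at a small but
    nonzero velocity), so beta equals slope / intercept of a weighted linear
    fit against the bin centers.
    """
    ok = (binned.n_frames > 0) & np.isfinite(binned.rate)
    x = binned.bin_centers[ok]
    y = binned.rate[ok]
    wgt = binned.n_frames[ok].astype(float)
    if ok.sum() < 2:
        raise ValueError("need at least two populated bins")
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(wgt))
    if intercept <= 0:
        raise ValueError("non-positive intercept; rate law fit failed")
    return float(slope / intercept)


# --------------------------------------------------------------------------
# activated cells

def count_activated_cells(
    traces: np.ndarray,
    schedule: StimSchedule,
    k_mads: float = 3.0,
) -> pd.DataFrame:
    """Count cells activated by each stimulation epoch.

    A cell is activated when its mean trace during the epoch exceeds the
    mean of the immediately preceding window of equal length by
    ``k_mads`` times the MAD of that baseline window.  The MAD is floored at
    a small fraction of the population trace range so that numerically-zero
    baselines (a quiescent noise-free cell) do not flag numerical ripple as
    activation.  Epochs without a full baseline window are skipped with a
    warning.
    Returns a frame with columns epoch, frequency_hz, n_activated.
    """
    traces = np.asarray(traces, dtype=float)
    mad_floor = 1e-6 * (np.ptp(traces) if traces.size else 0.0)
    rows = []
    for k, ep in enumerate(schedule.epochs):
        length = ep.stop - ep.start
        if ep.start - length < 0:
            warnings.warn(f"epoch {k} lacks a pre-epoch baseline window; skipped")
            continue
        base = traces[:, ep.start - length:ep.start]
        stim = traces[:, ep.start:ep.stop]
        base_mean = base.mean(axis=1)
        base_mad = np.median(np.abs(base - np.median(base, axis=1, keepdims=True)),
                             axis=1)
        base_mad = np.maximum(base_mad, mad_floor)
        activated = stim.mean(axis=1) > base_mean + k_mads * base_mad
        rows.append({"epoch": k, "frequency_hz": ep.frequency_hz,
                     "n_activated": int(activated.sum())})
    return pd.DataFrame(rows, columns=["epoch", "frequency_hz", "n_activated"])


# --------------------------------------------------------------------------
# nonparametric statistics

def _ranks_and_ties(groups: list[np.ndarray]):
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    split = np.cumsum([len(g) for g in groups])[:-1]
    return np.split(ranks, split), pooled.size, tie_term


def kruskal_wallis(groups) -> StatResult:
    """Tie-corrected Kruskal-Wallis one-way analysis of variance on ranks.

    ``H = [12 / (N(N+1)) * sum n_i (Rbar_i - Rbar)^2] / (1 - sum(t^3 - t)/(N^3 - N))``
    with p from the chi-square distribution with k - 1 df.  Degenerate input
    (all values identical) yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    group_ranks, N, tie_term = _ranks_and_ties(groups)
    mean_rank = (N + 1) / 2.0
    H = 12.0 / (N * (N + 1)) * sum(
        len(r) * (r.mean() - mean_rank) ** 2 for r in group_ranks
    )
    correction = 1.0 - tie_term / (N**3 - N)
    if correction <= 0:
        return StatResult(statistic=0.0, p_value=1.0, df=len(groups) - 1)
    H /= correction
    df = len(groups) - 1
    return StatResult(statistic=float(H),
                      p_value=float(stats.chi2.sf(H, df)), df=df)


def _holm(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for k, o in enumerate(order):
        running = max(running, (m - k) * pvals[o])
        adj[o] = min(1.0, running)
    return adj


def dunn_posthoc(groups, adjust: str = "holm",
                 labels=None) -> list[dict]:
    """Dunn's post-hoc pairwise comparisons after Kruskal-Wallis.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with ``T = sum(t^3 - t)`` the tie term over the pooled sample.  Raw
    two-sided normal p-values are adjusted family-wise over all pairs by
    Holm (default) or Bonferroni.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if labels is None:
        labels = list(range(len(groups)))
    group_ranks, N, tie_term = _ranks_and_ties(groups)
    var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    results = []
    raw = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = 0.0 if se == 0 else (group_ranks[i].mean()
                                     - group_ranks[j].mean()) / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            results.append({"group_a": labels[i], "group_b": labels[j],
                            "z": float(z), "p_raw": p})
            raw.append(p)
    raw = np.asarray(raw)
    if adjust == "holm":
        adj = _holm(raw)
    elif adjust == "bonferroni":
        adj = np.minimum(raw * len(raw), 1.0)
    elif adjust in (None, "none"):
        adj = raw
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for r, a in zip(results, adj):
        r["p_adjusted"] = float(a)
    return results


# --------------------------------------------------------------------------
# stimulation vs behavior

def suppression_ratio(
    rate: np.ndarray,
    behavior: BehaviorTrace,
    schedule: StimSchedule,
    edges=DEFAULT_VELOCITY_EDGES,
    min_frames_per_bin: int = 20,
) -> float:
    """Ratio of stimulated to unstimulated rest-normalized ambulation rates.

    Both conditions are normalized to the same reference (mean rate at rest
    in unstimulated frames), binned by velocity, and compared bin-by-bin so
    that differences in the velocity distribution between conditions do not
    bias the ratio; the result is the frame-weighted mean of per-bin ratios
    over ambulation bins populated in both conditions.
    """
    T = len(behavior)
    stim_mask = schedule.indicator(T).astype(bool)
    rest_ref = rest_mean_rate(rate, behavior, frame_mask=~stim_mask)
    binned_off = normalize_to_rest(
        bin_rates_by_velocity(rate, behavior, edges, frame_mask=~stim_mask),
        rest_ref)
    binned_on = normalize_to_rest(
        bin_rates_by_velocity(rate, behavior, edges, frame_mask=stim_mask),
        rest_ref)
    ok = ((binned_off.n_frames >= min_frames_per_bin)
          & (binned_on.n_frames >= min_frames_per_bin))
    ok[0] = False    # ambulation bins only
    ok &= np.isfinite(binned_off.rate) & (binned_off.rate > 0)
    if not ok.any():
        raise ValueError("no velocity bin is populated in both conditions")
    ratios = binned_on.rate[ok] / binned_off.rate[ok]
    wgt = np.minimum(binned_on.n_frames[ok], binned_off.n_frames[ok]).astype(float)
    return float(np.average(ratios, weights=wgt))
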