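"""Quantitative benchmark of contamination rejection by extraction method.

One-photon recordings made during electrical stimulation carry a
stimulation-locked, low-spatial-frequency background from out-of-focus
activation.  This module injects such contamination into a synthetic movie
with known ground truth and scores how much of it leaks into the traces each
extraction method reports, with and without a spatial bandpass prefilter.

Metrics per method:

* median absolute Pearson correlation between extracted traces and the
  contamination's temporal envelope, evaluated on stimulation-containing
  frames (lower = better rejection);
* median pairwise inter-trace correlation (contamination leaking everywhere
  makes all traces look alike);
* precision/recall of footprint recovery against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .extract import (
    ExtractionResult,
    PcaIcaExtractor,
    RingCnmf,
    RoiExtractor,
    match_components,
)
from .preprocess import SpatialBandpass
from .sim import GroundTruth, SimConfig, simulate_session

__all__ = [
    "MethodScore",
    "BenchReport",
    "inject_contamination",
    "score_rejection",
    "run_method_comparison",
]


@dataclass
class MethodScore:
    method: str
    bandpass: bool
    n_found: int
    median_abs_contam_corr: float
    median_pairwise_corr: float | None
    precision: float
    recall: float
    constant_traces: int = 0
    error: str | None = None


@dataclass
class BenchReport:
    scores: list[MethodScore] = field(default_factory=list)
    contamination_amplitude: float = 0.0
    seed: int = 0

    def get(self, method: str, bandpass: bool) -> MethodScore:
        for s in self.scores:
            if s.method == method and s.bandpass == bandpass:
                return s
        raise KeyError((method, bandpass))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.scores])

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"contamination_amplitude": self.contamination_amplitude,
             "seed": self.seed,
             "scores": [asdict(s) for s in self.scores]},
            indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def inject_contamination(movie: np.ndarray, spatial: np.ndarray,
                         temporal: np.ndarray,
                         amplitude: float = 1.0) -> np.ndarray:
    """Add ``amplitude * spatial (x) temporal`` to a movie (rank-1, additive)."""
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be (T, H, W)")
    if spatial.shape != movie.shape[1:]:
        raise ValueError("spatial field shape mismatch")
    if temporal.shape[0] != movie.shape[0]:
        raise ValueError("temporal envelope length mismatch")
    return movie + amplitude * temporal[:, None, None] * spatial[None]


def score_rejection(result: ExtractionResult, truth: GroundTruth) -> MethodScore:
    """Score one extraction against the known contamination."""
    env = truth.contamination_temporal
    if np.ptp(env) == 0:
        raise ValueError("contamination envelope is constant; nothing to score")
    # frames on which stimulation-locked contamination is present
    frames = env > 0.01 * env.max()
    if frames.sum() < 3:
        frames = np.ones_like(env, dtype=bool)
    traces = result.traces[:, frames]
    env_f = env[frames]
    corrs = []
    n_constant = 0
    for tr in traces:
        if np.ptp(tr) == 0:
            n_constant += 1
            corrs.append(0.0)   # flagged via constant_traces
        else:
            corrs.append(abs(float(np.corrcoef(tr, env_f)[0, 1])))
    pairwise = None
    if len(traces) >= 2:
        keep = [i for i, tr in enumerate(traces) if np.ptp(tr) > 0]
        if len(keep) >= 2:
            R = np.corrcoef(traces[keep])
            iu = np.triu_indices(len(keep), k=1)
            pairwise = float(np.median(R[iu]))
    match = match_components(result.footprints, truth.footprints.footprints)
    return MethodScore(
        method=result.method_label,
        bandpass=False,
        n_found=result.n_found,
        median_abs_contam_corr=float(np.median(corrs)) if corrs else np.nan,
        median_pairwise_corr=pairwise,
        precision=match.precision,
        recall=match.recall,
        constant_traces=n_constant,
    )


def _make_extractor(method: str, truth: GroundTruth, config: SimConfig,
                    seed: int):
    radius = float(np.mean(config.cell_radius_px))
    if method == "roi":
        return RoiExtractor(seeds=truth.footprints.centers, radius_px=radius)
    if method == "pca_ica":
        n = max(int(round(1.5 * config.n_cells)), 2)
        return PcaIcaExtractor(n_components=n, mu=0.5, random_state=seed)
    if method == "cnmf_ring":
        return RingCnmf(neuron_diameter_px=4.0 * radius,
                        max_cells=2 * config.n_cells, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def run_method_comparison(
    sim_config: SimConfig,
    n_frames: int,
    methods: tuple[str, ...] = ("roi", "pca_ica", "cnmf_ring"),
    bandpass_options: tuple[bool, ...] = (False, True),
    bandpass_cutoffs: tuple[float, float] = (5.0, 31.0),
    amplitude_scale: float = 2.0,
    seed: int | None = None,
    schedule_kw: dict | None = None,
) -> BenchReport:
    """Run the full contamination-rejection comparison on one synthetic movie.

    The substrate movie carries ongoing asynchronous cell activity (so the
    envelope correlation of a perfectly extracted trace is ~0), and
    stimulation-locked contamination with amplitude ``amplitude_scale`` times
    the median cell peak is injected on top.  Every method then runs on the
    raw and (optionally) bandpass-prefiltered movie.  Method failures are
    recorded per method and the comparison continues.
    """
    from .sim import build_stim_schedule, generate_contamination

    seed = sim_config.seed if seed is None else seed
    cfg = sim_config.replace(seed=seed, contamination_amplitude=0.0)
    movie, truth = simulate_session(cfg, None, n_frames)
    schedule = build_stim_schedule("anesthetized", n_frames,
                                   cfg.frame_rate_hz, **(schedule_kw or {}))
    truth.schedule = schedule
    _, envelope_shape = generate_contamination(
        schedule, n_frames, cfg.replace(contamination_amplitude=1.0))
    # amplitude tied to signal strength: 2 x the median cell trace peak
    peaks = truth.traces.max(axis=1)
    active = peaks[peaks > 0]
    median_peak = float(np.median(active)) if active.size else 1.0
    amplitude = amplitude_scale * median_peak
    movie = inject_contamination(movie, truth.contamination_spatial,
                                 envelope_shape, amplitude)
    # score against the unit-peak envelope shape: correlation is
    # scale-invariant, and this keeps the zero-amplitude control scorable
    truth.contamination_temporal = envelope_shape

    report = BenchReport(contamination_amplitude=amplitude, seed=seed)
    filtered = None
    for use_bp in bandpass_options:
        if use_bp and filtered is None:
            filtered = SpatialBandpass(*bandpass_cutoffs).fit_transform(movie)
        for method in methods:
            if method == "cnmf_ring" and use_bp:
                # the ring model is the background handler; it runs on raw data
                continue
            data = filtered if use_bp else movie
            if method == "cnmf_ring":
                data = movie
            try:
                est = _make_extractor(method, truth, cfg, seed)
                est.fit(data)
                score = score_rejection(est.result_, truth)
                score.bandpass = use_bp
            except Exception as exc:   # record and continue
                score = MethodScore(method=method, bandpass=use_bp, n_found=0,
                                    median_abs_contam_corr=np.nan,
                                    median_pairwise_corr=None,
                                    precision=np.nan, recall=np.nan,
                                    error=str(exc))
            report.scores.append(score)
    return report
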