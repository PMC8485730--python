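"""Generative model of single-photon miniscope recordings under deep-brain
stimulation.

The simulator produces everything the downstream analyses consume, with full
ground truth:

* a fluorescence movie: somatic footprints times calcium traces, on top of a
  structured static background, plus stimulation-locked low-spatial-frequency
  contamination emulating out-of-focus activation, plus Gaussian sensor noise;
* a locomotor-velocity trace (rectified Ornstein-Uhlenbeck process) with both
  rest (< 0.5 cm/s) and ambulation periods;
* a stimulation schedule for either the anesthetized paradigm (10-s trains at
  30/80/130 Hz separated by quiet intervals, the triplet repeated three times)
  or the awake open-field paradigm (long OFF blocks interleaved with 30 Hz and
  130 Hz ON blocks).

Spiking follows an inhomogeneous Poisson law.  Outside stimulation each cell
fires at ``baseline_rate_hz * (1 + velocity_gain * v(t))``.  Under the
anesthetized paradigm the baseline is ~0 (the striatum is quiescent under
anesthesia) and each stimulation epoch independently recruits each cell with a
frequency-dependent probability; recruited cells fire at an elevated rate for
the epoch.  Under the awake paradigm stimulation multiplies the ongoing rate
by a suppression factor < 1.

All randomness derives from one integer seed; each component draws from its
own fixed substream so that, e.g., adding noise does not perturb spike times.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "SimConfig",
    "BehaviorTrace",
    "StimEpoch",
    "StimSchedule",
    "FootprintSet",
    "GroundTruth",
    "generate_footprints",
    "generate_velocity_trace",
    "build_stim_schedule",
    "generate_spike_trains",
    "convolve_calcium",
    "calcium_kernel",
    "generate_contamination",
    "generate_baseline_image",
    "render_movie",
    "simulate_session",
]

# fixed substream offsets so components are independently reproducible
_STREAM_FOOTPRINTS = 1
_STREAM_VELOCITY = 2
_STREAM_SPIKES = 3
_STREAM_CONTAMINATION = 4
_STREAM_BASELINE = 5
_STREAM_NOISE = 6

ANESTHETIZED = "anesthetized"
AWAKE = "awake"


def _substream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


@dataclass
class SimConfig:
    """Parameters of the generative model.

    Units: rates in Hz, velocities in cm/s, kernel time constants in seconds,
    sizes in pixels of the simulated field of view.
    """

    fov_px: tuple[int, int] = (100, 100)
    frame_rate_hz: float = 20.0
    n_cells: int = 30
    cell_radius_px: tuple[float, float] = (3.0, 5.0)
    baseline_rate_hz: float = 0.2
    velocity_gain: float = 0.5           # beta in lambda = lambda0*(1 + beta*v)
    recruit_prob: dict[float, float] = field(
        default_factory=lambda: {30.0: 0.1, 80.0: 0.4, 130.0: 0.5}
    )
    stim_rate_hz: float = 2.0            # firing rate of recruited cells
    suppression_factor: float = 0.6      # awake: rate multiplier during stim
    kernel_rise_s: float = 0.1           # GCaMP6m-like transient
    kernel_decay_s: float = 0.8
    noise_sd: float = 0.03
    contamination_amplitude: float = 0.0
    baseline_offset: float = 1.0         # mean level of the static background
    baseline_texture: float = 0.3        # amplitude of its smooth structure
    ou_mean_cmps: float = 2.0            # velocity process parameters
    ou_tau_s: float = 2.0
    ou_sigma: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.fov_px
        if h < 16 or w < 16:
            raise ValueError("fov_px dimensions must be at least 16")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        rmin, rmax = self.cell_radius_px
        if rmin <= 0 or rmax < rmin:
            raise ValueError("cell_radius_px must satisfy 0 < min <= max")
        if self.kernel_decay_s <= self.kernel_rise_s:
            raise ValueError("kernel_decay_s must exceed kernel_rise_s")
        for f, p in self.recruit_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"recruit_prob[{f}] outside [0, 1]")
        for name in ("baseline_rate_hz", "velocity_gain", "noise_sd",
                     "contamination_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class BehaviorTrace:
    """Frame-aligned locomotor velocity in cm/s."""

    velocity_cmps: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.velocity_cmps = np.asarray(self.velocity_cmps, dtype=float)
        if self.velocity_cmps.ndim != 1:
            raise ValueError("velocity must be a 1-D sequence")
        if np.any(self.velocity_cmps < 0):
            raise ValueError("velocities must be nonnegative")

    def __len__(self) -> int:
        return self.velocity_cmps.size


@dataclass(frozen=True)
class StimEpoch:
    start: int          # frame, inclusive
    stop: int           # frame, exclusive
    frequency_hz: float
    amplitude_ua: float
    pulse_width_us: float


@dataclass
class StimSchedule:
    epochs: list[StimEpoch]
    paradigm: str

    def __post_init__(self) -> None:
        prev_stop = -1
        for ep in self.epochs:
            if ep.stop <= ep.start:
                raise ValueError(f"empty or inverted epoch {ep}")
            if ep.start < prev_stop:
                raise ValueError("epochs overlap or are unsorted")
            prev_stop = ep.stop

    def indicator(self, n_frames: int) -> np.ndarray:
        """Binary per-frame stimulation indicator."""
        ind = np.zeros(n_frames)
        for ep in self.epochs:
            ind[ep.start:min(ep.stop, n_frames)] = 1.0
        return ind

    def frame_frequency(self, n_frames: int) -> np.ndarray:
        """Per-frame stimulation frequency (0 outside epochs)."""
        f = np.zeros(n_frames)
        for ep in self.epochs:
            f[ep.start:min(ep.stop, n_frames)] = ep.frequency_hz
        return f


@dataclass
class FootprintSet:
    footprints: np.ndarray   # (n_cells, H, W), each peak-normalized to 1
    centers: np.ndarray      # (n_cells, 2) as (row, col)
    sigmas: np.ndarray       # (n_cells,) Gaussian widths

    @property
    def n_cells(self) -> int:
        return self.footprints.shape[0]


@dataclass
class GroundTruth:
    footprints: FootprintSet
    traces: np.ndarray                 # (n_cells, T), noiseless
    events: np.ndarray                 # (n_cells, T) integer counts
    baseline_image: np.ndarray         # (H, W)
    contamination_spatial: np.ndarray  # (H, W), peak 1 (or zeros)
    contamination_temporal: np.ndarray # (T,)
    behavior: BehaviorTrace
    schedule: StimSchedule


# --------------------------------------------------------------------------
# footprints

def generate_footprints(config: SimConfig) -> FootprintSet:
    """Place ``n_cells`` isotropic Gaussian somata in the field of view.

    Widths (sigma) are uniform in ``cell_radius_px``; profiles are truncated
    at two sigma, then peak-normalized.  Centers keep at least the maximum
    cell radius from the FOV edge and at least one such radius apart.
    Raises ``RuntimeError`` when placement fails repeatedly, which signals a
    FOV too small for the requested cell count.
    """
    h, w = config.fov_px
    rmin, rmax = config.cell_radius_px
    rng = _substream(config.seed, _STREAM_FOOTPRINTS)
    n = config.n_cells
    if n == 0:
        return FootprintSet(
            footprints=np.zeros((0, h, w)),
            centers=np.zeros((0, 2)),
            sigmas=np.zeros(0),
        )
    margin = rmax
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise RuntimeError("FOV too small for the requested cell radius")
    centers: list[np.ndarray] = []
    max_attempts = 200 * n
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} cells with spacing {rmax:.1f}px "
                f"in a {h}x{w} FOV; enlarge the FOV or reduce n_cells"
            )
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(cand - c)) >= rmax for c in centers):
            centers.append(cand)
    centers_arr = np.array(centers)
    sigmas = rng.uniform(rmin, rmax, size=n)
    yy, xx = np.mgrid[0:h, 0:w]
    fp = np.zeros((n, h, w))
    for i, ((cy, cx), s) in enumerate(zip(centers_arr, sigmas)):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        blob = np.exp(-d2 / (2 * s**2))
        blob[d2 > (2 * s) ** 2] = 0.0   # truncate at 2 sigma
        fp[i] = blob / blob.max()
    return FootprintSet(footprints=fp, centers=centers_arr, sigmas=sigmas)


# --------------------------------------------------------------------------
# behavior

def generate_velocity_trace(n_frames: int, config: SimConfig) -> BehaviorTrace:
    """Rectified Ornstein-Uhlenbeck locomotor velocity.

    The latent process mean-reverts to ``ou_mean_cmps`` with time constant
    ``ou_tau_s`` and stationary scale set by ``ou_sigma``; negative values are
    clipped to zero (the animal cannot move backwards in speed).  Default
    parameters yield both rest (< 0.5 cm/s) and ambulation (> 2 cm/s) in
    realistic proportions.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _substream(config.seed, _STREAM_VELOCITY)
    dt = 1.0 / config.frame_rate_hz
    theta = 1.0 / config.ou_tau_s
    mu = config.ou_mean_cmps
    decay = np.exp(-theta * dt)
    if config.ou_sigma == 0:
        return BehaviorTrace(np.full(n_frames, max(mu, 0.0)),
                             config.frame_rate_hz)
    sd_step = config.ou_sigma * np.sqrt((1 - decay**2) / (2 * theta))
    v = np.empty(n_frames)
    x = mu
    steps = rng.standard_normal(n_frames)
    for t in range(n_frames):
        v[t] = max(x, 0.0)
        x = mu + (x - mu) * decay + sd_step * steps[t]
    return BehaviorTrace(v, config.frame_rate_hz)


# --------------------------------------------------------------------------
# stimulation schedules

def build_stim_schedule(
    paradigm: str,
    n_frames: int,
    frame_rate_hz: float,
    *,
    epoch_s: float = 10.0,
    gap_s: float = 60.0,
    pre_s: float = 10.0,
    block_s: float = 600.0,
    anesthetized_amplitude_ua: float = 30.0,
    awake_amplitude_ua: float = 30.0,
) -> StimSchedule:
    """Construct the stimulation schedule for one recording.

    anesthetized
        ``epoch_s``-long trains separated by ``gap_s`` quiet intervals, the
        frequency triplet (30, 80, 130 Hz) repeated three times (9 epochs),
        140 us pulse width.
    awake
        alternating OFF / ON blocks of ``block_s`` each, ON frequencies
        cycling through 30 then 130 Hz, 200 us pulse width.

    Raises ``ValueError`` naming the minimum duration when ``n_frames`` is
    too short for a single epoch.
    """
    fr = float(frame_rate_hz)
    epochs: list[StimEpoch] = []
    if paradigm == ANESTHETIZED:
        freqs = [30.0, 80.0, 130.0] * 3
        period = int(round((epoch_s + gap_s) * fr))
        ep_len = int(round(epoch_s * fr))
        start0 = int(round(pre_s * fr))
        min_frames = start0 + ep_len
        if n_frames < min_frames:
            raise ValueError(
                f"recording too short for the anesthetized paradigm: need at "
                f"least {min_frames} frames ({min_frames / fr:.0f} s)"
            )
        for k, f in enumerate(freqs):
            start = start0 + k * period
            stop = start + ep_len
            if stop > n_frames:
                break
            epochs.append(StimEpoch(start, stop, f, anesthetized_amplitude_ua, 140.0))
    elif paradigm == AWAKE:
        blk = int(round(block_s * fr))
        min_frames = 2 * blk
        if n_frames < min_frames:
            raise ValueError(
                f"recording too short for the awake paradigm: need at least "
                f"{min_frames} frames ({min_frames / fr:.0f} s, one OFF and "
                f"one ON block)"
            )
        on_freqs = [30.0, 130.0]
        k = 0
        start = blk            # first block is OFF
        while start + blk <= n_frames:
            f = on_freqs[k % len(on_freqs)]
            epochs.append(StimEpoch(start, start + blk, f, awake_amplitude_ua, 200.0))
            k += 1
            start += 2 * blk   # skip the following OFF block
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    return StimSchedule(epochs=epochs, paradigm=paradigm)


# --------------------------------------------------------------------------
# spiking

def generate_spike_trains(
    behavior: BehaviorTrace,
    schedule: StimSchedule | None,
    footprints: FootprintSet,
    config: SimConfig,
) -> np.ndarray:
    """Inhomogeneous-Poisson event raster, (n_cells, T) integer counts.

    Outside stimulation every cell fires at
    ``baseline_rate_hz * (1 + velocity_gain * v(t))``.  Anesthetized epochs
    recruit each cell independently with ``recruit_prob[frequency]`` (redrawn
    every epoch, so responses to repeated identical stimulation are
    heterogeneous); recruited cells fire at ``stim_rate_hz`` for the epoch.
    Awake epochs multiply the ongoing rate by ``suppression_factor``.
    """
    T = len(behavior)
    n = footprints.n_cells
    rng = _substream(config.seed, _STREAM_SPIKES)
    v = behavior.velocity_cmps
    lam = np.broadcast_to(
        config.baseline_rate_hz * (1.0 + config.velocity_gain * v), (n, T)
    ).copy()
    if schedule is not None:
        for ep in schedule.epochs:
            if ep.stop > T:
                raise ValueError("schedule extends beyond the recording")
            if schedule.paradigm == ANESTHETIZED:
                p = config.recruit_prob.get(float(ep.frequency_hz), 0.0)
                recruited = rng.random(n) < p
                lam[recruited, ep.start:ep.stop] = config.stim_rate_hz
            else:
                lam[:, ep.start:ep.stop] *= config.suppression_factor
    return rng.poisson(lam / config.frame_rate_hz).astype(np.int64)


# --------------------------------------------------------------------------
# calcium dynamics

def calcium_kernel(config: SimConfig) -> np.ndarray:
    """Causal double-exponential transient, peak-normalized to 1.

    ``k(t) = exp(-t/tau_decay) - exp(-t/tau_rise)``, sampled at the frame
    rate and truncated once the decay falls below 1e-3 of the peak.
    """
    fr = config.frame_rate_hz
    n = int(np.ceil(7.0 * config.kernel_decay_s * fr)) + 1
    t = np.arange(n) / fr
    k = np.exp(-t / config.kernel_decay_s) - np.exp(-t / config.kernel_rise_s)
    k = np.clip(k, 0.0, None)
    peak = k.max()
    if peak <= 0:       # kernel shorter than one frame; use a unit impulse
        k = np.zeros(n)
        k[0] = 1.0
        return k
    return k / peak


def convolve_calcium(events: np.ndarray, config: SimConfig) -> np.ndarray:
    """Convolve an event raster with the calcium kernel (linear, causal)."""
    events = np.asarray(events, dtype=float)
    if events.ndim != 2:
        raise ValueError("events must be (n_cells, T)")
    n, T = events.shape
    if n == 0 or T == 0:
        return np.zeros_like(events)
    k = calcium_kernel(config)
    out = signal.fftconvolve(events, k[None, :], axes=1)[:, :T]
    return np.clip(out, 0.0, None)


# --------------------------------------------------------------------------
# contamination and background

def generate_contamination(
    schedule: StimSchedule | None,
    n_frames: int,
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulation-locked out-of-focus background contamination.

    Returns ``(spatial, temporal)``.  The spatial field models defocused
    out-of-plane somata: a sum of 1-3 broad Gaussians (sigma >= FOV/4)
    carrying most of the energy, plus a weaker ripple of blurred soma-sized
    blobs — out-of-focus cells are smooth but not featureless, which is why
    a spatial bandpass attenuates this contamination without eliminating it.
    The field is peak-normalized to 1.  The temporal envelope is the epoch
    indicator, weighted per epoch by frequency (higher stimulation frequency
    evokes a larger out-of-focus rise), convolved with the calcium kernel and
    scaled so its peak equals ``contamination_amplitude``.
    """
    h, w = config.fov_px
    rng = _substream(config.seed, _STREAM_CONTAMINATION)
    n_gauss = int(rng.integers(1, 4))
    yy, xx = np.mgrid[0:h, 0:w]
    spatial = np.zeros((h, w))
    for _ in range(n_gauss):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        s = rng.uniform(w / 4.0, w / 2.0)
        spatial += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    spatial /= spatial.max()
    ripple = np.zeros((h, w))
    blur = 2.0 * config.cell_radius_px[1]
    for _ in range(max(h * w // 300, 5)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ripple += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * blur**2))
    if ripple.max() > 0:
        spatial = spatial + 0.25 * ripple / ripple.max()
    spatial /= spatial.max()

    drive = np.zeros(n_frames)
    if schedule is not None:
        freqs = [ep.frequency_hz for ep in schedule.epochs]
        fmax = max(freqs) if freqs else 1.0
        for ep in schedule.epochs:
            drive[ep.start:min(ep.stop, n_frames)] = ep.frequency_hz / fmax
    k = calcium_kernel(config)
    temporal = signal.fftconvolve(drive, k)[:n_frames]
    temporal = np.clip(temporal, 0.0, None)
    peak = temporal.max()
    if peak > 0:
        temporal = temporal / peak * config.contamination_amplitude
    return spatial, temporal


def generate_baseline_image(config: SimConfig) -> np.ndarray:
    """Static structured background: positive offset plus smooth texture."""
    h, w = config.fov_px
    rng = _substream(config.seed, _STREAM_BASELINE)
    noise = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(noise, sigma=min(h, w) / 8.0)
    span = np.abs(smooth).max()
    if span > 0:
        smooth = smooth / span
    img = config.baseline_offset + config.baseline_texture * smooth
    return np.clip(img, 0.1 * config.baseline_offset, None)


# --------------------------------------------------------------------------
# rendering

def render_movie(truth: GroundTruth, config: SimConfig) -> np.ndarray:
    """Compose the movie from ground-truth components.

    ``frame(t) = baseline + sum_i footprint_i * trace_i(t)
    + contamination_spatial * contamination_temporal(t) + N(0, noise_sd)``,
    clipped at zero.  With ``noise_sd = 0`` the composition is exact.
    """
    fp = truth.footprints.footprints
    n, h, w = fp.shape
    T = truth.traces.shape[1]
    if truth.traces.shape[0] != n:
        raise ValueError("traces and footprints disagree on cell count")
    if truth.baseline_image.shape != (h, w):
        raise ValueError("baseline image shape mismatch")
    if truth.contamination_spatial.shape != (h, w):
        raise ValueError("contamination field shape mismatch")
    if truth.contamination_temporal.shape[0] != T:
        raise ValueError("contamination envelope length mismatch")
    movie = np.empty((T, h, w), dtype=np.float64)
    movie[:] = truth.baseline_image[None]
    if n:
        movie += (truth.traces.T @ fp.reshape(n, -1)).reshape(T, h, w)
    movie += truth.contamination_temporal[:, None, None] * truth.contamination_spatial[None]
    if config.noise_sd > 0:
        rng = _substream(config.seed, _STREAM_NOISE)
        movie += rng.normal(0.0, config.noise_sd, size=movie.shape)
        np.clip(movie, 0.0, None, out=movie)
    return movie


# --------------------------------------------------------------------------
# one-call session

def simulate_session(
    config: SimConfig,
    paradigm: str | None,
    n_frames: int,
    *,
    schedule: StimSchedule | None = None,
    render: bool = True,
    **schedule_kw,
) -> tuple[np.ndarray | None, GroundTruth]:
    """Generate a full synthetic recording session.

    ``paradigm`` is ``"anesthetized"``, ``"awake"`` or ``None`` (no
    stimulation).  A pre-built ``schedule`` overrides paradigm construction.
    With ``render=False`` only ground truth is produced (the movie is None),
    which is what the raster-level statistics need.
    """
    if schedule is None and paradigm is not None:
        schedule = build_stim_schedule(
            paradigm, n_frames, config.frame_rate_hz, **schedule_kw
        )
    footprints = generate_footprints(config)
    behavior = generate_velocity_trace(n_frames, config)
    events = generate_spike_trains(behavior, schedule, footprints, config)
    traces = convolve_calcium(events, config)
    contamination_spatial, contamination_temporal = generate_contamination(
        schedule, n_frames, config
    )
    truth = GroundTruth(
        footprints=footprints,
        traces=traces,
        events=events,
        baseline_image=generate_baseline_image(config),
        contamination_spatial=contamination_spatial,
        contamination_temporal=contamination_temporal,
        behavior=behavior,
        schedule=schedule if schedule is not None else StimSchedule([], "none"),
    )
    movie = render_movie(truth, config) if render else None
    return movie, truth
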