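"""Movie preprocessing: spatial downsampling, dF/F, spatial bandpass,
rigid motion correction.

The steps mirror a standard miniscope workflow: movies are spatially
downsampled by block averaging (a factor of two, then optionally a further
factor of three), motion corrected by rigid translation against a reference
frame, converted to dF/F against a per-pixel baseline, and optionally
bandpass-filtered with a difference of Gaussians whose cutoffs bracket the
size of cell bodies (5 and 31 pixels by default).

Each step is exposed both as a scikit-learn style transformer (operating on
``(T, H, W)`` arrays) and as a plain function wrapping it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PreprocessConfig",
    "SpatialDownsampler",
    "DeltaFOverF",
    "SpatialBandpass",
    "RigidMotionCorrector",
    "downsample_spatial",
    "compute_dff",
    "spatial_bandpass",
    "motion_correct_rigid",
]


@dataclass
class PreprocessConfig:
    downsample_factor_1: int = 2
    downsample_factor_2: int = 3
    bandpass_cutoffs_px: tuple[float, float] = (5.0, 31.0)
    max_shift_px: int = 10
    motion_correct: bool = True   # off for anesthetized recordings
    dff_baseline: str = "mean"    # or "percentile"
    dff_percentile: float = 10.0

    def __post_init__(self) -> None:
        if self.downsample_factor_1 < 1 or self.downsample_factor_2 < 1:
            raise ValueError("downsample factors must be >= 1")
        lo, hi = self.bandpass_cutoffs_px
        if not 0 < lo < hi:
            raise ValueError("bandpass cutoffs must satisfy 0 < low < high")


def _check_movie(movie: np.ndarray) -> np.ndarray:
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError(f"movie must be (T, H, W); got shape {movie.shape}")
    return movie


class SpatialDownsampler(BaseEstimator, TransformerMixin):
    """Block-mean spatial downsampling by an integer factor.

    Trailing rows/columns that do not fill a complete block are cropped
    (never padded), so a non-divisible FOV shrinks by less than one block.
    """

    def __init__(self, factor: int = 2):
        self.factor = factor

    def fit(self, X, y=None):
        if int(self.factor) < 1:
            raise ValueError("factor must be >= 1")
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        X = _check_movie(X)
        f = int(self.factor)
        if f == 1:
            return X.copy()
        T, h, w = X.shape
        hq, wq = h // f, w // f
        if hq == 0 or wq == 0:
            raise ValueError("FOV smaller than one block")
        cropped = X[:, : hq * f, : wq * f]
        return cropped.reshape(T, hq, f, wq, f).mean(axis=(2, 4))


class DeltaFOverF(BaseEstimator, TransformerMixin):
    """Per-pixel dF/F: ``(F - F0) / F0``.

    ``F0`` is the per-pixel temporal mean (default) or a lower temporal
    percentile.  The baseline is learned in ``fit`` so a session can be
    normalized against its own (or another movie's) baseline.
    """

    def __init__(self, baseline: str = "mean", percentile: float = 10.0):
        self.baseline = baseline
        self.percentile = percentile

    def fit(self, X, y=None):
        X = _check_movie(X)
        if self.baseline == "mean":
            f0 = X.mean(axis=0)
        elif self.baseline == "percentile":
            f0 = np.percentile(X, self.percentile, axis=0)
        else:
            raise ValueError(f"unknown baseline method {self.baseline!r}")
        n_bad = int(np.count_nonzero(f0 <= 0))
        if n_bad:
            raise ValueError(
                f"dF/F baseline is non-positive at {n_bad} pixel(s)"
            )
        self.f0_ = f0
        return self

    def transform(self, X) -> np.ndarray:
        X = _check_movie(X)
        return (X - self.f0_[None]) / self.f0_[None]


class SpatialBandpass(BaseEstimator, TransformerMixin):
    """Per-frame difference-of-Gaussians bandpass.

    Cutoffs are given as structure sizes in pixels; they map to Gaussian
    widths as ``sigma = cutoff / 4`` (so a cutoff names roughly the full
    width of the structures it passes or blocks).  Structures smaller than
    ``low`` and broader than ``high`` pixels are attenuated.
    """

    def __init__(self, low: float = 5.0, high: float = 31.0):
        self.low = low
        self.high = high

    def fit(self, X, y=None):
        if not 0 < self.low < self.high:
            raise ValueError("cutoffs must satisfy 0 < low < high")
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        X = _check_movie(X).astype(float, copy=False)
        s_lo = self.low / 4.0
        s_hi = self.high / 4.0
        fine = ndimage.gaussian_filter(X, sigma=(0, s_lo, s_lo))
        coarse = ndimage.gaussian_filter(X, sigma=(0, s_hi, s_hi))
        return fine - coarse


class RigidMotionCorrector(BaseEstimator, TransformerMixin):
    """Rigid (translation-only) registration against a reference frame.

    Per frame, the translation maximizing the cross-correlation with the
    reference within ``+/- max_shift`` pixels is found on the integer grid
    and refined to subpixel precision by a parabolic fit of the correlation
    peak; the frame is shifted back by linear interpolation.  Flat
    correlation surfaces (e.g. constant frames) resolve to zero shift.
    ``shifts_`` holds the applied (dy, dx) per frame.
    """

    def __init__(self, max_shift: int = 10, reference: str | int = "mean",
                 subpixel: bool = True):
        self.max_shift = max_shift
        self.reference = reference
        self.subpixel = subpixel

    def fit(self, X, y=None):
        X = _check_movie(X)
        if self.max_shift >= min(X.shape[1], X.shape[2]) / 2:
            raise ValueError("max_shift must be below half the FOV size")
        if self.reference == "mean":
            self.reference_ = X.mean(axis=0)
        else:
            self.reference_ = X[int(self.reference)].astype(float)
        return self

    def _estimate_shift(self, frame: np.ndarray, ref_f: np.ndarray,
                        h: int, w: int) -> tuple[float, float]:
        m = int(self.max_shift)
        f = np.asarray(frame, dtype=float)
        if m == 0 or f.std() == 0 or not np.isfinite(f).all():
            return 0.0, 0.0
        cc = np.fft.irfft2(ref_f * np.conj(np.fft.rfft2(f - f.mean())),
                           s=(h, w))
        # restrict the search window to +/- max_shift around zero lag
        window = np.full((h, w), -np.inf)
        window[:m + 1, :m + 1] = cc[:m + 1, :m + 1]
        window[:m + 1, -m:] = cc[:m + 1, -m:]
        window[-m:, :m + 1] = cc[-m:, :m + 1]
        window[-m:, -m:] = cc[-m:, -m:]
        peak = np.unravel_index(np.argmax(window), window.shape)
        if window[peak] <= cc[0, 0] + 1e-12 * abs(cc[0, 0]):
            peak = (0, 0)   # tie-break: prefer zero shift
        dy = peak[0] if peak[0] <= h // 2 else peak[0] - h
        dx = peak[1] if peak[1] <= w // 2 else peak[1] - w
        if self.subpixel and abs(dy) < m and abs(dx) < m:
            dy += _parabolic_offset(
                cc[(peak[0] - 1) % h, peak[1]], cc[peak], cc[(peak[0] + 1) % h, peak[1]]
            )
            dx += _parabolic_offset(
                cc[peak[0], (peak[1] - 1) % w], cc[peak], cc[peak[0], (peak[1] + 1) % w]
            )
        # snap numerically-integer shifts so exact translations roll losslessly
        if abs(dy - round(dy)) < 1e-3:
            dy = round(dy)
        if abs(dx - round(dx)) < 1e-3:
            dx = round(dx)
        return float(dy), float(dx)

    def transform(self, X) -> np.ndarray:
        X = _check_movie(X).astype(float, copy=False)
        T, h, w = X.shape
        ref = self.reference_ - self.reference_.mean()
        ref_f = np.fft.rfft2(ref)
        out = np.empty_like(X)
        shifts = np.zeros((T, 2))
        for t in range(T):
            dy, dx = self._estimate_shift(X[t], ref_f, h, w)
            shifts[t] = (dy, dx)
            if dy == 0 and dx == 0:
                out[t] = X[t]
            elif dy == int(dy) and dx == int(dx):
                out[t] = np.roll(X[t], (int(dy), int(dx)), axis=(0, 1))
            else:
                out[t] = ndimage.shift(X[t], (dy, dx), order=1,
                                       mode="nearest")
        self.shifts_ = shifts
        return out


def _parabolic_offset(left: float, center: float, right: float) -> float:
    denom = left - 2 * center + right
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    off = 0.5 * (left - right) / denom
    return float(np.clip(off, -0.5, 0.5))


# --------------------------------------------------------------------------
# functional wrappers

def downsample_spatial(movie: np.ndarray, factor: int) -> np.ndarray:
    return SpatialDownsampler(factor=factor).fit_transform(movie)


def compute_dff(movie: np.ndarray, baseline: str = "mean",
                percentile: float = 10.0) -> np.ndarray:
    return DeltaFOverF(baseline=baseline, percentile=percentile).fit_transform(movie)


def spatial_bandpass(movie: np.ndarray,
                     cutoffs_px: tuple[float, float] = (5.0, 31.0)) -> np.ndarray:
    return SpatialBandpass(low=cutoffs_px[0], high=cutoffs_px[1]).fit_transform(movie)


def motion_correct_rigid(
    movie: np.ndarray,
    reference: np.ndarray | str | int = "mean",
    max_shift_px: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Register a movie by rigid translation; returns (movie, shifts)."""
    corr = RigidMotionCorrector(max_shift=max_shift_px)
    if isinstance(reference, np.ndarray):
        movie = _check_movie(movie)
        if reference.shape != movie.shape[1:]:
            raise ValueError("reference shape must match frame shape")
        corr.reference = 0
        corr.fit(movie)
        corr.reference_ = reference.astype(float)
    else:
        corr.reference = reference
        corr.fit(movie)
    corrected = corr.transform(movie)
    return corrected, corr.shifts_
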