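"""Neural-signal identification from one-photon calcium movies.

Three methods are implemented as scikit-learn style estimators, matching the
techniques commonly compared for microendoscope data:

``RoiExtractor``
    seeded region-of-interest averaging: the trace is the mean pixel value in
    a disk around each seed.  Deliberately performs no background
    subtraction, so low-spatial-frequency contamination leaks into every
    trace — the known weakness of ROI analysis.

``PcaIcaExtractor``
    truncated SVD followed by spatiotemporal ICA.  A weight ``mu`` blends the
    spatial and temporal representations of each principal component before
    fixed-point ICA de-mixing (``mu = 1`` purely spatial, ``mu = 0`` purely
    temporal).  Cells firing synchronously share a temporal subspace
    direction, which is why this method struggles to split them.

``RingCnmf``
    a single-patch constrained NMF with a ring model of background
    fluorescence: the background at each pixel is a learned nonnegative
    combination of the residual movie on a surrounding ring (one weight
    vector shared across pixels, i.e. a translation-invariant ring kernel).
    Cells are seeded greedily from a local-correlation x peak-to-noise image;
    footprints are support-constrained to a box around their seed and updated
    together with traces by hierarchical alternating least squares.  This is
    a compact re-implementation of the ring-background idea, not the full
    published CNMF-E pipeline (no patching, no in-loop deconvolution).

All estimators expose ``footprints_`` (n, H, W, nonnegative), ``traces_``
(n, T) and ``diagnostics_`` after ``fit``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "ExtractionResult",
    "CnmfRingConfig",
    "RoiExtractor",
    "PcaIcaExtractor",
    "RingCnmf",
    "Matching",
    "extract_roi",
    "extract_pca_ica",
    "extract_cnmf_ring",
    "match_components",
]


@dataclass
class ExtractionResult:
    """Spatial footprints, temporal traces and metadata from one method."""

    footprints: np.ndarray   # (n_found, H, W), nonnegative
    traces: np.ndarray       # (n_found, T)
    method_label: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_found(self) -> int:
        return self.footprints.shape[0]


@dataclass
class CnmfRingConfig:
    """Tuning of the ring-background constrained NMF."""

    neuron_diameter_px: float = 12.0
    ring_diameter_px: float | None = None   # default 1.5 x neuron diameter
    max_iterations: int = 20
    warmup_iterations: int = 3
    inner_iterations: int = 5
    background_update_every: int = 3
    min_corr: float = 0.8
    min_pnr: float = 8.0
    convergence_tol: float = 1e-5
    merge_threshold: float = 0.8
    min_compactness: float = 0.5
    min_trace_snr: float = 5.0
    n_background_components: int = 2
    max_cells: int | None = None
    seed: int = 0

    def resolved_ring_diameter(self) -> float:
        if self.ring_diameter_px is not None:
            return float(self.ring_diameter_px)
        return 1.5 * self.neuron_diameter_px


def _as_movie(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError(f"expected a (T, H, W) movie, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("movie contains non-finite values")
    return X


class _BaseExtractor(BaseEstimator):
    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the temporal traces (n_found, T)."""
        self.fit(X)
        return self.traces_

    @property
    def result_(self) -> ExtractionResult:
        return ExtractionResult(
            footprints=self.footprints_,
            traces=self.traces_,
            method_label=self._method_label,
            diagnostics=self.diagnostics_,
        )


# --------------------------------------------------------------------------
# seeded ROI averaging

class RoiExtractor(_BaseExtractor):
    """Mean intensity inside a disk around each seed, no background model."""

    _method_label = "roi"

    def __init__(self, seeds=(), radius_px: float = 4.0):
        self.seeds = seeds
        self.radius_px = radius_px

    def fit(self, X, y=None):
        X = _as_movie(X)
        T, h, w = X.shape
        seeds = np.atleast_2d(np.asarray(self.seeds, dtype=float))
        if seeds.size == 0:
            seeds = seeds.reshape(0, 2)
        n = seeds.shape[0]
        yy, xx = np.mgrid[0:h, 0:w]
        footprints = np.zeros((n, h, w))
        traces = np.zeros((n, T))
        flat = X.reshape(T, -1)
        for i, (cy, cx) in enumerate(seeds):
            if not (0 <= cy < h and 0 <= cx < w):
                raise ValueError(f"seed {i} at ({cy}, {cx}) outside the FOV")
            disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= self.radius_px**2
            footprints[i] = disk
            traces[i] = flat[:, disk.ravel()].mean(axis=1)
        self.footprints_ = footprints
        self.traces_ = traces
        self.diagnostics_ = {"n_seeds": n}
        return self


# --------------------------------------------------------------------------
# PCA/ICA

class PcaIcaExtractor(_BaseExtractor):
    """Truncated SVD + spatiotemporal fixed-point ICA component sorting."""

    _method_label = "pca_ica"

    def __init__(self, n_components: int = 10, mu: float = 0.5,
                 threshold_sd: float = 3.0, max_iter: int = 400,
                 random_state: int = 0):
        self.n_components = n_components
        self.mu = mu
        self.threshold_sd = threshold_sd
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_movie(X).astype(float, copy=False)
        T, h, w = X.shape
        P = h * w
        k = int(self.n_components)
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must lie in [0, 1]")
        if k < 1 or k > min(T, P):
            raise ValueError("n_components must be in [1, min(T, H*W)]")
        flat = X.reshape(T, P)
        mean_px = flat.mean(axis=0)
        centered = flat - mean_px
        U, S, Vt = randomized_svd(centered, n_components=k,
                                  random_state=self.random_state)
        # unit-variance spatial and temporal representations of each PC
        spatial = Vt / (Vt.std(axis=1, keepdims=True) + 1e-12)
        temporal = U.T / (U.T.std(axis=1, keepdims=True) + 1e-12)
        joint = np.concatenate(
            [self.mu * spatial, (1.0 - self.mu) * temporal], axis=1
        )
        converged = True
        if k == 1:
            unmix = np.eye(1)
        else:
            ica = FastICA(n_components=k, max_iter=self.max_iter,
                          random_state=self.random_state, whiten="unit-variance")
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                ica.fit(joint.T)          # samples = concatenated pixels+frames
            converged = not any("did not converge" in str(c.message)
                                for c in caught)
            unmix = ica.components_
        maps = unmix @ Vt                  # (k, P) spatial filters
        # orient each component so its bright side is positive
        flips = np.where(np.abs(maps.max(axis=1)) >= np.abs(maps.min(axis=1)),
                         1.0, -1.0)
        maps *= flips[:, None]
        footprints = self._threshold(maps, h, w)
        keep = footprints.reshape(len(footprints), -1).sum(axis=1) > 0
        footprints = footprints[keep]
        traces = _project_traces(centered, footprints)
        self.footprints_ = footprints
        self.traces_ = traces
        self.diagnostics_ = {
            "converged": converged,
            "n_components_requested": k,
            "n_components_kept": int(keep.sum()),
            "singular_values": S,
        }
        if not converged:
            warnings.warn("ICA did not converge; returning partial result",
                          RuntimeWarning)
        return self

    def _threshold(self, maps: np.ndarray, h: int, w: int) -> np.ndarray:
        """Zero sub-threshold pixels; contested pixels go to the component
        with the larger peak."""
        k = maps.shape[0]
        thr = self.threshold_sd * maps.std(axis=1, keepdims=True)
        fp = np.where(maps > thr, maps, 0.0)
        peaks = fp.max(axis=1)
        contested = (fp > 0).sum(axis=0) > 1
        if contested.any():
            order = np.argsort(peaks)      # ascending: larger peaks win last
            winner = np.full(maps.shape[1], -1)
            for i in order:
                winner[(fp[i] > 0) & contested] = i
            for i in range(k):
                fp[i, contested & (winner != i)] = 0.0
        return fp.reshape(k, h, w)


def _project_traces(centered_flat: np.ndarray,
                    footprints: np.ndarray) -> np.ndarray:
    """Least-squares projection of a (T, P) movie onto footprints."""
    n = footprints.shape[0]
    T = centered_flat.shape[0]
    if n == 0:
        return np.zeros((0, T))
    A = footprints.reshape(n, -1)
    sol, *_ = np.linalg.lstsq(A.T, centered_flat.T, rcond=None)
    return sol


# --------------------------------------------------------------------------
# ring-background constrained NMF

class RingCnmf(_BaseExtractor):
    """Simplified constrained NMF with a translation-invariant ring
    background model.

    Model: ``Y ~ A C + B`` with ``A, C >= 0`` and
    ``B_t = conv2(Y_t - (A C)_t, K_w)`` where ``K_w`` carries learned
    nonnegative weights on an annulus of the configured ring diameter.
    The ring is wider than any soma, so it reconstructs smooth out-of-focus
    background but cannot reproduce a compact cell body.
    """

    _method_label = "cnmf_ring"

    def __init__(self, neuron_diameter_px: float = 12.0,
                 ring_diameter_px: float | None = None,
                 max_iterations: int = 20, warmup_iterations: int = 3,
                 inner_iterations: int = 5, background_update_every: int = 3,
                 min_corr: float = 0.8, min_pnr: float = 8.0,
                 convergence_tol: float = 1e-5, merge_threshold: float = 0.8,
                 min_compactness: float = 0.5, min_trace_snr: float = 5.0,
                 n_background_components: int = 2,
                 max_cells: int | None = None, seed: int = 0):
        self.neuron_diameter_px = neuron_diameter_px
        self.ring_diameter_px = ring_diameter_px
        self.max_iterations = max_iterations
        self.warmup_iterations = warmup_iterations
        self.inner_iterations = inner_iterations
        self.background_update_every = background_update_every
        self.min_corr = min_corr
        self.min_pnr = min_pnr
        self.convergence_tol = convergence_tol
        self.merge_threshold = merge_threshold
        self.min_compactness = min_compactness
        self.min_trace_snr = min_trace_snr
        self.n_background_components = n_background_components
        self.max_cells = max_cells
        self.seed = seed

    @classmethod
    def from_config(cls, config: CnmfRingConfig) -> "RingCnmf":
        return cls(
            neuron_diameter_px=config.neuron_diameter_px,
            ring_diameter_px=config.ring_diameter_px,
            max_iterations=config.max_iterations,
            warmup_iterations=config.warmup_iterations,
            inner_iterations=config.inner_iterations,
            background_update_every=config.background_update_every,
            min_corr=config.min_corr,
            min_pnr=config.min_pnr,
            convergence_tol=config.convergence_tol,
            merge_threshold=config.merge_threshold,
            min_compactness=config.min_compactness,
            min_trace_snr=config.min_trace_snr,
            n_background_components=config.n_background_components,
            max_cells=config.max_cells,
            seed=config.seed,
        )

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        X = _as_movie(X).astype(np.float32)
        if X.min() < 0:
            raise ValueError("ring-CNMF expects a nonnegative movie")
        T, h, w = X.shape
        d = float(self.neuron_diameter_px)
        ring_d = (float(self.ring_diameter_px)
                  if self.ring_diameter_px is not None else 1.5 * d)

        filtered = self._highpass(X, d)
        seeds, corr_img, pnr_img = self._find_seeds(filtered)
        diagnostics: dict = {
            "n_seeds": len(seeds),
            "correlation_image": corr_img,
            "pnr_image": pnr_img,
            "objective": [],
        }
        if len(seeds) == 0:
            self.footprints_ = np.zeros((0, h, w))
            self.traces_ = np.zeros((0, T))
            self.diagnostics_ = diagnostics
            return self

        A, C, support = self._initialize(filtered, seeds, d, (h, w))
        offsets = _ring_offsets(ring_d)
        Yf = X.reshape(T, -1).T                      # (P, T)
        weights = None
        Bf = np.zeros_like(Yf)
        # global low-rank background U^T V: absorbs the static baseline and
        # field-wide fluctuations (e.g. stimulation-locked out-of-focus
        # rises), which are exactly low-rank; updated before the ring so the
        # ring only models what a local annulus genuinely predicts
        k_bg = int(self.n_background_components)
        rng_bg = np.random.default_rng(self.seed + 11)
        mean_img = Yf.mean(axis=1)
        # mean-image columns with broken symmetry so HALS can de-mix them
        Ub = np.asarray(mean_img[None]
                        * (0.5 + rng_bg.random((k_bg, h * w))) / max(k_bg, 1),
                        dtype=np.float32)
        Vb = np.ones((k_bg, T), dtype=np.float32)
        bg_support = np.ones((k_bg, h * w), dtype=bool)

        step_count = [0]

        def step(A, C, Bf, weights, Ub, Vb):
            AC = A.T @ C                             # (P, T)
            if k_bg:
                Ub, Vb = _hals(Yf - AC - Bf, Ub, Vb, bg_support, n_iter=3)
                G = Ub.T @ Vb
            else:
                G = 0.0
            # refit the ring background every few iterations (it changes
            # slowly and its FFT convolution dominates the per-iteration
            # cost); accept a proposal only if it does not increase the
            # objective at the current (A, C) — this keeps the recorded
            # objective non-increasing while letting the factor updates
            # continue when a proposal overshoots
            if step_count[0] % int(self.background_update_every) == 0:
                B_prop, w_prop = self._ring_background(
                    (Yf - AC - G).T.reshape(T, h, w), offsets, weights
                )
                Bp = B_prop.reshape(T, -1).T
                if _fro(Yf - AC - G - Bp) <= _fro(Yf - AC - G - Bf):
                    Bf, weights = Bp, w_prop
            step_count[0] += 1
            A, C = _hals(Yf - Bf - G, A, C, support,
                         n_iter=int(self.inner_iterations))
            return A, C, Bf, weights, Ub, Vb

        # warm-up with the full candidate set, then consolidate duplicates
        # before the main (recorded) optimization
        for _ in range(int(self.warmup_iterations)):
            A, C, Bf, weights, Ub, Vb = step(A, C, Bf, weights, Ub, Vb)
        A, C, support = self._consolidate(A, C, support, (h, w))
        diagnostics["n_after_consolidation"] = A.shape[0]

        prev_obj = np.inf
        for it in range(int(self.max_iterations)):
            if A.shape[0] == 0:
                break
            A, C, Bf, weights, Ub, Vb = step(A, C, Bf, weights, Ub, Vb)
            obj = _fro(Yf - A.T @ C - Bf - (Ub.T @ Vb if k_bg else 0.0))
            diagnostics["objective"].append(obj)
            if prev_obj < np.inf and (prev_obj - obj) / max(prev_obj, 1e-12) < self.convergence_tol:
                break
            prev_obj = obj

        A, C, support = self._consolidate(A, C, support, (h, w))
        # polish: refit factors on the tightened supports, then prune again
        if A.shape[0]:
            for _ in range(2):
                A, C, Bf, weights, Ub, Vb = step(A, C, Bf, weights, Ub, Vb)
            A, C, support = self._consolidate(A, C, support, (h, w))
        diagnostics["ring_weights"] = weights
        diagnostics["global_background"] = (Ub.reshape(-1, h, w), Vb)
        diagnostics["iterations"] = len(diagnostics["objective"])
        self.footprints_ = A.reshape(-1, h, w)
        self.traces_ = C
        self.diagnostics_ = diagnostics
        return self

    # -- components of the algorithm --------------------------------------

    @staticmethod
    def _highpass(X: np.ndarray, diameter: float) -> np.ndarray:
        """Cell-scale DoG filter used for seeding and initialization."""
        s1 = max(diameter / 8.0, 0.5)
        s2 = diameter / 2.0
        return (ndimage.gaussian_filter(X, (0, s1, s1))
                - ndimage.gaussian_filter(X, (0, s2, s2)))

    @staticmethod
    def _corr_pnr(F: np.ndarray):
        """Local-correlation and peak-to-noise images of a (T, h, w) movie.

        The correlation image averages, over the 8-neighborhood, the temporal
        correlation of each pixel with its neighbors; the noise scale comes
        from frame-to-frame differences (calcium transients are slow relative
        to the frame rate, so first differences isolate the noise).
        """
        mu = F.mean(axis=0)
        Fc = F - mu
        sd = Fc.std(axis=0) + 1e-12
        Z = Fc / sd
        ksum = ndimage.uniform_filter(Z, size=(1, 3, 3), mode="constant") * 9.0
        neigh = ksum - Z
        nn = (ndimage.uniform_filter(np.ones(F.shape[1:]), size=3,
                                     mode="constant") * 9.0 - 1.0)
        corr = (Z * neigh).mean(axis=0) / nn
        noise = (np.median(np.abs(np.diff(F, axis=0)), axis=0)
                 / (0.6745 * np.sqrt(2)) + 1e-12)
        pnr = Fc.max(axis=0) / noise
        return corr, pnr

    def _find_seeds(self, filtered: np.ndarray):
        """Greedy peak picking on local-correlation x peak-to-noise.

        Candidates above both thresholds are taken in descending score order;
        each pick suppresses a quarter-diameter neighborhood so immediately
        adjacent pixels of the same soma are not re-picked.  Residual
        duplicates (filter halos of bright cells) are removed later by the
        consolidation step, not here.
        """
        F = filtered.astype(np.float32, copy=False)
        T, h, w = F.shape
        corr_img, pnr_img = self._corr_pnr(F)
        eligible = (corr_img >= self.min_corr) & (pnr_img >= self.min_pnr)
        score = np.where(eligible, corr_img * pnr_img, -np.inf)
        radius = max(int(round(self.neuron_diameter_px / 4.0)), 1)
        limit = self.max_cells if self.max_cells is not None else h * w
        seeds: list[tuple[int, int]] = []
        while len(seeds) < limit:
            idx = int(np.argmax(score))
            if not np.isfinite(score.flat[idx]):
                break
            cy, cx = divmod(idx, w)
            seeds.append((cy, cx))
            score[max(cy - radius, 0):cy + radius + 1,
                  max(cx - radius, 0):cx + radius + 1] = -np.inf
        return seeds, corr_img, pnr_img

    def _initialize(self, filtered: np.ndarray, seeds, diameter: float,
                    shape: tuple[int, int]):
        """Rank-1 init of each component inside a box around its seed.

        The regression footprint is tapered by a Gaussian window centered on
        the seed so each component starts localized on its own soma; without
        the taper, cells firing synchronously would start with identical
        (joint) footprints and the factorization could never tell them apart.
        """
        h, w = shape
        T = filtered.shape[0]
        half = max(int(round(diameter)), 2)
        n = len(seeds)
        A = np.zeros((n, h * w), dtype=np.float32)
        C = np.zeros((n, T), dtype=np.float32)
        support = np.zeros((n, h * w), dtype=bool)
        flat = filtered.reshape(T, -1)
        yy, xx = np.mgrid[0:h, 0:w]
        taper_sig = max(diameter / 4.0, 1.0)
        for i, (cy, cx) in enumerate(seeds):
            box = np.zeros((h, w), dtype=bool)
            box[max(cy - half, 0):cy + half + 1,
                max(cx - half, 0):cx + half + 1] = True
            support[i] = box.ravel()
            taper = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                           / (2 * taper_sig**2)).ravel()
            c = np.clip(flat[:, cy * w + cx], 0.0, None)
            if c.max() <= 0:
                c = np.ones(T)
            a = np.clip(flat[:, support[i]].T @ c, 0.0, None)
            a *= taper[support[i]]
            norm = np.linalg.norm(a)
            if norm > 0:
                a /= norm
            A[i, support[i]] = a
            C[i] = c
        return A, C, support

    def _ring_background(self, resid: np.ndarray, offsets: np.ndarray,
                         weights: np.ndarray | None):
        """Fit shared nonnegative ring weights and evaluate the background.

        The weights are refit by NNLS on a random-but-fixed subsample of
        pixels and frames; the background is then the residual movie
        convolved with the resulting ring kernel.
        """
        T, h, w = resid.shape
        rng = np.random.default_rng(self.seed + 7)
        r = int(np.ceil(np.abs(offsets).max()))
        inner_h = np.arange(r, h - r)
        inner_w = np.arange(r, w - r)
        if inner_h.size == 0 or inner_w.size == 0:
            return np.zeros_like(resid), np.zeros(len(offsets))
        n_pix = min(600, inner_h.size * inner_w.size)
        n_frm = min(80, T)
        ys = rng.choice(inner_h, size=n_pix)
        xs = rng.choice(inner_w, size=n_pix)
        ts = rng.choice(T, size=n_frm, replace=False)
        sub = resid[ts]                                   # (n_frm, h, w)
        design = np.empty((n_frm * n_pix, len(offsets)))
        for k, (dy, dx) in enumerate(offsets):
            design[:, k] = sub[:, ys + dy, xs + dx].ravel()
        target = np.asarray(sub[:, ys, xs].ravel(), dtype=np.float64)
        try:
            weights, _ = optimize.nnls(design, target, maxiter=10 * len(offsets))
        except RuntimeError:
            weights = (np.zeros(len(offsets)) if weights is None else weights)
        kernel = _offsets_to_kernel(offsets, weights)
        B = signal.fftconvolve(resid, kernel[None].astype(resid.dtype),
                               mode="same", axes=(1, 2))
        # coverage normalization: near the FOV edge part of the ring falls
        # outside the frame, so rescale by the in-bounds weight fraction
        total = kernel.sum()
        if total > 0:
            coverage = signal.fftconvolve(np.ones((h, w)), kernel, mode="same")
            B /= np.maximum(coverage / total, 0.25)[None]
        return np.clip(B, 0.0, None).astype(resid.dtype), weights

    def _compactness(self, A: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Fraction of each footprint's mass within a soma-sized disk
        around its peak; diffuse background-chasing components score low."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = (self.neuron_diameter_px / 2.0) ** 2
        out = np.zeros(A.shape[0])
        for i, a in enumerate(A):
            total = a.sum()
            if total <= 0:
                continue
            py, px = divmod(int(np.argmax(a)), w)
            disk = ((yy - py) ** 2 + (xx - px) ** 2) <= r2
            out[i] = a[disk.ravel()].sum() / total
        return out

    def _consolidate(self, A: np.ndarray, C: np.ndarray,
                     support: np.ndarray, shape: tuple[int, int]):
        """Merge duplicate components and prune non-somatic ones.

        Two components are duplicates of one soma when their footprint peaks
        coincide to within a quarter diameter (the signature of a halo seed,
        or of a residual shard left on an already-claimed cell), or when both
        their footprints and traces agree (cosine and correlation >=
        merge_threshold).  Afterwards, components with empty factors,
        non-compact footprints, or traces without appreciable transients
        (peak-to-noise below min_trace_snr) are dropped.
        """
        h, w = shape
        thr = self.merge_threshold
        dedup_px = max(self.neuron_diameter_px / 4.0, 2.0)
        changed = True
        while changed and A.shape[0] > 1:
            changed = False
            n = A.shape[0]
            norms = np.linalg.norm(A, axis=1) + 1e-12
            G = (A @ A.T) / np.outer(norms, norms)
            Cc = C - C.mean(axis=1, keepdims=True)
            cn = np.linalg.norm(Cc, axis=1) + 1e-12
            R = (Cc @ Cc.T) / np.outer(cn, cn)
            peaks = np.array([divmod(int(np.argmax(a)), w) for a in A])
            energy = (A * A).sum(axis=1) * (C * C).sum(axis=1)
            for i in range(n):
                for j in range(i + 1, n):
                    close = np.hypot(*(peaks[i] - peaks[j])) <= dedup_px
                    if close or (R[i, j] >= thr and G[i, j] >= thr):
                        # absorb the weaker component into the stronger one:
                        # footprints add (amplitude-matched), the dominant
                        # trace is kept
                        a, b = (i, j) if energy[i] >= energy[j] else (j, i)
                        scale = C[b].max() / max(C[a].max(), 1e-12)
                        merged_a = (A[a] + scale * A[b])[None]
                        merged_c = C[a][None]
                        merged_s = (support[i] | support[j])[None]
                        keep_rows = np.delete(np.arange(n), [i, j])
                        A = np.vstack([A[keep_rows], merged_a])
                        C = np.vstack([C[keep_rows], merged_c])
                        support = np.vstack([support[keep_rows], merged_s])
                        changed = True
                        break
                if changed:
                    break
        # spatial cleanup: drop sub-threshold tails and satellite fragments,
        # keeping the connected region around each footprint's peak; the
        # support is tightened to a one-pixel dilation of what remains
        for i in range(A.shape[0]):
            a = A[i].reshape(h, w)
            peak = a.max()
            if peak <= 0:
                continue
            mask = a > 0.02 * peak
            labels, n_lab = ndimage.label(mask)
            if n_lab > 1:
                py, px = np.unravel_index(int(np.argmax(a)), a.shape)
                mask = labels == labels[py, px]
            a = np.where(mask, a, 0.0)
            A[i] = a.ravel()
            support[i] = ndimage.binary_dilation(mask).ravel()
        keep = (A.sum(axis=1) > 0) & (np.abs(C).sum(axis=1) > 0)
        keep &= self._compactness(A, shape) >= self.min_compactness
        keep &= _trace_snr(C) >= self.min_trace_snr
        return A[keep], C[keep], support[keep]


def _trace_snr(C: np.ndarray) -> np.ndarray:
    """Transient amplitude of each trace relative to its fast noise."""
    if C.shape[0] == 0:
        return np.zeros(0)
    noise = (np.median(np.abs(np.diff(C, axis=1)), axis=1)
             / (0.6745 * np.sqrt(2)) + 1e-12)
    return (C.max(axis=1) - np.median(C, axis=1)) / noise


def _fro(R: np.ndarray) -> float:
    """Frobenius norm accumulated in float64."""
    return float(np.sqrt(np.einsum("ij,ij->", R, R, dtype=np.float64)))


def _ring_offsets(ring_diameter: float) -> np.ndarray:
    """Integer (dy, dx) offsets on an annulus of the given diameter."""
    r = ring_diameter / 2.0
    rr = int(np.ceil(r + 1.0))
    ys, xs = np.mgrid[-rr:rr + 1, -rr:rr + 1]
    dist = np.hypot(ys, xs)
    mask = (dist >= r - 0.5) & (dist <= r + 1.0)
    return np.stack([ys[mask], xs[mask]], axis=1)


def _offsets_to_kernel(offsets: np.ndarray, weights: np.ndarray) -> np.ndarray:
    rr = int(np.abs(offsets).max())
    kernel = np.zeros((2 * rr + 1, 2 * rr + 1))
    # convolution flips the kernel; store weights mirrored so that the
    # background at x sums w_k * resid(x + offset_k)
    for (dy, dx), wt in zip(offsets, weights):
        kernel[rr - dy, rr - dx] = wt
    return kernel


def _hals(Y: np.ndarray, A: np.ndarray, C: np.ndarray,
          support: np.ndarray, n_iter: int = 5):
    """Hierarchical ALS updates of ``min ||Y - A^T C||`` with A, C >= 0.

    ``Y`` is (P, T); ``A`` is (n, P), support-masked; ``C`` is (n, T).
    Each sweep decreases the objective for fixed background.
    """
    for _ in range(n_iter):
        # temporal update
        U = A @ Y                       # (n, T)
        V = A @ A.T                     # (n, n)
        for k in range(A.shape[0]):
            denom = V[k, k]
            if denom <= 0:
                continue
            C[k] = np.clip(C[k] + (U[k] - V[k] @ C) / denom, 0.0, None)
        # spatial update
        U = C @ Y.T                     # (n, P)
        V = C @ C.T
        for k in range(A.shape[0]):
            denom = V[k, k]
            if denom <= 0:
                continue
            upd = np.clip(A[k] + (U[k] - V[k] @ A) / denom, 0.0, None)
            upd[~support[k]] = 0.0
            A[k] = upd
    return A, C


# --------------------------------------------------------------------------
# matching against ground truth

@dataclass
class Matching:
    pairs: list[tuple[int, int]]        # (found index, true index)
    similarities: list[float]
    precision: float
    recall: float


def match_components(found_footprints: np.ndarray,
                     true_footprints: np.ndarray,
                     min_similarity: float = 0.5) -> Matching:
    """Optimal one-to-one footprint assignment by cosine similarity.

    The assignment maximizes total cosine similarity (Hungarian algorithm);
    pairs below ``min_similarity`` are discarded.  Precision is matched /
    found, recall is matched / true.
    """
    nf = found_footprints.shape[0]
    nt = true_footprints.shape[0]
    if nf == 0 or nt == 0:
        # no found components -> vacuous precision; no true cells -> vacuous recall
        return Matching([], [], precision=1.0 if nf == 0 else 0.0,
                        recall=1.0 if nt == 0 else 0.0)
    F = found_footprints.reshape(nf, -1)
    G = true_footprints.reshape(nt, -1)
    sim = (F @ G.T) / (
        np.outer(np.linalg.norm(F, axis=1), np.linalg.norm(G, axis=1)) + 1e-12
    )
    rows, cols = linear_sum_assignment(-sim)
    pairs, sims = [], []
    for r, c in zip(rows, cols):
        if sim[r, c] >= min_similarity:
            pairs.append((int(r), int(c)))
            sims.append(float(sim[r, c]))
    return Matching(pairs, sims, precision=len(pairs) / nf,
                    recall=len(pairs) / nt)


# --------------------------------------------------------------------------
# functional wrappers

def extract_roi(movie: np.ndarray, seeds, radius_px: float = 4.0) -> ExtractionResult:
    return RoiExtractor(seeds=seeds, radius_px=radius_px).fit(movie).result_


def extract_pca_ica(movie: np.ndarray, n_components: int, mu: float = 0.5,
                    random_state: int = 0, **kw) -> ExtractionResult:
    est = PcaIcaExtractor(n_components=n_components, mu=mu,
                          random_state=random_state, **kw)
    return est.fit(movie).result_


def extract_cnmf_ring(movie: np.ndarray,
                      config: CnmfRingConfig | None = None,
                      **kw) -> ExtractionResult:
    if config is not None:
        est = RingCnmf.from_config(config)
    else:
        est = RingCnmf(**kw)
    return est.fit(movie).result_
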