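"""Deterministic synthetic fixture bundles for tests and examples.

Each size label fixes a field of view, duration, cell count and seed, so a
bundle regenerates bit-identically.  ``tiny`` runs end-to-end in seconds and
is the default for unit tests; ``bench`` is the full-scale benchmark the
extraction comparison uses.
"""

from __future__ import annotations

from pathlib import Path

from . import io
from .sim import SimConfig, simulate_session

__all__ = ["FIXTURE_SIZES", "fixture_config", "make_fixtures"]

FIXTURE_SIZES: dict[str, dict] = {
    "tiny": dict(fov=(16, 16), n_frames=200, n_cells=3,
                 cell_radius_px=(1.5, 2.5), seed=11),
    "small": dict(fov=(64, 64), n_frames=2000, n_cells=15,
                  cell_radius_px=(3.0, 5.0), seed=12),
    "bench": dict(fov=(100, 100), n_frames=4000, n_cells=30,
                  cell_radius_px=(3.0, 5.0), seed=13),
}


def fixture_config(size: str, **overrides) -> tuple[SimConfig, int]:
    """Return the SimConfig and frame count for a fixture size label."""
    try:
        spec = FIXTURE_SIZES[size]
    except KeyError:
        raise ValueError(
            f"unknown fixture size {size!r}; choose from {sorted(FIXTURE_SIZES)}"
        ) from None
    cfg = SimConfig(
        fov_px=spec["fov"],
        n_cells=spec["n_cells"],
        cell_radius_px=spec["cell_radius_px"],
        seed=spec["seed"],
        **overrides,
    )
    return cfg, spec["n_frames"]


def make_fixtures(size: str, outdir, paradigm: str | None = "awake",
                  **overrides) -> dict[str, Path]:
    """Generate and write one fixture bundle; returns the artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg, n_frames = fixture_config(size, **overrides)
    schedule_kw = {}
    if paradigm == "awake":
        # scale ON/OFF blocks to the fixture duration (4 blocks + margin)
        schedule_kw["block_s"] = n_frames / cfg.frame_rate_hz / 4.5
    elif paradigm == "anesthetized":
        schedule_kw["gap_s"] = max(
            (n_frames / cfg.frame_rate_hz - 10.0) / 9.0 - 10.0, 1.0)
    movie, truth = simulate_session(cfg, paradigm, n_frames, **schedule_kw)
    paths = {
        "movie": outdir / f"{size}_movie.tif",
        "truth": outdir / f"{size}_truth.h5",
        "behavior": outdir / f"{size}_behavior.csv",
        "schedule": outdir / f"{size}_schedule.csv",
    }
    io.write_movie(movie, paths["movie"], frame_rate_hz=cfg.frame_rate_hz)
    io.write_ground_truth(truth, paths["truth"])
    io.write_behavior(truth.behavior, paths["behavior"])
    io.write_schedule(truth.schedule, paths["schedule"])
    return paths
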