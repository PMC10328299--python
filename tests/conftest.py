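import numpy as np
import pytest

from hopmat import FrameSequence, GridSpec, HopSimConfig, make_samples, render_hop


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def sequence_from(records, grid: GridSpec | None = None, n_frames: int | None = None,
                  meta: dict | None = None) -> FrameSequence:
    """Hand-built sparse sequence from (frame, row, col, pressure) tuples."""
    grid = grid or GridSpec()
    samples = make_samples(records)
    if n_frames is None:
        n_frames = int(samples["frame"].max()) + 1 if samples.size else 0
    return FrameSequence(grid=grid, n_frames=n_frames, samples=samples, meta=meta or {})


@pytest.fixture
def clean_hop(rng):
    """A noise-free, deterministic eastbound hop with ground truth."""
    config = HopSimConfig(offload_lambda=0.3, noise_sd_log=0.0, direction=+1)
    return render_hop(config, rng, animal_id="r01", session_id="preop_1", run_id="t1")


def mirror_track(seq: FrameSequence) -> FrameSequence:
    """Reflect the sequence across the track axis (columns reversed)."""
    samples = seq.samples.copy()
    samples["col"] = seq.grid.n_cols - 1 - samples["col"]
    out = seq.with_samples(make_samples(
        (f, r, c, p) for f, r, c, p in
        zip(samples["frame"], samples["row"], samples["col"], samples["pressure"])
    ))
    if "direction_override" in out.meta:
        out.meta["direction_override"] = f"{-int(out.meta['direction_override']):+d}"
    return out
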