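"""Forward simulator of rabbit hops on a pressure-sensing mat.

The generator produces frame sequences with the statistical structure the
analysis pipeline assumes, together with analytic ground truth, so that
every downstream stage — segmentation, load metrics, reference ranges,
timepoint tests — can be exercised and checked against known answers.

Model of one hop
----------------
Each hind limb exerts a half-sine total force over its stance,
``F(t) = F0 * sin(pi * t / T)`` for ``t`` in (0, T), whose analytic impulse
is ``(2/pi) * F0 * T``.  The nominal per-limb peak is half of
``load_factor * body_mass * g`` (default 1.5 x bodyweight across both hind
limbs, a plausible hopping load for a 4 kg rabbit).  Lameness is a
multiplicative offload of the right limb by ``(1 - offload_lambda)``;
run-to-run variation is independent lognormal noise on each limb
(``noise_sd_log``), and each animal carries a fixed baseline left/right
asymmetry ``baseline_asym`` applied as ``exp(+-b)`` to the two limbs.  The
run-level symmetry ratio implied by the model is

    ratio = tanh((ln(1 - lambda) + 2 b + eps_R - eps_L) / 2)

with median ``-lambda / (2 - lambda)``; :func:`recover_lambda` inverts it.

Force is spread over a fixed within-paw weight map and divided by sensor
area to give per-sensor pressures; readings below the device's sensitive
minimum are omitted (a nearly unloaded paw leaves no print), and exceeding
the device maximum is a configuration error unless saturation is requested.
A pair of staggered fore-paw prints lands earlier and behind the hind pair
along the travel axis, which is what lets the pipeline infer the travel
direction from a single hop; the fore prints never overlap the hind prints
in time or space unless a defect is injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mat_io import FrameSequence, GridSpec, make_samples
from .segmentation import SegmentationConfig, binarize, label_contacts

__all__ = [
    "GRAVITY_M_S2",
    "HopSimConfig",
    "SessionSpec",
    "CohortSimConfig",
    "HopTruth",
    "SimulatedCohort",
    "render_hop",
    "inject_defect",
    "simulate_cohort",
    "write_cohort",
    "sample_run_ratio",
    "ratio_from_lambda",
    "recover_lambda",
]

GRAVITY_M_S2 = 9.81

DEFECT_KINDS = ("edge_clipped", "cross_paw_overlap", "hesitation")


class SimConfigError(ValueError):
    """The simulator configuration renders physically invalid pressures."""


@dataclass(frozen=True)
class HopSimConfig:
    """Parameters of a single simulated hop.

    ``baseline_asym`` is the realised per-animal asymmetry (the cohort
    simulator draws it once per animal from N(0, ``baseline_sd``));
    ``direction`` is +1, -1, or 0 for random; ``hind_t0_s`` pins the hind
    landing time (by default it is jittered so the stance phase relative to
    the frame clock varies between runs, as it does on the real device).
    """

    grid: GridSpec = GridSpec()
    body_mass_kg: float = 4.08
    load_factor: float = 1.5
    offload_lambda: float = 0.0
    stance_s: float = 0.25
    hind_paw_shape: tuple[int, int] = (4, 2)
    fore_paw_shape: tuple[int, int] = (2, 2)
    fore_force_fraction: float = 0.35
    fore_stance_s: float = 0.12
    noise_sd_log: float = 0.20
    baseline_sd: float = 0.03
    baseline_asym: float = 0.0
    direction: int = 0
    include_fore: bool = True
    hind_t0_s: float | None = None
    allow_saturation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.offload_lambda <= 1.0:
            raise ValueError("offload_lambda must be in [0, 1]")
        if self.stance_s <= 0:
            raise ValueError("stance_s must be positive")
        if self.direction not in (0, +1, -1):
            raise ValueError("direction must be +1, -1 or 0 (random)")


@dataclass(frozen=True)
class SessionSpec:
    """One measurement day: an offload distribution over the cohort."""

    session_id: str
    lambda_mean: float
    lambda_sd: float = 0.0
    phase: str = "postop"  # "preop" or "postop"


def _default_sessions() -> tuple[SessionSpec, ...]:
    return (
        SessionSpec("preop_1", 0.0, 0.0, "preop"),
        SessionSpec("preop_2", 0.0, 0.0, "preop"),
        SessionSpec("preop_3", 0.0, 0.0, "preop"),
        SessionSpec("week_1", 0.88, 0.08, "postop"),
        SessionSpec("week_12", 0.50, 0.10, "postop"),
    )


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-shaped cohort: 12 animals, 3 preoperative days, follow-ups.

    Visual scores are generated from the true offload: an observer sees
    ``lambda + N(0, observer_sd)`` and grades it through strictly
    increasing thresholds onto the ordinal 0-4 scale.  Defect rates give
    the per-run probability of each QC-violating artifact; the first
    ``min_clean_runs`` runs of every session are kept defect-free so each
    (animal, day) retains evaluable data.
    """

    hop: HopSimConfig = HopSimConfig()
    n_animals: int = 12
    sessions: tuple[SessionSpec, ...] = field(default_factory=_default_sessions)
    runs_per_session: int = 5
    min_clean_runs: int = 2
    score_thresholds: tuple[float, ...] = (0.15, 0.40, 0.70, 0.92)
    observer_sd: float = 0.08
    defect_rates: dict[str, float] = field(
        default_factory=lambda: {
            "edge_clipped": 0.08,
            "cross_paw_overlap": 0.15,
            "hesitation": 0.05,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.defect_rates.values()):
            raise ValueError("defect rates must be probabilities")
        if sum(self.defect_rates.values()) > 1:
            raise ValueError("defect rates must sum to at most 1")
        if list(self.score_thresholds) != sorted(set(self.score_thresholds)):
            raise ValueError("score thresholds must be strictly increasing")
        if self.runs_per_session < self.min_clean_runs:
            raise ValueError("runs_per_session must cover min_clean_runs")


@dataclass(frozen=True)
class HopTruth:
    """Analytic ground truth of one rendered hop."""

    run_id: str
    animal_id: str
    session_id: str
    offload_lambda: float
    baseline_asym: float
    direction: int
    f0_left: float
    f0_right: float
    impulse_left: float
    impulse_right: float
    peak_kpa_left: float
    peak_kpa_right: float
    ratio_force_true: float
    left_row_span: tuple[int, int]
    right_row_span: tuple[int, int]
    defect: str = "none"


@dataclass
class SimulatedCohort:
    """All runs, ground truth and visual scores of one simulated study."""

    runs: list[FrameSequence]
    truth: pd.DataFrame
    scores: pd.DataFrame


def _weight_map(shape: tuple[int, int]) -> np.ndarray:
    """Fixed within-paw pressure distribution: centre loaded, rim lighter."""

    def window(n: int) -> np.ndarray:
        if n == 1:
            return np.ones(1)
        return 1.0 - 0.4 * np.abs(np.linspace(-1.0, 1.0, n))

    w = np.outer(window(shape[0]), window(shape[1]))
    return w / w.sum()


def ratio_from_lambda(lam: float) -> float:
    """Noise-free symmetry ratio implied by a right-limb offload lambda."""
    return -lam / (2.0 - lam)


def recover_lambda(ratio_force: float) -> float:
    """Invert the offload model: lambda_hat = -2 I / (1 - I).

    Defined for ratios in [-1, 1); a ratio of exactly 1 (no load on the
    left limb) has no right-offload interpretation.
    """
    if ratio_force >= 1.0:
        raise ValueError("lambda is undefined for ratio_force >= 1")
    return -2.0 * ratio_force / (1.0 - ratio_force)


def sample_run_ratio(
    rng: np.random.Generator,
    offload_lambda: float,
    baseline_asym: float = 0.0,
    noise_sd_log: float = 0.20,
) -> float:
    """Draw one run-level symmetry ratio from the generator's load model.

    This is the exact distribution of the rendered ratio when both paws
    share the stance clock (they do): the per-limb lognormal factors and
    the offload enter the ratio only through the log load ratio.  Used for
    large replicate studies (type-I error, power) where rendering every
    frame would add nothing.
    """
    if offload_lambda >= 1.0:
        return -1.0
    eps_l, eps_r = rng.normal(0.0, noise_sd_log, size=2)
    log_ratio = math.log1p(-offload_lambda) + 2.0 * baseline_asym + eps_r - eps_l
    return math.tanh(log_ratio / 2.0)


def _paint_paw(
    cells: list,
    limb: str,
    f0: float,
    top_row: int,
    left_col: int,
    weights: np.ndarray,
    t0: float,
    stance: float,
    grid: GridSpec,
) -> None:
    """Append (limb, frame, row, col, pressure_kpa) cells for one paw."""
    if f0 <= 0:
        return
    hz = grid.frame_rate_hz
    k_first = int(math.floor(t0 * hz)) + 1
    k_last = int(math.ceil((t0 + stance) * hz)) - 1
    denom = grid.sensor_area_m2 * 1000.0  # kPa per N on one sensor, inverted
    for k in range(k_first, k_last + 1):
        t = k / hz
        amp = math.sin(math.pi * (t - t0) / stance)
        if amp <= 0:
            continue
        force = f0 * amp
        for (i, j), w in np.ndenumerate(weights):
            p_kpa = force * w / denom
            if p_kpa < grid.p_min_kpa:
                continue
            cells.append((limb, k, top_row + i, left_col + j, p_kpa))


def render_hop(
    config: HopSimConfig,
    rng: np.random.Generator,
    animal_id: str = "a01",
    session_id: str = "s1",
    run_id: str = "r1",
) -> tuple[FrameSequence, HopTruth]:
    """Render one hop as a sparse frame sequence plus analytic ground truth.

    The hind pair lands simultaneously, symmetric about the track
    centreline and strictly interior to the mat's edge ring; the fore pair
    (optional) lands earlier and behind, its two prints staggered in time
    so they never form a spurious simultaneous pair.  Travel runs along
    columns; a hop in the opposite direction is the 180-degree rotation of
    the canonical scene, which keeps the anatomical left paw on the
    animal's left.
    """
    grid = config.grid
    hz = grid.frame_rate_hz
    direction = config.direction
    if direction == 0:
        direction = +1 if rng.random() < 0.5 else -1
    t0h = config.hind_t0_s if config.hind_t0_s is not None else 0.35 + rng.uniform(0.0, 0.1)

    f0_nominal = config.load_factor * config.body_mass_kg * GRAVITY_M_S2 / 2.0
    b = config.baseline_asym
    if config.noise_sd_log > 0:
        eps_l, eps_r = rng.normal(0.0, config.noise_sd_log, size=2)
    else:
        eps_l = eps_r = 0.0
    f0_left = f0_nominal * math.exp(-b + eps_l)
    f0_right = f0_nominal * (1.0 - config.offload_lambda) * math.exp(b + eps_r)

    hr, hc = config.hind_paw_shape
    fr, fc = config.fore_paw_shape
    row_gap = 3
    block = 2 * hr + row_gap
    top_lo, top_hi = 2, grid.n_rows - 2 - block
    if top_hi < top_lo:
        raise SimConfigError("grid too small for the configured hind footprints")
    r_top = int(rng.integers(top_lo, top_hi + 1))
    fore_offset = fc + 4  # columns behind the hind pair
    c_lo = 1 + fore_offset
    c_hi = grid.n_cols - 2 - hc
    if c_hi < c_lo:
        raise SimConfigError("grid too small for the configured track layout")
    c_hind = int(rng.integers(c_lo, c_hi + 1))

    hind_w = _weight_map((hr, hc))
    cells: list = []
    # Canonical scene travels toward +cols; the left limb is the upper
    # (smaller-row) print.
    _paint_paw(cells, "left", f0_left, r_top, c_hind, hind_w, t0h, config.stance_s, grid)
    _paint_paw(
        cells, "right", f0_right, r_top + hr + row_gap, c_hind, hind_w, t0h, config.stance_s, grid
    )
    if config.include_fore:
        fore_w = _weight_map((fr, fc))
        f0_fore = config.fore_force_fraction * config.body_mass_kg * GRAVITY_M_S2 / 2.0
        t0_f1 = t0h - 2 * config.fore_stance_s - 0.05
        t0_f2 = t0_f1 + config.fore_stance_s  # staggered: no shared frames
        c_fore = c_hind - fore_offset
        r_mid = r_top + hr + (row_gap - fr) // 2
        _paint_paw(cells, "fore", f0_fore, r_top + 1, c_fore, fore_w, t0_f1,
                   config.fore_stance_s, grid)
        _paint_paw(cells, "fore", f0_fore, r_mid + fr, c_fore, fore_w, t0_f2,
                   config.fore_stance_s, grid)

    if direction == -1:  # rotate the scene 180 degrees in the mat plane
        cells = [
            (limb, f, grid.n_rows - 1 - r, grid.n_cols - 1 - c, p)
            for limb, f, r, c, p in cells
        ]

    merged: dict[tuple[int, int, int], float] = {}
    limb_rows: dict[str, list[int]] = {"left": [], "right": []}
    for limb, f, r, c, p in cells:
        merged[(f, r, c)] = merged.get((f, r, c), 0.0) + p
        if limb in limb_rows:
            limb_rows[limb].append(r)
    over = [k for k, p in merged.items() if p > grid.p_max_kpa]
    if over:
        if not config.allow_saturation:
            raise SimConfigError(
                f"rendered pressure exceeds p_max={grid.p_max_kpa} kPa at {over[0]}; "
                "set allow_saturation=True to clip"
            )
        for k in over:
            merged[k] = grid.p_max_kpa

    n_frames = (max(f for f, _, _ in merged) + 2) if merged else 0
    seq = FrameSequence(
        grid=grid,
        n_frames=n_frames,
        samples=make_samples((f, r, c, p) for (f, r, c), p in merged.items()),
        meta={"animal": animal_id, "session": session_id, "run": run_id},
    )
    if not config.include_fore:
        # A lone hind pair has no temporal structure to orient by.
        seq.meta["direction_override"] = f"{direction:+d}"

    impulse_left = (2.0 / math.pi) * f0_left * config.stance_s
    impulse_right = (2.0 / math.pi) * f0_right * config.stance_s
    total = impulse_left + impulse_right
    w_max = float(hind_w.max())
    kpa_per_n = 1.0 / (grid.sensor_area_m2 * 1000.0)

    def _span(rows: list[int]) -> tuple[int, int]:
        return (min(rows), max(rows)) if rows else (-1, -1)

    truth = HopTruth(
        run_id=run_id,
        animal_id=animal_id,
        session_id=session_id,
        offload_lambda=config.offload_lambda,
        baseline_asym=b,
        direction=direction,
        f0_left=f0_left,
        f0_right=f0_right,
        impulse_left=impulse_left,
        impulse_right=impulse_right,
        peak_kpa_left=f0_left * w_max * kpa_per_n,
        peak_kpa_right=f0_right * w_max * kpa_per_n,
        ratio_force_true=(impulse_right - impulse_left) / total if total > 0 else float("nan"),
        left_row_span=_span(limb_rows["left"]),
        right_row_span=_span(limb_rows["right"]),
    )
    return seq, truth


def _hind_contacts(seq: FrameSequence):
    contacts = label_contacts(binarize(seq), seq.grid)
    contacts.sort(key=lambda c: -c.area_sensors)
    return contacts[:2], contacts


def _rebuild(seq: FrameSequence, cell_map: dict, n_frames: int | None = None) -> FrameSequence:
    samples = make_samples((f, r, c, p) for (f, r, c), p in cell_map.items())
    return seq.with_samples(samples, n_frames=n_frames)


def inject_defect(
    seq: FrameSequence,
    kind: str,
    rng: np.random.Generator,
    seg_config: SegmentationConfig = SegmentationConfig(),
) -> FrameSequence:
    """Corrupt a clean run so that QC must reject it for the given reason.

    ``edge_clipped`` shifts one hind print onto the outermost sensor ring
    (part of the paw lands off the mat); ``cross_paw_overlap`` paints a
    merged fore-and-hind smear wider than any single paw across the hind
    stance, the classic unresolvable-ROI artifact; ``hesitation`` prolongs
    both hind stances beyond the steady-traversal limit.
    """
    if kind not in DEFECT_KINDS:
        raise ValueError(f"unknown defect kind {kind!r}; expected one of {DEFECT_KINDS}")
    hinds, _ = _hind_contacts(seq)
    if not hinds:
        raise ValueError("sequence has no contacts to corrupt")
    cell_map = {
        (int(f), int(r), int(c)): float(p)
        for f, r, c, p in zip(
            seq.samples["frame"], seq.samples["row"], seq.samples["col"], seq.samples["pressure"]
        )
    }
    out_frames = seq.n_frames

    if kind == "edge_clipped":
        target = min(hinds, key=lambda c: int(c.samples["row"].min()))
        shift = int(target.samples["row"].min())
        moved = {}
        target_cells = target.sensor_frames()
        for (f, r, c), p in cell_map.items():
            if (f, r, c) in target_cells:
                moved[(f, r - shift, c)] = moved.get((f, r - shift, c), 0.0) + p
            else:
                moved[(f, r, c)] = moved.get((f, r, c), 0.0) + p
        cell_map = moved

    elif kind == "cross_paw_overlap":
        rows = np.concatenate([h.samples["row"] for h in hinds])
        cols = np.concatenate([h.samples["col"] for h in hinds])
        frames = np.concatenate([h.samples["frame"] for h in hinds])
        uniq, counts = np.unique(frames, return_counts=True)
        peak_frames = uniq[np.argsort(counts)][-2:]
        r_lo = max(1, int(rows.min()) - 1)
        r_hi = min(seq.grid.n_rows - 2, int(rows.max()) + 1)
        c_lo = max(1, int(cols.min()) - 2)
        c_hi = min(seq.grid.n_cols - 2, int(cols.min()) + 4)
        smear_kpa = max(15.0, seq.grid.p_min_kpa * 2)
        for f in peak_frames:
            for r in range(r_lo, r_hi + 1):
                for c in range(c_lo, c_hi + 1):
                    cell_map.setdefault((int(f), r, c), smear_kpa)

    else:  # hesitation
        target_span = seg_config.max_stance_frames + 2
        for h in hinds:
            first, last = h.frame_span
            extra = target_span - (last - first + 1)
            tail = h.samples[h.samples["frame"] == last]
            for i in range(1, extra + 1):
                for rec in tail:
                    key = (int(last + i), int(rec["row"]), int(rec["col"]))
                    cell_map.setdefault(key, float(rec["pressure"]) * 0.9**i)
                out_frames = max(out_frames, last + i + 2)

    out = _rebuild(seq, cell_map, n_frames=out_frames)
    out.meta["defect"] = kind
    return out


def _draw_lambda(rng: np.random.Generator, spec: SessionSpec) -> float:
    if spec.lambda_sd <= 0:
        return float(spec.lambda_mean)
    return float(np.clip(rng.normal(spec.lambda_mean, spec.lambda_sd), 0.0, 1.0))


def _observe_score(rng: np.random.Generator, lam: float, config: CohortSimConfig) -> int:
    seen = lam + rng.normal(0.0, config.observer_sd)
    return int(np.searchsorted(np.asarray(config.score_thresholds), seen, side="left"))


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Simulate the full study: animals x sessions x runs, scores, truth.

    Reproducible: the same config (including seed) yields byte-identical
    output.  Per animal, a baseline asymmetry is drawn once; per
    (animal, session), an offload lambda from the session's distribution
    and one observer score; per run, limb noise, geometry, travel direction
    and (beyond the guaranteed clean runs) a possible injected defect.
    """
    rng = np.random.default_rng(config.seed)
    defect_kinds = list(config.defect_rates)
    defect_probs = np.array([config.defect_rates[k] for k in defect_kinds])
    runs: list[FrameSequence] = []
    truth_rows: list[dict] = []
    score_rows: list[dict] = []
    for a in range(config.n_animals):
        animal_id = f"r{a + 1:02d}"
        baseline = float(rng.normal(0.0, config.hop.baseline_sd))
        for spec in config.sessions:
            lam = _draw_lambda(rng, spec)
            score_rows.append(
                {
                    "animal_id": animal_id,
                    "session_id": spec.session_id,
                    "score": _observe_score(rng, lam, config),
                }
            )
            for k in range(config.runs_per_session):
                run_id = f"{animal_id}_{spec.session_id}_k{k + 1}"
                hop = replace(
                    config.hop, offload_lambda=lam, baseline_asym=baseline
                )
                seq, truth = render_hop(
                    hop, rng, animal_id=animal_id, session_id=spec.session_id, run_id=run_id
                )
                defect = "none"
                if k >= config.min_clean_runs and defect_kinds:
                    u = rng.random()
                    cum = np.cumsum(defect_probs)
                    idx = int(np.searchsorted(cum, u, side="right"))
                    if idx < len(defect_kinds):
                        defect = defect_kinds[idx]
                        seq = inject_defect(seq, defect, rng)
                runs.append(seq)
                row = truth.__dict__.copy()
                row["defect"] = defect
                row["left_row_min"], row["left_row_max"] = row.pop("left_row_span")
                row["right_row_min"], row["right_row_max"] = row.pop("right_row_span")
                truth_rows.append(row)
    return SimulatedCohort(
        runs=runs, truth=pd.DataFrame(truth_rows), scores=pd.DataFrame(score_rows)
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> pd.DataFrame:
    """Write a simulated cohort to disk: PMAT-CSV runs plus CSV tables.

    Returns the run metadata table (run_id, animal_id, session_id, path).
    """
    from pathlib import Path

    from .mat_io import write_frame_sequence

    outdir = Path(outdir)
    runs_dir = outdir / "runs"
    runs_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for seq in cohort.runs:
        run_id = seq.meta["run"]
        path = runs_dir / f"{run_id}.pmat.csv"
        write_frame_sequence(seq, path)
        meta_rows.append(
            {
                "run_id": run_id,
                "animal_id": seq.meta["animal"],
                "session_id": seq.meta["session"],
                "path": str(path.relative_to(outdir)),
            }
        )
    metadata = pd.DataFrame(meta_rows)
    metadata.to_csv(outdir / "metadata.csv", index=False)
    cohort.scores.to_csv(outdir / "scores.csv", index=False)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    return metadata
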