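"""Spatiotemporal paw-contact segmentation and run quality control.

A paw contact is one maximal connected component of above-threshold sensor
readings in the 3-D lattice (frame, row, col).  Default connectivity is
26-connected (Chebyshev distance <= 1 in all three coordinates): at 10 Hz a
rolling paw can shift a full sensor between consecutive frames, so purely
face-wise (6-connected) components would fragment real stances.

After labeling, the hind-limb pair of a hop is identified geometrically:
the two contacts that overlap in time, are separated across the track axis,
and jointly cover the largest area.  Left/right follows a fixed convention
— with row 0 the top sensor row seen from above and travel toward
increasing columns, the animal's left hind paw is the contact with the
smaller row centroid; the assignment mirrors when the animal travels the
other way.

Run acceptance mirrors the protocol criteria a measurement must satisfy:
both hind paws entirely on the mat (no contact on the outermost sensor
ring), no unresolvable overlap between paws in a single frame, and no
hesitation on the mat (proxied here by a maximum hind-stance duration,
since the original steadiness judgement relied on video).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .mat_io import SAMPLE_DTYPE, FrameSequence, GridSpec

__all__ = [
    "HIND_LEFT",
    "HIND_RIGHT",
    "FORE",
    "UNKNOWN",
    "QC_REASONS",
    "SegmentationConfig",
    "Contact",
    "HopPair",
    "RunQC",
    "AmbiguousDirectionError",
    "binarize",
    "label_contacts",
    "infer_direction",
    "classify_paws",
    "qc_run",
    "segment_run",
    "temporal_overlap_fraction",
]

HIND_LEFT = "hind_left"
HIND_RIGHT = "hind_right"
FORE = "fore"
UNKNOWN = "unknown"

#: QC rejection reasons, in reporting order.
QC_REASONS = ("edge_clipped", "cross_paw_overlap", "no_hind_pair", "hesitation", "saturation")


class AmbiguousDirectionError(ValueError):
    """Travel direction cannot be inferred from the contacts.

    Set ``direction_override`` (+1 or -1) in the run metadata to resolve.
    """


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of segmentation, pairing and QC.

    threshold_kpa
        Activation threshold; ``None`` means the grid's sensitive minimum
        (the device cannot resolve pressure below it anyway).
    connectivity
        26 (Chebyshev) or 6 (face-wise) neighborhood in (frame, row, col).
    min_pair_overlap
        Minimum temporal overlap fraction (relative to the shorter stance)
        for two contacts to count as a simultaneous hind pair.
    max_single_paw_area
        Per-frame footprint (sensor count) above which a component must be
        several merged paws and the run is unresolvable.
    max_stance_frames
        Longest credible hind stance; longer means the animal hesitated.
    track_axis
        Axis of travel across the mat: "cols" or "rows".
    direction_slope_tol
        Minimum |slope| (sensors per frame) for direction inference.
    """

    threshold_kpa: float | None = None
    connectivity: int = 26
    min_pair_overlap: float = 0.5
    max_single_paw_area: int = 40
    max_stance_frames: int = 6
    track_axis: str = "cols"
    direction_slope_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.track_axis not in ("rows", "cols"):
            raise ValueError("track_axis must be 'rows' or 'cols'")
        if not 0 < self.min_pair_overlap <= 1:
            raise ValueError("min_pair_overlap must be in (0, 1]")

    def resolve_threshold(self, grid: GridSpec) -> float:
        return grid.p_min_kpa if self.threshold_kpa is None else self.threshold_kpa


@dataclass
class Contact:
    """One spatiotemporally connected paw print."""

    samples: np.ndarray
    label: str = UNKNOWN
    centroid_rc: tuple[float, float] = (np.nan, np.nan)
    frame_span: tuple[int, int] = (0, 0)
    area_sensors: int = 0
    touches_edge: bool = False

    @classmethod
    def from_samples(cls, samples: np.ndarray, grid: GridSpec, label: str = UNKNOWN) -> "Contact":
        if samples.size == 0:
            raise ValueError("a contact needs at least one sample")
        w = samples["pressure"]
        centroid = (
            float(np.average(samples["row"], weights=w)),
            float(np.average(samples["col"], weights=w)),
        )
        span = (int(samples["frame"].min()), int(samples["frame"].max()))
        area = int(np.unique(np.stack([samples["row"], samples["col"]], axis=1), axis=0).shape[0])
        on_edge = bool(
            np.any(samples["row"] == 0)
            or np.any(samples["row"] == grid.n_rows - 1)
            or np.any(samples["col"] == 0)
            or np.any(samples["col"] == grid.n_cols - 1)
        )
        return cls(
            samples=samples,
            label=label,
            centroid_rc=centroid,
            frame_span=span,
            area_sensors=area,
            touches_edge=on_edge,
        )

    @property
    def n_stance_frames(self) -> int:
        first, last = self.frame_span
        return last - first + 1

    @property
    def mid_frame(self) -> float:
        first, last = self.frame_span
        return (first + last) / 2.0

    def max_frame_footprint(self) -> int:
        """Largest number of distinct sensors active in any single frame."""
        frames = self.samples["frame"]
        return int(max(np.sum(frames == f) for f in np.unique(frames)))

    def sensor_frames(self) -> set[tuple[int, int, int]]:
        return {(int(f), int(r), int(c)) for f, r, c in
                zip(self.samples["frame"], self.samples["row"], self.samples["col"])}

    def relabeled(self, label: str) -> "Contact":
        return replace(self, label=label)


@dataclass
class HopPair:
    """The two near-simultaneous hind-paw contacts of one hop."""

    left: Contact
    right: Contact
    temporal_overlap_fraction: float

    def __post_init__(self) -> None:
        if self.left.label != HIND_LEFT or self.right.label != HIND_RIGHT:
            raise ValueError("HopPair requires hind_left / hind_right labeled contacts")


@dataclass
class RunQC:
    """Acceptance verdict for one run."""

    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accepted != (not self.reasons):
            raise ValueError("accepted must be True exactly when reasons is empty")


def binarize(seq: FrameSequence, threshold_kpa: float | None = None) -> np.ndarray:
    """Return the samples at or above the activation threshold.

    The threshold defaults to the grid's sensitive minimum and is inclusive.
    """
    thr = seq.grid.p_min_kpa if threshold_kpa is None else threshold_kpa
    if thr <= 0:
        raise ValueError("threshold_kpa must be positive")
    return seq.samples[seq.samples["pressure"] >= thr]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    return ndimage.generate_binary_structure(3, 1)


def label_contacts(
    active: np.ndarray, grid: GridSpec, connectivity: int = 26
) -> list[Contact]:
    """Partition active samples into maximal connected components.

    Components are connected in the (frame, row, col) lattice under the
    chosen neighborhood and returned as unlabeled contacts in a
    deterministic order: by first frame, then centroid column, then
    centroid row.
    """
    if active.size == 0:
        return []
    f0 = int(active["frame"].min())
    nf = int(active["frame"].max()) - f0 + 1
    mask = np.zeros((nf, grid.n_rows, grid.n_cols), dtype=bool)
    mask[active["frame"] - f0, active["row"], active["col"]] = True
    labels, n_comp = ndimage.label(mask, structure=_structure(connectivity))
    comp_of_sample = labels[active["frame"] - f0, active["row"], active["col"]]
    contacts = [
        Contact.from_samples(np.sort(active[comp_of_sample == k],
                                     order=["frame", "row", "col"]), grid)
        for k in range(1, n_comp + 1)
    ]
    contacts.sort(key=lambda c: (c.frame_span[0], c.centroid_rc[1], c.centroid_rc[0]))
    return contacts


def _track_coord(contact: Contact, track_axis: str) -> float:
    return contact.centroid_rc[1] if track_axis == "cols" else contact.centroid_rc[0]


def infer_direction(
    contacts: list[Contact],
    track_axis: str = "cols",
    override: int | None = None,
    slope_tol: float = 0.05,
) -> int:
    """Infer the travel direction along the track axis.

    Returns +1 if the animal moves toward increasing track coordinate, -1
    otherwise.  A metadata override always wins.  With two or more temporal
    clusters the sign comes from regressing contact-centroid track position
    on contact mid-frame; with a single cluster, from the within-stance
    drift of the pooled pressure centroid.  If neither slope clears
    ``slope_tol`` an :class:`AmbiguousDirectionError` is raised.
    """
    if override is not None:
        if override not in (+1, -1):
            raise ValueError("direction override must be +1 or -1")
        return override
    if not contacts:
        raise ValueError("infer_direction needs at least one contact")

    mids = np.array([c.mid_frame for c in contacts], dtype=float)
    coords = np.array([_track_coord(c, track_axis) for c in contacts], dtype=float)
    if len(contacts) >= 2 and np.ptp(mids) > 0:
        slope = np.polyfit(mids, coords, 1)[0]
        if abs(slope) >= slope_tol:
            return +1 if slope > 0 else -1

    # Single temporal cluster: pooled per-frame pressure centroid drift.
    pooled = np.concatenate([c.samples for c in contacts])
    frames = np.unique(pooled["frame"])
    if len(frames) >= 2:
        axis_field = "col" if track_axis == "cols" else "row"
        per_frame = np.array(
            [
                np.average(
                    pooled[axis_field][pooled["frame"] == f],
                    weights=pooled["pressure"][pooled["frame"] == f],
                )
                for f in frames
            ]
        )
        slope = np.polyfit(frames.astype(float), per_frame, 1)[0]
        if abs(slope) >= slope_tol:
            return +1 if slope > 0 else -1
    raise AmbiguousDirectionError(
        "travel direction is ambiguous; set meta key 'direction_override' to +1 or -1"
    )


def temporal_overlap_fraction(a: Contact, b: Contact) -> float:
    """Shared stance frames relative to the shorter of the two stances."""
    lo = max(a.frame_span[0], b.frame_span[0])
    hi = min(a.frame_span[1], b.frame_span[1])
    shared = max(0, hi - lo + 1)
    return shared / min(a.n_stance_frames, b.n_stance_frames)


def _cross_coord(contact: Contact, track_axis: str) -> float:
    return contact.centroid_rc[0] if track_axis == "cols" else contact.centroid_rc[1]


def classify_paws(
    contacts: list[Contact],
    direction: int,
    grid: GridSpec,
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[list[Contact], HopPair | None]:
    """Label contacts as hind_left / hind_right / fore / unknown.

    The hind pair is the pair of contacts with temporal overlap of at least
    ``min_pair_overlap``, cross-track centroid separation of at least one
    sensor, and the largest combined area (ties broken toward the earliest
    pair).  Left vs. right follows the viewing convention: traveling toward
    +cols with row 0 at the top, the smaller row centroid is the left hind
    paw; the assignment mirrors for the opposite direction (and rotates
    accordingly when the track runs along rows).  Remaining contacts are
    fore paws if they are smaller than both hinds and lie temporally clear
    of the hind stance, otherwise unknown.  Absence of a pair is not an
    error — it is reported downstream by :func:`qc_run`.
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    best: tuple | None = None
    for i in range(len(contacts)):
        for j in range(i + 1, len(contacts)):
            a, b = contacts[i], contacts[j]
            overlap = temporal_overlap_fraction(a, b)
            if overlap < config.min_pair_overlap:
                continue
            if abs(_cross_coord(a, config.track_axis) - _cross_coord(b, config.track_axis)) < 1.0:
                continue
            combined = a.area_sensors + b.area_sensors
            first = min(a.frame_span[0], b.frame_span[0])
            key = (-combined, first)
            if best is None or key < best[0]:
                best = (key, i, j, overlap)

    labeled = list(contacts)
    pair: HopPair | None = None
    if best is not None:
        _, i, j, overlap = best
        a, b = contacts[i], contacts[j]
        # Animal's left side: toward smaller rows when heading +cols (row 0
        # at top), toward larger rows heading -cols; toward larger cols when
        # heading +rows, smaller cols heading -rows.
        ca, cb = _cross_coord(a, config.track_axis), _cross_coord(b, config.track_axis)
        if config.track_axis == "cols":
            a_is_left = (ca < cb) if direction == +1 else (ca > cb)
        else:
            a_is_left = (ca > cb) if direction == +1 else (ca < cb)
        left, right = (a, b) if a_is_left else (b, a)
        left, right = left.relabeled(HIND_LEFT), right.relabeled(HIND_RIGHT)
        labeled[i] = left if a_is_left else right
        labeled[j] = right if a_is_left else left
        pair = HopPair(left=left, right=right, temporal_overlap_fraction=overlap)
        hind_first = min(left.frame_span[0], right.frame_span[0])
        hind_last = max(left.frame_span[1], right.frame_span[1])
        min_hind_area = min(left.area_sensors, right.area_sensors)
        for k, c in enumerate(labeled):
            if k in (i, j):
                continue
            clear_of_stance = c.frame_span[1] < hind_first or c.frame_span[0] > hind_last
            if c.area_sensors < min_hind_area and clear_of_stance:
                labeled[k] = c.relabeled(FORE)
            else:
                labeled[k] = c.relabeled(UNKNOWN)
    return labeled, pair


def qc_run(
    contacts: list[Contact],
    pair: HopPair | None,
    grid: GridSpec,
    config: SegmentationConfig = SegmentationConfig(),
) -> RunQC:
    """Apply the run-acceptance criteria and report every violated rule.

    Reasons (in order): ``edge_clipped`` — a hind contact reaches the
    outermost sensor ring, so part of the load fell off the mat;
    ``cross_paw_overlap`` — a component's single-frame footprint exceeds
    ``max_single_paw_area`` (merged paws cannot be attributed), or a fore
    contact shares a sensor-frame with a hind contact; ``no_hind_pair`` —
    no simultaneous hind pair was found; ``hesitation`` — a hind stance
    outlasts ``max_stance_frames``; ``saturation`` — a hind sensor reading
    at the device ceiling, so the true pressure is unknown.
    """
    reasons: list[str] = []
    if pair is not None and (pair.left.touches_edge or pair.right.touches_edge):
        reasons.append("edge_clipped")

    overlap = any(c.max_frame_footprint() > config.max_single_paw_area for c in contacts)
    if not overlap and pair is not None:
        hind_cells = pair.left.sensor_frames() | pair.right.sensor_frames()
        overlap = any(
            c.label == FORE and c.sensor_frames() & hind_cells for c in contacts
        )
    if overlap:
        reasons.append("cross_paw_overlap")

    if pair is None:
        reasons.append("no_hind_pair")
    else:
        if max(pair.left.n_stance_frames, pair.right.n_stance_frames) > config.max_stance_frames:
            reasons.append("hesitation")
        hind = np.concatenate([pair.left.samples, pair.right.samples])
        if np.any(hind["pressure"] >= grid.p_max_kpa):
            reasons.append("saturation")
    return RunQC(accepted=not reasons, reasons=reasons)


def segment_run(
    seq: FrameSequence, config: SegmentationConfig = SegmentationConfig()
) -> tuple[list[Contact], HopPair | None, RunQC, int | None]:
    """Full segmentation of one run: threshold, label, orient, pair, QC.

    Returns (labeled contacts, hind pair or None, QC verdict, direction or
    None).  An unresolvable travel direction is reported through the QC
    verdict as ``no_hind_pair`` only if no contacts exist; otherwise the
    :class:`AmbiguousDirectionError` propagates so the caller can supply an
    override.
    """
    active = binarize(seq, config.resolve_threshold(seq.grid))
    contacts = label_contacts(active, seq.grid, config.connectivity)
    if not contacts:
        return [], None, RunQC(accepted=False, reasons=["no_hind_pair"]), None
    direction = infer_direction(
        contacts,
        track_axis=config.track_axis,
        override=seq.direction_override,
        slope_tol=config.direction_slope_tol,
    )
    labeled, pair = classify_paws(contacts, direction, seq.grid, config)
    qc = qc_run(labeled, pair, seq.grid, config)
    return labeled, pair, qc, direction
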