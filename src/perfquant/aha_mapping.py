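"""AHA segmentation of the myocardium and coronary-territory scoring.

Pixels are assigned to the standard AHA segments (6 basal, 6 mid-cavity,
4 apical; the apical cap, segment 17, is not measurable with at most three
short-axis slices and is omitted) using the right-ventricular insertion
points.  Segments map to the three coronary territories via the classical
lookup, and the territory score is the mean of that territory's two lowest
segment means — a lower-tail statistic that is robust to focal sparing.

Angles are measured at the LV centroid, counterclockwise in image
coordinates with the patient-anterior direction up (12 o'clock = 0 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .kinetics import MBFMap

__all__ = [
    "TERRITORY_SEGMENTS",
    "SliceInsertion",
    "SegmentModel",
    "TerritoryResult",
    "pixel_angles",
    "detect_insertion_points",
    "compute_segment_labels",
    "build_segment_model",
    "segment_means",
    "territory_mbf",
]

#: Classical AHA segment -> coronary territory lookup (configurable by
#: passing an alternative mapping to :func:`territory_mbf`).
TERRITORY_SEGMENTS: dict[str, frozenset[int]] = {
    "LAD": frozenset({1, 2, 7, 8, 13, 14}),
    "RCA": frozenset({3, 4, 9, 10, 15}),
    "LCx": frozenset({5, 6, 11, 12, 16}),
}

_SLICE_BASE = {"basal": 1, "mid": 7, "apical": 13}


@dataclass(frozen=True)
class SliceInsertion:
    """RV insertion points of one slice, as (row, col) pixel coordinates."""

    anterior: tuple[float, float]
    inferior: tuple[float, float]
    anterior_deg: float
    inferior_deg: float


@dataclass
class SegmentModel:
    """Per-pixel AHA segment IDs (0 outside the myocardium) for all slices."""

    segment_label_map: np.ndarray  # (rows, cols, slices) int
    insertion_points: dict[str, SliceInsertion]
    centroids: dict[str, tuple[float, float]]
    slice_labels: Sequence[str]


@dataclass
class TerritoryResult:
    territory: str
    segment_means: dict[int, float]
    territory_mbf: float
    n_segments_used: int = 2


def pixel_angles(
    rows: np.ndarray, cols: np.ndarray, centroid: tuple[float, float]
) -> np.ndarray:
    """Angle in degrees, counterclockwise from 12 o'clock, in [0, 360)."""
    dr = np.asarray(rows, dtype=float) - centroid[0]
    dc = np.asarray(cols, dtype=float) - centroid[1]
    return np.degrees(np.arctan2(-dc, -dr)) % 360.0


def _mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())


def _arc_endpoints(angles: np.ndarray) -> tuple[float, float]:
    """End angles of a contiguous circular arc given its member angles.

    The largest angular gap between consecutive sorted angles separates the
    outside of the arc; the arc runs counterclockwise from the angle just
    after that gap to the angle just before it.
    """
    a = np.sort(np.unique(angles))
    if a.size == 1:
        return float(a[0]), float(a[0])
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    i = int(np.argmax(gaps))
    start = a[(i + 1) % a.size]
    end = a[i]
    return float(start), float(end)


def detect_insertion_points(
    myocardial_mask: np.ndarray, rv_mask: np.ndarray
) -> SliceInsertion:
    """Locate the anterior and inferior RV insertion points on one slice.

    The RV mask is dilated and intersected with the myocardium to find the
    contact arc along the epicardial contour; the two arc ends are the
    insertion points.  The anterior point is the end met first going
    counterclockwise from the LV centroid's 12 o'clock.
    """
    myo = np.asarray(myocardial_mask, dtype=bool)
    rv = np.asarray(rv_mask, dtype=bool)
    if myo.shape != rv.shape:
        raise ValueError("masks must share a grid")
    if not rv.any():
        raise ValueError("insertion-point detection failed: RV mask is empty")
    if not myo.any():
        raise ValueError("insertion-point detection failed: myocardial mask is empty")

    contact = ndimage.binary_dilation(rv, iterations=1) & myo
    if not contact.any():  # allow a 1-pixel gap between RV and epicardium
        contact = ndimage.binary_dilation(rv, iterations=2) & myo
    if not contact.any():
        raise ValueError(
            "insertion-point detection failed: RV mask is not adjacent to the myocardium"
        )
    centroid = _mask_centroid(myo)
    rr, cc = np.nonzero(contact)
    angles = pixel_angles(rr, cc, centroid)
    start, end = _arc_endpoints(angles)
    anterior_deg, inferior_deg = min(start, end), max(start, end)

    def nearest_pixel(target: float) -> tuple[float, float]:
        diff = np.abs((angles - target + 180.0) % 360.0 - 180.0)
        k = int(np.argmin(diff))
        return float(rr[k]), float(cc[k])

    return SliceInsertion(
        anterior=nearest_pixel(anterior_deg),
        inferior=nearest_pixel(inferior_deg),
        anterior_deg=anterior_deg,
        inferior_deg=inferior_deg,
    )


def compute_segment_labels(
    myocardial_mask: np.ndarray,
    insertion: SliceInsertion | float,
    slice_label: str,
    centroid: tuple[float, float] | None = None,
) -> np.ndarray:
    """AHA segment label map for one slice.

    Basal and mid slices use six equal 60-deg sectors anchored at the
    anterior insertion point, numbered counterclockwise (anterior,
    anteroseptal, inferoseptal, inferior, inferolateral, anterolateral).
    Apical slices use four 90-deg sectors whose anchor is rotated by 45 deg
    so the sector centres fall on anterior / septal / inferior / lateral.
    Pixels exactly on a boundary go to the counterclockwise (higher-angle)
    sector.  ``insertion`` may be a :class:`SliceInsertion` or the anterior
    insertion angle in degrees.
    """
    if slice_label not in _SLICE_BASE:
        raise ValueError(f"unknown slice label {slice_label!r}")
    myo = np.asarray(myocardial_mask, dtype=bool)
    if not myo.any():
        raise ValueError("empty myocardial mask")
    if centroid is None:
        centroid = _mask_centroid(myo)

    if isinstance(insertion, SliceInsertion):
        anchor = float(
            pixel_angles(
                np.array([insertion.anterior[0]]),
                np.array([insertion.anterior[1]]),
                centroid,
            )[0]
        )
    else:
        anchor = float(insertion) % 360.0

    rr, cc = np.nonzero(myo)
    angles = pixel_angles(rr, cc, centroid)
    labels = np.zeros(myo.shape, dtype=np.int16)
    base = _SLICE_BASE[slice_label]
    if slice_label in ("basal", "mid"):
        sector = np.floor(((angles - anchor) % 360.0) / 60.0).astype(int)
        sector = np.minimum(sector, 5)
        labels[rr, cc] = base + sector
    else:
        sector = np.floor(((angles - anchor + 45.0) % 360.0) / 90.0).astype(int)
        sector = np.minimum(sector, 3)
        labels[rr, cc] = base + sector
    return labels


def build_segment_model(
    myocardial_mask: np.ndarray,
    rv_mask: np.ndarray,
    slice_labels: Sequence[str],
) -> SegmentModel:
    """Detect insertion points and label every slice of a study."""
    myo = np.asarray(myocardial_mask, dtype=bool)
    rv = np.asarray(rv_mask, dtype=bool)
    label_map = np.zeros(myo.shape, dtype=np.int16)
    insertions: dict[str, SliceInsertion] = {}
    centroids: dict[str, tuple[float, float]] = {}
    for s, lab in enumerate(slice_labels):
        ins = detect_insertion_points(myo[:, :, s], rv[:, :, s])
        centroid = _mask_centroid(myo[:, :, s])
        label_map[:, :, s] = compute_segment_labels(myo[:, :, s], ins, lab, centroid)
        insertions[lab] = ins
        centroids[lab] = centroid
    return SegmentModel(
        segment_label_map=label_map,
        insertion_points=insertions,
        centroids=centroids,
        slice_labels=list(slice_labels),
    )


def segment_means(mbf_map: MBFMap, segment_model: SegmentModel) -> dict[int, float]:
    """Arithmetic mean of converged-pixel MBF per AHA segment.

    Segments with no converged pixel are absent from the result (a flag, not
    an error).
    """
    labels = segment_model.segment_label_map
    if labels.shape != mbf_map.values.shape:
        raise ValueError("segment model and MBF map must share a grid")
    good = mbf_map.mask & mbf_map.quality & np.isfinite(mbf_map.values)
    out: dict[int, float] = {}
    for seg in np.unique(labels[labels > 0]):
        sel = good & (labels == seg)
        if sel.any():
            out[int(seg)] = float(mbf_map.values[sel].mean())
    return out


def territory_mbf(
    seg_means: Mapping[int, float],
    territory: str,
    lookup: Mapping[str, frozenset[int]] | None = None,
) -> TerritoryResult:
    """Territory MBF = mean of the two lowest segment means of the territory."""
    table = lookup or TERRITORY_SEGMENTS
    if territory not in table:
        raise ValueError(f"unknown territory {territory!r}")
    present = {seg: m for seg, m in seg_means.items() if seg in table[territory]}
    if len(present) < 2:
        raise ValueError(
            f"territory {territory}: need at least 2 segments with data, "
            f"found {len(present)}"
        )
    lowest_two = sorted(present.values())[:2]
    return TerritoryResult(
        territory=territory,
        segment_means=present,
        territory_mbf=float(np.mean(lowest_two)),
        n_segments_used=2,
    )
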