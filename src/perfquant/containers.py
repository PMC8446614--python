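"""Core data containers shared across the pipeline.

A :class:`ConcentrationCurve` is a timestamped signal curve for one pixel or
region (arterial input or myocardial tissue).  A :class:`DynamicStudy` is a
multi-slice dynamic short-axis perfusion series with frame times and pixel
geometry.  Both are thin, validated wrappers around numpy arrays; image I/O
goes through nibabel (NIfTI + a JSON sidecar carrying the frame times).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = ["ConcentrationCurve", "DynamicStudy"]

VALID_SLICE_LABELS = ("basal", "mid", "apical")


@dataclass(frozen=True)
class ConcentrationCurve:
    """A signal (or scaled concentration) curve on a strictly increasing time grid.

    Parameters
    ----------
    times : array of float
        Frame times in seconds, strictly increasing.
    values : array of float
        Signal values in arbitrary units, one per time point.
    baseline_frames : int
        Number of leading pre-contrast frames that were used for baseline
        correction (0 if the curve is raw).
    label : str
        Either ``"aif"`` or ``"tissue"``.
    """

    times: np.ndarray
    values: np.ndarray
    baseline_frames: int = 0
    label: str = "tissue"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.size != values.size:
            raise ValueError(
                f"times ({times.size}) and values ({values.size}) differ in length"
            )
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.baseline_frames < times.size:
            raise ValueError("baseline_frames must be < curve length")
        if self.label not in ("aif", "tissue"):
            raise ValueError(f"label must be 'aif' or 'tissue', got {self.label!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray, **kwargs) -> "ConcentrationCurve":
        return replace(self, values=np.asarray(values, dtype=float), **kwargs)


@dataclass
class DynamicStudy:
    """Multi-slice dynamic perfusion series.

    ``data`` is indexed ``[row, col, slice, frame]``; ``frame_times`` are in
    seconds and strictly increasing; ``pixel_spacing`` is the in-plane pixel
    size in mm; ``slice_labels`` name the short-axis positions (always
    including basal and mid, optionally apical).
    """

    data: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: float = 1.25
    slice_labels: Sequence[str] = field(default_factory=lambda: ["basal", "mid", "apical"])

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (row, col, slice, frame)")
        if self.frame_times.size != self.data.shape[3]:
            raise ValueError("frame_times length must match the frame axis")
        if self.frame_times.size >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        labels = list(self.slice_labels)
        if len(labels) != self.data.shape[2]:
            raise ValueError("slice_labels must match the slice axis length")
        if len(labels) not in (2, 3):
            raise ValueError("a study has 2 or 3 slices")
        if not {"basal", "mid"} <= set(labels):
            raise ValueError("basal and mid slices are always required")
        for lab in labels:
            if lab not in VALID_SLICE_LABELS:
                raise ValueError(f"unknown slice label {lab!r}")
        self.slice_labels = labels

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def slice_index(self, label: str) -> int:
        return list(self.slice_labels).index(label)

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Write the series as 4-D NIfTI plus a ``.json`` frame-time sidecar."""
        path = Path(path)
        affine = np.diag([self.pixel_spacing, self.pixel_spacing, 10.0, 1.0])
        nib.save(nib.Nifti1Image(self.data, affine), str(path))
        sidecar = _sidecar_path(path)
        sidecar.write_text(
            json.dumps(
                {
                    "frame_times": self.frame_times.tolist(),
                    "pixel_spacing": self.pixel_spacing,
                    "slice_labels": list(self.slice_labels),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "DynamicStudy":
        path = Path(path)
        img = nib.load(str(path))
        meta = json.loads(_sidecar_path(path).read_text())
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            frame_times=np.asarray(meta["frame_times"], dtype=float),
            pixel_spacing=float(meta.get("pixel_spacing", 1.25)),
            slice_labels=meta["slice_labels"],
        )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")
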