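"""Dual-bolus dynamic perfusion phantoms and territory-level cohorts.

The phantom emulates a stress perfusion CMR acquisition: a diluted pre-bolus
(default 10% dose) followed by a full-dose main bolus on one time axis, a
gamma-variate first-pass arterial input in the LV blood pool, and myocardial
tissue curves generated by the two-compartment exchange model with
territory-dependent true MBF.  Geometry per slice is a concentric disk (LV
blood pool), an annulus (myocardium) and a crescent (RV) whose contact arc
defines ground-truth RV insertion points.

Signals are generated in linear units (signal proportional to
concentration), which is the operating assumption of dual-bolus
quantification; an optional saturation-recovery nonlinearity can be switched
on to emulate the high-dose AIF clipping that motivates the dual-bolus
scheme in the first place.

The cohort generator draws territory-level MBF observations for the three
coronary-status groups (normal, small aneurysm, affected) from a
quantile-matched log-normal family so that population median and
interquartile range equal the group specification exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import aha_mapping
from .containers import ConcentrationCurve, DynamicStudy
from .kinetics import (
    MYOCARDIAL_DENSITY_G_PER_ML,
    KineticParameters,
    forward_tissue_curve,
)

__all__ = [
    "AifParams",
    "PhantomConfig",
    "PhantomGroundTruth",
    "GroupSpec",
    "CohortConfig",
    "generate_aif",
    "generate_phantom",
    "generate_cohort",
]

TERRITORIES = ("LAD", "RCA", "LCx")

#: Normal quantile at p = 0.75, used to convert quartiles to log-scale widths.
_Z75 = 0.6744897501960817


# --------------------------------------------------------------------------
# Arterial input function
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class AifParams:
    """Gamma-variate first-pass bolus model.

    ``c(t) = amplitude * ((t - onset)/(shape*scale))**shape
             * exp(shape - (t - onset)/scale)`` for ``t > onset``, else 0 —
    normalised so the peak value is ``amplitude`` and the peak time is
    ``onset + shape*scale``.  An optional dispersed recirculation pass can be
    added; first-pass quantification does not require it and it is off by
    default.
    """

    amplitude: float = 1.0
    onset: float = 5.0
    shape: float = 1.0
    scale: float = 2.5
    recirculation_fraction: float = 0.0
    recirculation_delay: float = 25.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.shape <= 0 or self.scale <= 0:
            raise ValueError("amplitude, shape and scale must be > 0")
        if not 0 <= self.recirculation_fraction < 1:
            raise ValueError("recirculation_fraction must be in [0, 1)")


def _gamma_variate(
    times: np.ndarray, amplitude: float, onset: float, shape: float, scale: float
) -> np.ndarray:
    x = np.asarray(times, dtype=float) - onset
    out = np.zeros_like(x)
    pos = x > 0
    xp = x[pos]
    out[pos] = amplitude * (xp / (shape * scale)) ** shape * np.exp(shape - xp / scale)
    return out


def generate_aif(
    aif_params: AifParams, times: np.ndarray, dose_scale: float = 1.0
) -> ConcentrationCurve:
    """First-pass AIF on ``times``, linearly scaled by ``dose_scale``."""
    times = np.asarray(times, dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if dose_scale <= 0:
        raise ValueError("dose_scale must be > 0")
    p = aif_params
    values = _gamma_variate(times, p.amplitude, p.onset, p.shape, p.scale)
    if p.recirculation_fraction > 0:
        values = values + _gamma_variate(
            times,
            p.amplitude * p.recirculation_fraction,
            p.onset + p.recirculation_delay,
            p.shape,
            p.scale * 2.0,
        )
    return ConcentrationCurve(times=times, values=dose_scale * values, label="aif")


# --------------------------------------------------------------------------
# Phantom
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition, geometry and physiology of one synthetic scan.

    Defaults emulate the target acquisition: 128x128 grid at 1.25 mm, three
    short-axis slices, 0.7 s frame interval (stress heart rate near 100 bpm),
    60 frames per pass, 10% pre-bolus dose, and a hypoperfused LAD territory
    (1.3 ml/min/g) against normally perfused RCA/LCx (2.5 ml/min/g).
    """

    grid_size: int = 128
    n_slices: int = 3
    frame_interval: float = 0.7
    n_frames_per_pass: int = 60
    interpass_gap: float = 30.0
    prebolus_dose_fraction: float = 0.1
    aif_params: AifParams = field(default_factory=AifParams)
    territory_mbf: Mapping[str, float] = field(
        default_factory=lambda: {"LAD": 1.3, "RCA": 2.5, "LCx": 2.5}
    )
    noise_sd: float = 0.005
    baseline_signal: float = 1.0
    pixel_spacing: float = 1.25
    # shared non-flow tissue parameters (canonical myocardium: blood volume
    # ~10%, interstitium ~20%, extraction ~0.3 at stress flow)
    tissue_ps: float = 1.0
    tissue_vp: float = 0.10
    tissue_ve: float = 0.2
    tissue_t0: float = 1.5
    density: float = MYOCARDIAL_DENSITY_G_PER_ML
    # ground-truth RV insertion angles (degrees CCW from 12 o'clock)
    anterior_insertion_deg: float = 60.0
    inferior_insertion_deg: float = 160.0
    # optional saturation-recovery nonlinearity (off: signal = concentration)
    saturation: bool = False
    sat_s0: float = 5.0
    sat_tsat: float = 0.1
    sat_r10: float = 1.0
    sat_relaxivity: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames_per_pass < 20:
            raise ValueError(
                "n_frames_per_pass must be >= 20 (baseline plus a full first pass)"
            )
        if not 0 < self.prebolus_dose_fraction <= 1:
            raise ValueError("prebolus_dose_fraction must be in (0, 1]")
        if self.n_slices not in (2, 3):
            raise ValueError("n_slices must be 2 or 3")
        for name, mbf in self.territory_mbf.items():
            if name not in TERRITORIES:
                raise ValueError(f"unknown territory {name!r}")
            if mbf <= 0:
                raise ValueError(f"territory {name}: MBF must be > 0")
        if self.grid_size < 24:
            raise ValueError("grid_size must be >= 24")

    @property
    def slice_labels(self) -> list[str]:
        return ["basal", "mid", "apical"][: self.n_slices]


@dataclass
class PhantomGroundTruth:
    """A generated phantom with everything downstream stages may be scored against."""

    series: DynamicStudy
    lv_blood_mask: np.ndarray
    myocardial_mask: np.ndarray
    rv_mask: np.ndarray
    insertion_points: dict[str, aha_mapping.SliceInsertion]
    true_mbf_map: np.ndarray
    true_params_map: dict[str, np.ndarray]
    true_aif: ConcentrationCurve  # noiseless full-dose AIF on the full time axis
    prebolus_arrival_time: float
    mainbolus_arrival_time: float
    config: PhantomConfig
    seed: int

    def save(self, out_dir: str | Path) -> None:
        """Write series, masks, insertion points and the truth table."""
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.series.save(out / "series.nii.gz")
        affine = np.diag([self.config.pixel_spacing, self.config.pixel_spacing, 10.0, 1.0])
        labels = (
            self.lv_blood_mask.astype(np.int16)
            + 2 * self.myocardial_mask.astype(np.int16)
            + 3 * self.rv_mask.astype(np.int16)
        )
        nib.save(nib.Nifti1Image(labels, affine), str(out / "masks.nii.gz"))
        (out / "insertion_points.json").write_text(
            json.dumps(
                {
                    lab: {
                        "anterior": list(ins.anterior),
                        "inferior": list(ins.inferior),
                        "anterior_deg": ins.anterior_deg,
                        "inferior_deg": ins.inferior_deg,
                    }
                    for lab, ins in self.insertion_points.items()
                },
                indent=2,
            )
        )
        rows = []
        rr, cc, ss = np.nonzero(self.myocardial_mask)
        for r, c, s in zip(rr, cc, ss):
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "slice": self.series.slice_labels[s],
                    "Fp": self.true_params_map["Fp"][r, c, s],
                    "PS": self.true_params_map["PS"][r, c, s],
                    "vp": self.true_params_map["vp"][r, c, s],
                    "ve": self.true_params_map["ve"][r, c, s],
                    "t0": self.true_params_map["t0"][r, c, s],
                    "mbf": self.true_mbf_map[r, c, s],
                }
            )
        pd.DataFrame(rows).to_csv(out / "ground_truth.csv", index=False)


def _slice_geometry(config: PhantomConfig, slice_label: str):
    """Disk + annulus + crescent geometry of one slice."""
    g = config.grid_size
    center = ((g - 1) / 2.0, (g - 1) / 2.0)
    scale = 0.75 if slice_label == "apical" else 1.0
    r_blood = 0.125 * g * scale
    r_epi = 0.1875 * g * scale
    r_rv = r_epi + max(2.0, 0.045 * g)

    rows, cols = np.mgrid[0:g, 0:g]
    radius = np.hypot(rows - center[0], cols - center[1])
    angles = aha_mapping.pixel_angles(rows, cols, center)

    lv_blood = radius <= r_blood
    myo = (radius > r_blood) & (radius <= r_epi)
    in_arc = ((angles - config.anterior_insertion_deg) % 360.0) <= (
        (config.inferior_insertion_deg - config.anterior_insertion_deg) % 360.0
    )
    rv = (radius > r_epi) & (radius <= r_rv) & in_arc
    return center, r_epi, lv_blood, myo, rv, angles


def _phantom_time_axis(config: PhantomConfig) -> tuple[np.ndarray, float]:
    """Concatenated two-pass time axis and the main-pass start time."""
    n = config.n_frames_per_pass
    dt = config.frame_interval
    pass1 = np.arange(n) * dt
    main_start = n * dt + config.interpass_gap
    pass2 = main_start + np.arange(n) * dt
    return np.concatenate([pass1, pass2]), main_start


def generate_phantom(config: PhantomConfig) -> PhantomGroundTruth:
    """Generate one dual-bolus phantom with full ground truth.

    The LV blood pool follows the gamma-variate input — scaled by the
    pre-bolus dose fraction in pass 1, full dose in pass 2 — and every
    myocardial pixel follows the 2CXM forward model driven by the combined
    two-pass input with its territory's true plasma flow.  Seeded Gaussian
    noise is added on top of a constant baseline signal.
    """
    missing = [t for t in TERRITORIES if t not in config.territory_mbf]
    if missing:
        raise ValueError(f"territory_mbf missing territories: {missing}")

    times, main_start = _phantom_time_axis(config)
    g = config.grid_size
    n_slices = config.n_slices
    slice_labels = config.slice_labels

    # combined two-pass blood-pool input (zero-baseline concentration units)
    pre = generate_aif(config.aif_params, times, config.prebolus_dose_fraction)
    main_params = replace(config.aif_params, onset=config.aif_params.onset + main_start)
    main = generate_aif(main_params, times, 1.0)
    blood_values = pre.values + main.values
    blood_input = ConcentrationCurve(times=times, values=blood_values, label="aif")
    # noiseless full-dose reference input on the main-bolus timing
    true_aif = ConcentrationCurve(times=times, values=main.values, label="aif")

    # one tissue curve per territory (pixels within a territory share params)
    tissue_curves = {}
    true_params = {}
    for terr in TERRITORIES:
        fp = config.territory_mbf[terr] * config.density
        params = KineticParameters(
            Fp=fp,
            PS=config.tissue_ps,
            vp=config.tissue_vp,
            ve=config.tissue_ve,
            t0=config.tissue_t0,
        )
        tissue_curves[terr] = forward_tissue_curve(blood_input, params).values
        true_params[terr] = params

    series = np.zeros((g, g, n_slices, times.size))
    lv_blood_mask = np.zeros((g, g, n_slices), dtype=bool)
    myocardial_mask = np.zeros_like(lv_blood_mask)
    rv_mask = np.zeros_like(lv_blood_mask)
    true_mbf = np.full((g, g, n_slices), np.nan)
    true_maps = {k: np.full((g, g, n_slices), np.nan) for k in ("Fp", "PS", "vp", "ve", "t0")}
    insertions: dict[str, aha_mapping.SliceInsertion] = {}

    for s, lab in enumerate(slice_labels):
        center, r_epi, lv_blood, myo, rv, _ = _slice_geometry(config, lab)
        lv_blood_mask[:, :, s] = lv_blood
        myocardial_mask[:, :, s] = myo
        rv_mask[:, :, s] = rv

        seg_labels = aha_mapping.compute_segment_labels(
            myo, config.anterior_insertion_deg, lab, center
        )
        series[lv_blood, s, :] = blood_values
        series[rv, s, :] = 0.7 * blood_values
        for terr, segs in aha_mapping.TERRITORY_SEGMENTS.items():
            sel = myo & np.isin(seg_labels, list(segs))
            series[sel, s, :] = tissue_curves[terr]
            p = true_params[terr]
            true_mbf[sel, s] = config.territory_mbf[terr]
            for key, val in (("Fp", p.Fp), ("PS", p.PS), ("vp", p.vp), ("ve", p.ve), ("t0", p.t0)):
                true_maps[key][sel, s] = val

        def on_epi(angle_deg: float) -> tuple[float, float]:
            rad = np.radians(angle_deg)
            return (
                center[0] - r_epi * np.cos(rad),
                center[1] - r_epi * np.sin(rad),
            )

        insertions[lab] = aha_mapping.SliceInsertion(
            anterior=on_epi(config.anterior_insertion_deg),
            inferior=on_epi(config.inferior_insertion_deg),
            anterior_deg=config.anterior_insertion_deg,
            inferior_deg=config.inferior_insertion_deg,
        )

    if config.saturation:
        r1 = config.sat_r10 + config.sat_relaxivity * series
        series = config.sat_s0 * (1.0 - np.exp(-config.sat_tsat * r1))

    series = series + config.baseline_signal
    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        series = series + rng.normal(0.0, config.noise_sd, series.shape)

    study = DynamicStudy(
        data=series,
        frame_times=times,
        pixel_spacing=config.pixel_spacing,
        slice_labels=slice_labels,
    )
    return PhantomGroundTruth(
        series=study,
        lv_blood_mask=lv_blood_mask,
        myocardial_mask=myocardial_mask,
        rv_mask=rv_mask,
        insertion_points=insertions,
        true_mbf_map=true_mbf,
        true_params_map=true_maps,
        true_aif=true_aif,
        prebolus_arrival_time=config.aif_params.onset,
        mainbolus_arrival_time=main_start + config.aif_params.onset,
        config=config,
        seed=config.seed,
    )


# --------------------------------------------------------------------------
# Cohort generator
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class GroupSpec:
    """Target median, quartiles and territory-observation count of one group."""

    median: float
    q1: float
    q3: float
    count: int

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be > 0")
        if not self.q1 < self.median < self.q3:
            raise ValueError(
                f"infeasible median/IQR: need q1 < median < q3, got "
                f"({self.q1}, {self.median}, {self.q3})"
            )
        if self.q1 <= 0:
            raise ValueError("q1 must be > 0")
        if self.count < 2:
            raise ValueError("count must be >= 2")


def _default_group_specs() -> dict[str, GroupSpec]:
    # group medians/IQRs of the emulated cohort; counts sized to ~15 scans
    # of 3 territories each
    return {
        "normal": GroupSpec(median=2.57, q1=2.02, q3=2.69, count=24),
        "small_aneurysm": GroupSpec(median=2.52, q1=2.45, q3=2.83, count=6),
        "affected": GroupSpec(median=1.26, q1=1.05, q3=1.67, count=15),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Group structure of a simulated territory-level cohort.

    ``distribution_family`` is ``"split_lognormal"`` (default; matches the
    target median and both quartiles exactly in population) or
    ``"lognormal"`` (symmetric log-width from the IQR; quartiles match only
    approximately when the printed IQR is log-asymmetric).
    """

    group_specs: Mapping[str, GroupSpec] = field(default_factory=_default_group_specs)
    distribution_family: str = "split_lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution_family not in ("split_lognormal", "lognormal"):
            raise ValueError(
                f"unknown distribution_family {self.distribution_family!r}"
            )
        if not self.group_specs:
            raise ValueError("group_specs must not be empty")


def _sample_group(
    spec: GroupSpec, family: str, rng: np.random.Generator, n: int
) -> np.ndarray:
    mu = np.log(spec.median)
    if family == "lognormal":
        sigma = (np.log(spec.q3) - np.log(spec.q1)) / (2.0 * _Z75)
        return np.exp(mu + sigma * rng.standard_normal(n))
    sigma_lo = (mu - np.log(spec.q1)) / _Z75
    sigma_hi = (np.log(spec.q3) - mu) / _Z75
    z = rng.standard_normal(n)
    sigma = np.where(z < 0, sigma_lo, sigma_hi)
    return np.exp(mu + sigma * z)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """One row per simulated territory observation: scan_id, territory, group, mbf."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for group in sorted(config.group_specs):
        spec = config.group_specs[group]
        mbf = _sample_group(spec, config.distribution_family, rng, spec.count)
        territories = [TERRITORIES[i % 3] for i in range(spec.count)]
        scan_ids = [f"sim-{group}-{i // 3:03d}" for i in range(spec.count)]
        frames.append(
            pd.DataFrame(
                {
                    "scan_id": scan_ids,
                    "territory": territories,
                    "group": group,
                    "mbf": mbf,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
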