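"""Shared fixtures: small phantoms and prepared AIFs, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from perfquant.kinetics import quantify_map
from perfquant.preprocessing import (
    build_composite_input,
    extract_blood_pool_curve,
    split_boluses,
)
from perfquant.synthetic_data import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless two-slice phantom with default physiology."""
    cfg = PhantomConfig(grid_size=48, n_slices=2, noise_sd=0.0, seed=7)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def prepared_inputs(noiseless_phantom):
    """(blood curve, split, composite AIF) of the noiseless phantom."""
    ph = noiseless_phantom
    blood = extract_blood_pool_curve(ph.series, ph.lv_blood_mask)
    split = split_boluses(blood, dose_fraction=ph.config.prebolus_dose_fraction)
    aif = build_composite_input(blood, split)
    return blood, split, aif


def subsample_mask(mask: np.ndarray, stride: int) -> np.ndarray:
    """Every ``stride``-th pixel of a boolean mask (pixel fits are independent)."""
    rr, cc, ss = np.nonzero(mask)
    keep = np.zeros_like(mask)
    idx = np.arange(0, rr.size, stride)
    keep[rr[idx], cc[idx], ss[idx]] = True
    return keep


def quantified_subset(phantom, aif, stride=10):
    keep = subsample_mask(phantom.myocardial_mask, stride)
    return keep, quantify_map(phantom.series, aif, keep)
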