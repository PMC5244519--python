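"""Shared fixtures: simulated animals are expensive, so build them once."""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from retinomapper.fourier_mapping import extract_response, retinotopy_from_phases
from retinomapper.isoi_sim import NoiseModel, build_default_sheet, simulate_movie
from retinomapper.movie_io import bin_movie
from retinomapper.response_quant import normalize_to_v1, region_means, responsive_mask
from retinomapper.segmentation import field_sign, segment_areas
from retinomapper.stimulus_model import (azimuth_bar_spec, elevation_bar_spec,
                                         grating_patch_spec)

F_STIM = 1.0 / 8.0

TRUE_RATIOS = {"V1": 1.0, "LM": 0.7, "LI": 0.5, "AL": 0.6, "RL": 0.6, "AMPM": 0.7}


@pytest.fixture(scope="session")
def default_sheet():
    return build_default_sheet()


@pytest.fixture(scope="session")
def bar_specs():
    return SimpleNamespace(azimuth=azimuth_bar_spec(), elevation=elevation_bar_spec(),
                           grating=grating_patch_spec(n_cycles=10))


def _simulate_animal(sheet, specs, noise, seeds):
    mov_a, truth = simulate_movie(sheet, specs.azimuth, noise=noise, seed=seeds[0])
    mov_e, _ = simulate_movie(sheet, specs.elevation, noise=noise, seed=seeds[1])
    mov_g, _ = simulate_movie(sheet, specs.grating, noise=noise, seed=seeds[2])
    return SimpleNamespace(raw=dict(azimuth=mov_a, elevation=mov_e, grating=mov_g),
                           truth=truth)


def _analyze(animal, specs):
    binned = {k: bin_movie(m) for k, m in animal.raw.items()}
    cmaps = {k: extract_response(m, F_STIM) for k, m in binned.items()}
    retino = retinotopy_from_phases(cmaps["azimuth"], cmaps["elevation"],
                                    specs.azimuth, specs.elevation)
    magnitude = cmaps["grating"].magnitude
    mask = responsive_mask(magnitude)
    fs = field_sign(retino, mask=mask)
    labels = segment_areas(fs, mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = normalize_to_v1(region_means(magnitude, mask, labels, erode_px=1))
    return SimpleNamespace(binned=binned, cmaps=cmaps, retino=retino,
                           magnitude=magnitude, mask=mask, field_sign=fs,
                           labels=labels, table=table)


@pytest.fixture(scope="session")
def silent_animal(default_sheet, bar_specs):
    """Noise-free simulated animal with full analysis products."""
    animal = _simulate_animal(default_sheet, bar_specs, NoiseModel.silent(),
                              (11, 12, 13))
    animal.analysis = _analyze(animal, bar_specs)
    return animal


@pytest.fixture(scope="session")
def noisy_animal(default_sheet, bar_specs):
    """Default-noise simulated animal with full analysis products."""
    animal = _simulate_animal(default_sheet, bar_specs, NoiseModel(), (21, 22, 23))
    animal.analysis = _analyze(animal, bar_specs)
    return animal


@pytest.fixture(scope="session")
def binned_truth_labels(silent_animal):
    """Ground-truth labels subsampled to the binned grid."""
    return silent_animal.truth.label_image[::2, ::2]


def binned_truth_map(img):
    """2x2 block-average a raw-scale ground-truth map (NaN-aware)."""
    h, w = img.shape
    blocks = img.reshape(h // 2, 2, w // 2, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.nanmean(blocks, axis=(1, 3))
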