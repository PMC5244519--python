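"""End-to-end orchestration: bin -> map -> gate -> segment -> quantify -> stats.

Stage order per animal is fixed: spatiotemporal binning, per-stimulus
Fourier extraction, the map-fidelity gate (animals whose retinotopic maps
fall below the SNR threshold are excluded and logged, not analyzed),
retinotopy, field-sign segmentation (or imported manual labels), the
responsive-cortex mask from the grating magnitude map, per-area means and
V1 normalization.  There is no cross-animal coupling before the stats
stage.  A manifest records the configuration hash, per-stage checksums,
and warnings so identical runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import AnovaResult, bonferroni_posthoc, one_way_anova, two_way_anova
from .fourier_mapping import (ComplexResponseMap, RetinotopyPair, extract_response,
                              map_fidelity, retinotopy_from_phases)
from .isoi_sim import (CorticalSheetModel, NoiseModel, simulate_animal_movies)
from .movie_io import BinnedMovie, RawMovie, bin_movie
from .response_quant import (ResponseTable, ThresholdRule, normalize_to_v1,
                             region_means, responsive_mask)
from .segmentation import AreaLabelMap, field_sign, import_labels, segment_areas
from .stimulus_model import (StimulusSpec, azimuth_bar_spec, elevation_bar_spec,
                             grating_patch_spec)

__all__ = ["AnalysisParams", "AnimalResult", "analyze_animal", "run_cohort",
           "run_stats", "simulate_imaging_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisParams:
    """Every tunable the per-animal analysis reads."""

    f_stim_hz: float = 1.0 / 8.0
    delay_s: float = 0.0
    signal_sign: int = -1
    smooth_sigma_px: float = 2.0
    min_component_px: int = 100
    mask_kernel_px: int = 5
    mask_sigma_px: float = 1.0
    threshold_mode: str = "fraction_of_p99"
    threshold_value: float = 0.25
    fidelity_threshold: float = 3.0
    medial_positive_x: bool = True
    region_erode_px: int = 1

    def threshold_rule(self) -> ThresholdRule:
        return ThresholdRule(mode=self.threshold_mode, value=self.threshold_value)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class AnimalResult:
    animal_id: str
    snr: float
    excluded: bool
    retinotopy: RetinotopyPair | None = None
    labels: AreaLabelMap | None = None
    mask: np.ndarray | None = None
    magnitude: np.ndarray | None = None
    table: ResponseTable | None = None
    manifest: dict = field(default_factory=dict)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def analyze_animal(
    movies: Mapping[str, RawMovie | BinnedMovie],
    specs: Mapping[str, StimulusSpec],
    params: AnalysisParams = AnalysisParams(),
    animal_id: str = "animal",
    manual_labels: AreaLabelMap | None = None,
) -> AnimalResult:
    """Run the full per-animal analysis.

    ``movies`` must contain runs keyed ``"azimuth"``, ``"elevation"`` and
    ``"grating"`` (raw movies are binned first; pre-binned accepted), with
    matching stimulus specs.  Returns an excluded result (no maps, no
    table) if the retinotopic-map SNR falls below the fidelity threshold.
    """
    for key in ("azimuth", "elevation", "grating"):
        if key not in movies:
            raise ValueError(f"missing {key!r} run for animal {animal_id}")

    manifest: dict = {
        "animal_id": animal_id,
        "software_version": __version__,
        "config_hash": params.config_hash(),
        "params": asdict(params),
        "warnings": [],
        "stages": {},
    }

    binned: dict[str, BinnedMovie] = {}
    for key, movie in movies.items():
        binned[key] = movie if isinstance(movie, BinnedMovie) else bin_movie(movie)
        manifest["stages"][f"bin:{key}"] = _checksum(binned[key].data)

    maps: dict[str, ComplexResponseMap] = {
        key: extract_response(m, params.f_stim_hz) for key, m in binned.items()
    }
    for key, cmap in maps.items():
        manifest["stages"][f"map:{key}"] = _checksum(cmap.coeff)

    snr = min(map_fidelity(binned["azimuth"], params.f_stim_hz),
              map_fidelity(binned["elevation"], params.f_stim_hz))
    manifest["fidelity_snr"] = snr
    if snr < params.fidelity_threshold:
        msg = (f"animal {animal_id} excluded: retinotopic-map SNR {snr:.2f} < "
               f"threshold {params.fidelity_threshold}")
        logger.warning(msg)
        manifest["warnings"].append(msg)
        manifest["excluded"] = True
        return AnimalResult(animal_id=animal_id, snr=snr, excluded=True,
                            manifest=manifest)
    manifest["excluded"] = False

    retino = retinotopy_from_phases(
        maps["azimuth"], maps["elevation"], specs["azimuth"], specs["elevation"],
        delay_s=params.delay_s, signal_sign=params.signal_sign)
    manifest["stages"]["retinotopy"] = _checksum(
        np.stack([retino.azimuth_deg, retino.elevation_deg]))

    magnitude = maps["grating"].magnitude
    mask = responsive_mask(magnitude, kernel_px=params.mask_kernel_px,
                           sigma=params.mask_sigma_px, rule=params.threshold_rule())
    manifest["stages"]["mask"] = _checksum(mask)

    if manual_labels is not None:
        labels = manual_labels
    else:
        fs = field_sign(retino, smooth_sigma_px=params.smooth_sigma_px, mask=mask)
        labels = segment_areas(fs, mask, min_size_px=params.min_component_px,
                               medial_positive_x=params.medial_positive_x)
    manifest["stages"]["labels"] = _checksum(labels.labels)

    table = region_means(magnitude, mask, labels, animal_id=animal_id,
                         erode_px=params.region_erode_px)
    table = normalize_to_v1(table)
    if table.missing_areas:
        manifest["warnings"].append(
            f"animal {animal_id}: areas with no responsive pixels: "
            f"{table.missing_areas}")

    return AnimalResult(animal_id=animal_id, snr=snr, excluded=False,
                        retinotopy=retino, labels=labels, mask=mask,
                        magnitude=magnitude, table=table, manifest=manifest)


def default_specs(n_cycles: int = 10) -> dict[str, StimulusSpec]:
    return {
        "azimuth": azimuth_bar_spec(n_cycles=n_cycles),
        "elevation": elevation_bar_spec(n_cycles=n_cycles),
        "grating": grating_patch_spec(n_cycles=n_cycles),
    }


def simulate_imaging_cohort(
    sheets_by_animal: Mapping[str, CorticalSheetModel],
    factors_by_animal: Mapping[str, Mapping[str, str]],
    noise: NoiseModel | None = None,
    params: AnalysisParams = AnalysisParams(),
    n_cycles: int = 10,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[AnimalResult]]:
    """Simulate, analyze, and tabulate a whole imaging cohort.

    Each animal gets its own sheet (e.g. genotype-scaled amplitudes) and
    an independent noise stream.  Returns the tidy cohort table (excluded
    animals omitted, with their exclusion logged in the results list) and
    all per-animal results.
    """
    specs = default_specs(n_cycles=n_cycles)
    ss = np.random.SeedSequence(seed)
    rows = []
    results = []
    for child, (animal_id, sheet) in zip(ss.spawn(len(sheets_by_animal)),
                                         sheets_by_animal.items()):
        movies, _ = simulate_animal_movies(
            sheet, specs, noise=noise, seed=int(child.generate_state(1)[0]))
        res = analyze_animal(movies, specs, params=params, animal_id=animal_id)
        results.append(res)
        if res.excluded:
            continue
        row = dict(factors_by_animal.get(animal_id, {}))
        row.update(res.table.to_row())
        rows.append(row)
    return pd.DataFrame(rows), results


def run_stats(
    table: pd.DataFrame,
    design: str,
    areas: list[str] | None = None,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> dict[str, AnovaResult]:
    """Run the configured ANOVA design on each area's normalized amplitude.

    ``design`` is ``"oneway:<factor>"`` or ``"twoway:<factorA>*<factorB>"``.
    Bonferroni post hoc tests are attached for one-way designs whose
    effect is significant at ``alpha``.  By default every ``norm_*``
    column except V1 is tested (normalized V1 is identically 1); pass
    ``areas`` explicitly to override.
    """
    if areas is None:
        areas = [c[len("norm_"):] for c in table.columns
                 if c.startswith("norm_") and c != "norm_V1"]
    kind, _, spec = design.partition(":")
    results: dict[str, AnovaResult] = {}
    for area in areas:
        col = f"norm_{area}"
        sub = table.dropna(subset=[col])
        if kind == "oneway":
            res = one_way_anova(sub[col], sub[spec])
            if posthoc and res.effects[0].p < alpha:
                res.posthoc = bonferroni_posthoc(sub[col], sub[spec], anova=res)
        elif kind == "twoway":
            fa, _, fb = spec.partition("*")
            res = two_way_anova(sub[col], sub[fa], sub[fb], names=(fa, fb))
        else:
            raise ValueError(f"unknown design {design!r}; use oneway:<factor> "
                             "or twoway:<a>*<b>")
        results[area] = res
    return results


def run_cohort(
    table: pd.DataFrame,
    designs: list[str],
    min_cell_n: int = 2,
) -> dict[str, dict[str, AnovaResult]]:
    """Run one or more statistical designs over a cohort table.

    Raises if any compared cell has fewer than ``min_cell_n`` animals
    after exclusions, listing the offending cells.
    """
    if table.empty:
        raise ValueError("cohort table is empty (no animals survived analysis?)")
    out: dict[str, dict[str, AnovaResult]] = {}
    for design in designs:
        kind, _, spec = design.partition(":")
        factors = spec.split("*") if kind == "twoway" else [spec]
        counts = table.groupby(factors).size()
        small = counts[counts < min_cell_n]
        if not small.empty:
            raise ValueError(
                f"design {design!r}: cells below n={min_cell_n}: "
                f"{small.to_dict()}")
        out[design] = run_stats(table, design)
    return out
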