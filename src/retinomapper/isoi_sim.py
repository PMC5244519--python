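"""Forward model: synthetic widefield movies and cohorts with ground truth.

A :class:`CorticalSheetModel` lays out a large V1 patch and five smaller
higher visual areas, each with an affine retinotopic map; mirror areas run
their azimuth map backwards so the visual field sign alternates across
borders.  :func:`simulate_movie` renders the periodic reflectance
modulation those maps imply under a given stimulus — intrinsic signals are
reflectance DECREASES on activation, so the modulation enters with a minus
sign (a constant pi offset in phase, handled downstream) — plus white
noise, slow drift, and a periodic physiological artifact, quantized to
12-bit camera counts.

:func:`simulate_cohort_responses` is the fast response-level generator
used for statistical calibration: it skips imaging entirely and draws
per-animal normalized amplitudes around programmed cell means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .movie_io import MAX_12BIT, RawMovie
from .stimulus_model import (
    ScreenGeometry,
    StimulusSpec,
    motion_onset_time,
)

__all__ = [
    "AreaSpec",
    "CorticalSheetModel",
    "NoiseModel",
    "SimulatedGroundTruth",
    "CohortDesign",
    "build_default_sheet",
    "simulate_movie",
    "simulate_animal_movies",
    "simulate_cohort_responses",
    "raised_cosine",
    "first_harmonic_factor",
    "AREA_NAMES",
]

AREA_NAMES = ("V1", "LM", "LI", "AL", "RL", "AMPM")

#: Default area footprints in micrometres: (x0, x1, y0, y1) with x
#: increasing medially (rightward in the image) and y increasing
#: posteriorly (downward).  Gaps of >= 200 um separate the patches.
_DEFAULT_LAYOUT_UM: dict[str, tuple[float, float, float, float]] = {
    "V1":   (2740.0, 4540.0, 2300.0, 4500.0),
    "LM":   (1240.0, 2540.0, 3300.0, 4700.0),
    "LI":   (40.0, 1040.0, 2700.0, 4100.0),
    "AL":   (1240.0, 2540.0, 1400.0, 2800.0),
    "RL":   (2740.0, 3840.0, 400.0, 1800.0),
    "AMPM": (4040.0, 5100.0, 600.0, 2000.0),
}

_DEFAULT_MIRROR = {"V1": False, "LM": True, "LI": False,
                   "AL": True, "RL": False, "AMPM": True}

#: Default fractional reflectance modulation (peak Delta-R/R) per area.
_DEFAULT_AMPLITUDE = {"V1": 0.010, "LM": 0.007, "LI": 0.005,
                      "AL": 0.006, "RL": 0.006, "AMPM": 0.007}


@dataclass(frozen=True)
class AreaSpec:
    """One cortical area: polygon footprint plus an affine retinotopic map.

    ``polygon_px`` is an (N, 2) array of (x, y) vertices in pixels.  The
    retinotopy is affine over the polygon's bounding box: azimuth varies
    linearly with x and elevation with y; ``mirror`` reverses the azimuth
    axis, flipping the field sign.
    """

    name: str
    polygon_px: np.ndarray
    mirror: bool
    response_amplitude: float
    # represented visual field sits inside the sweep range (-55..55 az,
    # -37.5..37.5 el) with a margin, keeping preferred response times away
    # from the cycle wrap where phase noise flips to the opposite sweep end
    azimuth_range_deg: tuple[float, float] = (-50.0, 50.0)
    elevation_range_deg: tuple[float, float] = (-34.0, 34.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.response_amplitude < 0.1):
            raise ValueError(
                f"response_amplitude must be in [0, 0.1), got {self.response_amplitude}")

    def bbox(self) -> tuple[float, float, float, float]:
        xs, ys = self.polygon_px[:, 0], self.polygon_px[:, 1]
        return xs.min(), xs.max(), ys.min(), ys.max()

    def retinotopy(self, xx: np.ndarray, yy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Azimuth/elevation (deg) at pixel coordinates ``xx``, ``yy``."""
        x0, x1, y0, y1 = self.bbox()
        fx = np.clip((xx - x0) / (x1 - x0), 0.0, 1.0)
        fy = np.clip((yy - y0) / (y1 - y0), 0.0, 1.0)
        if self.mirror:
            fx = 1.0 - fx
        alo, ahi = self.azimuth_range_deg
        elo, ehi = self.elevation_range_deg
        return alo + fx * (ahi - alo), elo + fy * (ehi - elo)


@dataclass(frozen=True)
class CorticalSheetModel:
    """The simulated cortical field of view."""

    field_px: tuple[int, int] = (128, 128)
    um_per_px: float = 40.0
    areas: tuple[AreaSpec, ...] = ()
    delay_s: float = 0.0
    baseline_counts: int = 3000
    waveform_duty: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.baseline_counts <= MAX_12BIT):
            raise ValueError("baseline_counts must be in (0, 4095]")
        if not (0 < self.waveform_duty <= 1):
            raise ValueError("waveform_duty must be in (0, 1]")
        self._validate_no_overlap()

    def _validate_no_overlap(self) -> None:
        h, w = self.field_px
        occupancy = np.zeros((h, w), dtype=np.int32)
        for area in self.areas:
            rr, cc = draw_polygon(area.polygon_px[:, 1], area.polygon_px[:, 0],
                                  shape=(h, w))
            occupancy[rr, cc] += 1
        if (occupancy > 1).any():
            raise ValueError("area polygons overlap")

    def label_image(self) -> np.ndarray:
        """Integer label image; 0 = background, i+1 = areas[i]."""
        h, w = self.field_px
        labels = np.zeros((h, w), dtype=np.int32)
        for i, area in enumerate(self.areas):
            rr, cc = draw_polygon(area.polygon_px[:, 1], area.polygon_px[:, 0],
                                  shape=(h, w))
            labels[rr, cc] = i + 1
        return labels

    def label_names(self) -> dict[int, str]:
        names = {0: "background"}
        names.update({i + 1: a.name for i, a in enumerate(self.areas)})
        return names

    def retinotopy_images(self) -> tuple[np.ndarray, np.ndarray]:
        """True (azimuth, elevation) degree images; NaN outside areas."""
        h, w = self.field_px
        azi = np.full((h, w), np.nan)
        elev = np.full((h, w), np.nan)
        yy, xx = np.mgrid[0:h, 0:w]
        labels = self.label_image()
        for i, area in enumerate(self.areas):
            inside = labels == i + 1
            a, e = area.retinotopy(xx[inside].astype(float), yy[inside].astype(float))
            azi[inside] = a
            elev[inside] = e
        return azi, elev

    def amplitude_image(self) -> np.ndarray:
        h, w = self.field_px
        amp = np.zeros((h, w))
        labels = self.label_image()
        for i, area in enumerate(self.areas):
            amp[labels == i + 1] = area.response_amplitude
        return amp


@dataclass(frozen=True)
class NoiseModel:
    """Additive acquisition noise, in camera counts."""

    white_sigma: float = 15.0
    drift_amp: float = 20.0
    drift_timescale_s: float = 30.0
    physio_amp: float = 10.0
    physio_freq_hz: float = 3.1  # heartbeat-like; must not alias onto f_stim
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("white_sigma", "drift_amp", "physio_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(white_sigma=0.0, drift_amp=0.0, physio_amp=0.0)


@dataclass
class SimulatedGroundTruth:
    """Everything a recovery test needs to score the analysis."""

    sheet: CorticalSheetModel
    label_image: np.ndarray
    label_names: dict[int, str]
    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray
    t_pref_s: np.ndarray
    amplitude: np.ndarray
    true_amplitude_by_area: dict[str, float]
    delay_s: float
    seed: int | None

    def save(self, directory: str | Path) -> None:
        import tifffile

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(directory / "labels.tif", self.label_image.astype(np.int32))
        tifffile.imwrite(directory / "azimuth.tif", self.azimuth_deg.astype(np.float32))
        tifffile.imwrite(directory / "elevation.tif",
                         self.elevation_deg.astype(np.float32))
        (directory / "ground_truth.json").write_text(json.dumps({
            "label_names": {str(k): v for k, v in self.label_names.items()},
            "true_amplitude_by_area": self.true_amplitude_by_area,
            "delay_s": self.delay_s,
            "seed": self.seed,
            "um_per_px": self.sheet.um_per_px,
        }, indent=1))


def build_default_sheet(
    field_px: tuple[int, int] = (128, 128),
    um_per_px: float = 40.0,
    amplitudes: Mapping[str, float] | None = None,
    delay_s: float = 0.0,
    baseline_counts: int = 3000,
    waveform_duty: float = 0.5,
    layout_um: Mapping[str, tuple[float, float, float, float]] | None = None,
    mirror_flags: Mapping[str, bool] | None = None,
) -> CorticalSheetModel:
    """Deterministic default layout: V1 plus LM, LI, AL, RL, AMPM.

    The layout is defined in micrometres and converted to pixels, so
    doubling ``um_per_px`` quarters every polygon's pixel area.  V1 is
    strictly the largest patch; the HVAs sit lateral (LM, LI), anterior-
    lateral (AL), anterior (RL) and anterior-medial (AMPM) of it, with
    mirror flags alternating so the field sign flips across each border.
    """
    layout = dict(_DEFAULT_LAYOUT_UM if layout_um is None else layout_um)
    mirrors = dict(_DEFAULT_MIRROR if mirror_flags is None else mirror_flags)
    amps = dict(_DEFAULT_AMPLITUDE)
    if amplitudes:
        amps.update(amplitudes)
    areas = []
    for name in layout:
        x0, x1, y0, y1 = (v / um_per_px for v in layout[name])
        poly = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
        areas.append(AreaSpec(
            name=name, polygon_px=poly, mirror=mirrors[name],
            response_amplitude=amps[name],
        ))
    return CorticalSheetModel(
        field_px=field_px, um_per_px=um_per_px, areas=tuple(areas),
        delay_s=delay_s, baseline_counts=baseline_counts,
        waveform_duty=waveform_duty,
    )


def raised_cosine(tau: np.ndarray, period_s: float, duty: float = 0.5) -> np.ndarray:
    """Unit-peak raised-cosine bump centered at tau = 0 (mod period).

    Support is ``duty * period_s`` wide; zero elsewhere in the cycle.
    """
    tau = np.mod(np.asarray(tau, dtype=float) + period_s / 2, period_s) - period_s / 2
    half = duty * period_s / 2.0
    out = np.where(np.abs(tau) <= half,
                   0.5 * (1.0 + np.cos(np.pi * tau / np.where(half > 0, half, 1.0))),
                   0.0)
    return out


def first_harmonic_factor(duty: float = 0.5, period_s: float = 8.0,
                          n: int = 200_001) -> float:
    """Cosine-amplitude of the waveform's fundamental, by dense quadrature.

    The analysis recovers ``amplitude * first_harmonic_factor`` from the
    Fourier magnitude at the stimulus frequency.
    """
    tau = np.linspace(-period_s / 2, period_s / 2, n)
    w = raised_cosine(tau, period_s, duty)
    integrand = w * np.cos(2 * np.pi * tau / period_s)
    return float(2.0 / period_s * np.trapezoid(integrand, tau))


def _t_pref_image(sheet: CorticalSheetModel, spec: StimulusSpec) -> np.ndarray:
    """Preferred response time (s within cycle) per pixel, NaN outside areas."""
    azi, elev = sheet.retinotopy_images()
    if spec.kind == "bar_azimuth":
        lo, hi = spec.sweep_range_deg
        return (azi - lo) / (hi - lo) * spec.period_s
    if spec.kind == "bar_elevation":
        lo, hi = spec.sweep_range_deg
        return (elev - lo) / (hi - lo) * spec.period_s
    # grating: response locked to motion onset, uniform across the sheet
    onset = motion_onset_time(spec)
    t_pref = np.full(sheet.field_px, np.nan)
    t_pref[np.isfinite(azi)] = onset
    return t_pref


def simulate_movie(
    sheet: CorticalSheetModel,
    spec: StimulusSpec,
    geom: ScreenGeometry | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    frame_rate_hz: float = 30.0,
    chunk_frames: int = 256,
) -> tuple[RawMovie, SimulatedGroundTruth]:
    """Render one stimulus run as a quantized 12-bit movie.

    Per pixel, ``counts(t) = baseline * (1 - a * w((t - t_pref - delay)
    mod P)) + noise(t)``, rounded to integers and clipped to [0, 4095]
    only where noise pushes values past the rails.  ``a = 0`` outside
    every area.  Identical ``seed`` gives bit-identical output.
    """
    noise = noise or NoiseModel.silent()
    if noise.physio_amp > 0:
        ratio = noise.physio_freq_hz * spec.period_s
        if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
            raise ValueError(
                f"physio_freq_hz {noise.physio_freq_hz} is a harmonic of the "
                f"stimulus frequency {1 / spec.period_s}")
    amp = sheet.amplitude_image()
    if sheet.baseline_counts * (1 + amp.max()) > MAX_12BIT + 0.5:
        raise ValueError("baseline + modulation exceeds the 12-bit range")
    if (sheet.baseline_counts * (1 - amp.max())) < 0:
        raise ValueError("modulation amplitude drives counts negative")

    t_pref = _t_pref_image(sheet, spec)
    t_pref_filled = np.nan_to_num(t_pref, nan=0.0)
    inside = np.isfinite(t_pref)
    amp = np.where(inside, amp, 0.0)

    h, w = sheet.field_px
    n_frames = int(round(spec.duration_s * frame_rate_hz))
    dt = 1.0 / frame_rate_hz
    effective_seed = seed if seed is not None else noise.seed
    rng = np.random.default_rng(effective_seed)

    # global nuisance traces, shared by all pixels
    if noise.drift_amp > 0:
        from scipy.ndimage import gaussian_filter1d

        sigma = max(noise.drift_timescale_s * frame_rate_hz, 1.0)
        drift = gaussian_filter1d(rng.standard_normal(n_frames), sigma, mode="wrap")
        drift -= drift.mean()  # center before scaling to the target sd
        sd = drift.std()
        drift = drift / sd * noise.drift_amp if sd > 0 else drift * 0.0
    else:
        drift = np.zeros(n_frames)
    if noise.physio_amp > 0:
        phi = rng.uniform(0, 2 * np.pi)
        times_all = np.arange(n_frames) * dt
        physio = noise.physio_amp * np.sin(2 * np.pi * noise.physio_freq_hz
                                           * times_all + phi)
    else:
        physio = np.zeros(n_frames)

    n_px = h * w
    amp_flat = amp.ravel()
    t_resp_flat = (t_pref_filled + sheet.delay_s).ravel()
    active = np.flatnonzero(amp_flat > 0)  # waveform only where it matters
    data = np.empty((n_px, n_frames), dtype=np.uint16)
    baseline = float(sheet.baseline_counts)

    # the modulation repeats every cycle: evaluate the waveform over one
    # cycle and index it periodically instead of per frame
    fpc = spec.period_s * frame_rate_hz
    frames_per_cycle = int(round(fpc)) if abs(fpc - round(fpc)) < 1e-9 else 0
    wave_cycle = None
    if active.size and frames_per_cycle:
        cyc_times = np.arange(frames_per_cycle) * dt
        tau = cyc_times[None, :] - t_resp_flat[active, None]
        wave_cycle = baseline * amp_flat[active, None] * raised_cosine(
            tau, spec.period_s, sheet.waveform_duty)

    noiseless = (noise.white_sigma == 0 and noise.drift_amp == 0
                 and noise.physio_amp == 0)
    if noiseless and wave_cycle is not None:
        # noise-free: quantize one cycle and tile it
        data[:] = np.uint16(baseline + 0.5)
        cycle = np.clip(baseline - wave_cycle, 0.0, MAX_12BIT)
        cycle_u16 = (cycle + 0.5).astype(np.uint16)
        for start in range(0, n_frames, frames_per_cycle):
            stop = min(start + frames_per_cycle, n_frames)
            data[active, start:stop] = cycle_u16[:, :stop - start]
        return _finalize_movie(data.reshape(h, w, n_frames), sheet, spec, geom,
                               frame_rate_hz, effective_seed, t_pref, amp)

    for start in range(0, n_frames, chunk_frames):
        stop = min(start + chunk_frames, n_frames)
        counts = np.full((n_px, stop - start), baseline)
        if active.size:
            if wave_cycle is not None:
                idx = np.arange(start, stop) % frames_per_cycle
                counts[active] -= wave_cycle[:, idx]
            else:
                times = np.arange(start, stop) * dt
                tau = times[None, :] - t_resp_flat[active, None]
                counts[active] -= baseline * amp_flat[active, None] * raised_cosine(
                    tau, spec.period_s, sheet.waveform_duty)
        counts += (drift + physio)[None, start:stop]
        if noise.white_sigma > 0:
            counts += rng.normal(0.0, noise.white_sigma, size=counts.shape)
        np.clip(counts, 0.0, MAX_12BIT, out=counts)
        data[:, start:stop] = (counts + 0.5).astype(np.uint16)  # round half up
    return _finalize_movie(data.reshape(h, w, n_frames), sheet, spec, geom,
                           frame_rate_hz, effective_seed, t_pref, amp)


def _finalize_movie(data, sheet, spec, geom, frame_rate_hz, effective_seed,
                    t_pref, amp):
    movie = RawMovie(data=data, frame_rate_hz=frame_rate_hz, stimulus=spec,
                     geometry=geom, meta={"simulated": True, "seed": effective_seed})
    azi, elev = sheet.retinotopy_images()
    truth = SimulatedGroundTruth(
        sheet=sheet,
        label_image=sheet.label_image(),
        label_names=sheet.label_names(),
        azimuth_deg=azi,
        elevation_deg=elev,
        t_pref_s=t_pref,
        amplitude=amp,
        true_amplitude_by_area={a.name: a.response_amplitude for a in sheet.areas},
        delay_s=sheet.delay_s,
        seed=effective_seed,
    )
    return movie, truth


def simulate_animal_movies(
    sheet: CorticalSheetModel,
    specs: Mapping[str, StimulusSpec],
    noise: NoiseModel | None = None,
    seed: int | None = None,
    geom: ScreenGeometry | None = None,
) -> tuple[dict[str, RawMovie], SimulatedGroundTruth]:
    """Simulate the standard three runs (azimuth bar, elevation bar, grating).

    Each run gets an independent noise stream derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    movies: dict[str, RawMovie] = {}
    truth = None
    for child, (name, spec) in zip(ss.spawn(len(specs)), specs.items()):
        run_seed = int(child.generate_state(1)[0]) if seed is not None else None
        movies[name], truth = simulate_movie(sheet, spec, geom=geom, noise=noise,
                                             seed=run_seed)
    return movies, truth


# ---------------------------------------------------------------------------
# cohort-level generator (no imaging)

GENOTYPES = ("WT", "Het", "KO")
SEXES = ("M", "F")
AGE_GROUPS = ("P17", "P30", "P100")

_AGE_DAYS = {"P17": 17, "P30": 31, "P100": 101}


@dataclass(frozen=True)
class CohortDesign:
    """Factorial design for response-level simulation.

    ``cell_means[cell][area]`` is the programmed mean normalized amplitude
    for the factor-level combination ``cell`` (a tuple aligned with
    ``factors``); ``n_per_cell[cell]`` its sample size.  Between-animal
    noise is Gaussian with sd ``animal_sd``, truncated at zero.
    """

    factors: tuple[str, ...]
    levels: Mapping[str, tuple[str, ...]]
    n_per_cell: Mapping[tuple[str, ...], int]
    cell_means: Mapping[tuple[str, ...], Mapping[str, float]]
    animal_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        valid = {"genotype": GENOTYPES, "sex": SEXES, "age_group": AGE_GROUPS}
        for f in self.factors:
            if f not in valid:
                raise ValueError(f"unknown factor {f!r}")
            for lvl in self.levels[f]:
                if lvl not in valid[f]:
                    raise ValueError(f"unknown level {lvl!r} for factor {f!r}")
        for cell, n in self.n_per_cell.items():
            if n < 2:
                raise ValueError(f"cell {cell} needs n >= 2, got {n}")
        for cell, means in self.cell_means.items():
            for area, m in means.items():
                if m <= 0:
                    raise ValueError(f"mean for {cell}/{area} must be > 0")
        if self.animal_sd < 0:
            raise ValueError("animal_sd must be >= 0")

    @classmethod
    def one_way_genotype(
        cls,
        means_by_genotype: Mapping[str, Mapping[str, float]],
        n: int = 7,
        sex: str = "M",
        age_group: str = "P100",
        animal_sd: float = 0.1,
        seed: int | None = None,
    ) -> "CohortDesign":
        """Adult single-sex design: one factor (genotype), n per genotype."""
        genotypes = tuple(means_by_genotype)
        return cls(
            factors=("genotype",),
            levels={"genotype": genotypes, "sex": (sex,), "age_group": (age_group,)},
            n_per_cell={(g,): n for g in genotypes},
            cell_means={(g,): dict(means_by_genotype[g]) for g in genotypes},
            animal_sd=animal_sd,
            seed=seed,
        )

    def cells(self) -> list[tuple[str, ...]]:
        out: list[tuple[str, ...]] = [()]
        for f in self.factors:
            out = [c + (lvl,) for c in out for lvl in self.levels[f]]
        return out


def simulate_cohort_responses(design: CohortDesign,
                              seed: int | None = None) -> pd.DataFrame:
    """Draw per-animal normalized amplitudes around the programmed cell means.

    Returns a tidy table with one row per animal: factor columns, weight
    and age covariates, and one ``norm_<area>`` column per area.
    """
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    fixed = {f: design.levels[f][0]
             for f in ("genotype", "sex", "age_group") if f not in design.factors}
    rows = []
    animal = 0
    for cell in design.cells():
        means = design.cell_means[cell]
        n = design.n_per_cell[cell]
        info = dict(zip(design.factors, cell))
        info.update(fixed)
        for _ in range(n):
            animal += 1
            sex = info["sex"]
            weight = rng.normal(26.0 if sex == "M" else 21.0, 1.5)
            age = _AGE_DAYS[info["age_group"]] + rng.integers(0, 4)
            row = {
                "animal_id": f"sim{animal:03d}",
                "genotype": info["genotype"],
                "sex": sex,
                "age_group": info["age_group"],
                "weight_g": round(float(weight), 2),
                "age_days": int(age),
            }
            for area, mean in means.items():
                value = mean + rng.normal(0.0, design.animal_sd)
                row[f"norm_{area}"] = max(value, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
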