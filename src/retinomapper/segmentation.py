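"""Area segmentation from retinotopy: field sign and reversal-based labels.

The border between a visual area and its mirror-image neighbour is a
reversal in the progression of retinotopy; the visual field sign — the
sign of the z-component of the cross product of the azimuth and elevation
gradients (the retinotopic Jacobian) — flips exactly at such reversals,
so connected patches of constant sign are the automated counterpart of
manual border drawing.  Manual label masks can still be imported.

Area naming is geometric: the largest patch is V1; the rest are matched
to a template of expected positions relative to the V1 centroid (LM
lateral-posterior, LI further lateral, AL anterior-lateral, RL anterior,
AMPM anterior-medial), assuming anterior is up (-y) and medial is +x
(configurable via ``medial_positive_x``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .fourier_mapping import RetinotopyPair

__all__ = ["FieldSignMap", "AreaLabelMap", "field_sign", "segment_areas",
           "import_labels", "export_labels", "dice_by_area"]

logger = logging.getLogger(__name__)

HVA_NAMES = ("LM", "LI", "AL", "RL", "AMPM")

#: Expected HVA centroid offsets from the V1 centroid, in units of the
#: V1 equivalent radius (sqrt of V1 pixel area); (dx, dy) with +x medial,
#: +y posterior.  Derived from the canonical mouse HVA arrangement.
DEFAULT_TEMPLATE: dict[str, tuple[float, float]] = {
    "LM": (-0.9, 0.3),
    "LI": (-1.5, 0.0),
    "AL": (-0.85, -0.65),
    "RL": (-0.15, -1.15),
    "AMPM": (0.5, -1.05),
}


@dataclass
class FieldSignMap:
    """Per-pixel field sign in {-1, 0, +1}; 0 marks low-confidence pixels."""

    sign: np.ndarray
    smooth_sigma_px: float


@dataclass
class AreaLabelMap:
    """Integer label image plus label -> area-name table."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        if 0 not in self.names:
            self.names[0] = "background"
        seen: dict[str, int] = {}
        for lbl, name in self.names.items():
            if name != "background" and name in seen:
                raise ValueError(f"duplicate area name {name!r} "
                                 f"(labels {seen[name]} and {lbl})")
            seen[name] = lbl

    def label_of(self, name: str) -> int | None:
        for lbl, n in self.names.items():
            if n == name:
                return lbl
        return None

    def mask_of(self, name: str) -> np.ndarray:
        lbl = self.label_of(name)
        if lbl is None:
            raise KeyError(f"no area named {name!r}")
        return self.labels == lbl

    def area_names(self) -> list[str]:
        return [n for n in self.names.values() if n != "background"]


def _masked_smooth(img: np.ndarray, sigma: float, mask: np.ndarray) -> np.ndarray:
    """Gaussian smoothing that ignores (and extrapolates over) masked-out pixels."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(img * m, sigma, mode="nearest")
    den = ndimage.gaussian_filter(m, sigma, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.nan_to_num(out, nan=0.0)


def field_sign(retino: RetinotopyPair, smooth_sigma_px: float = 2.0,
               noise_floor: float = 0.0,
               mask: np.ndarray | None = None) -> FieldSignMap:
    """Sign of the retinotopic Jacobian after Gaussian smoothing.

    ``cross = dAzi/dx * dElev/dy - dAzi/dy * dElev/dx``; pixels with
    ``|cross| <= noise_floor`` are set to 0.  With ``mask`` the smoothing
    is mask-weighted (normalized convolution), so meaningless retinotopy
    outside the responsive region cannot corrupt gradients at area edges.
    An all-constant input yields an all-zero map (logged, not an error).
    """
    azi_in = np.asarray(retino.azimuth_deg, dtype=float)
    elev_in = np.asarray(retino.elevation_deg, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        azi = _masked_smooth(azi_in, smooth_sigma_px, mask)
        elev = _masked_smooth(elev_in, smooth_sigma_px, mask)
        # gradients must not read extrapolated values outside the mask:
        # NaNs there zero out a 1-px ring at mask borders via the stencil
        azi[~mask] = np.nan
        elev[~mask] = np.nan
    else:
        azi = ndimage.gaussian_filter(azi_in, smooth_sigma_px, mode="nearest")
        elev = ndimage.gaussian_filter(elev_in, smooth_sigma_px, mode="nearest")
    dazi_dy, dazi_dx = np.gradient(azi)
    delev_dy, delev_dx = np.gradient(elev)
    with np.errstate(invalid="ignore"):
        cross = dazi_dx * delev_dy - dazi_dy * delev_dx
        sign = np.sign(np.nan_to_num(cross, nan=0.0)).astype(np.int8)
        sign[np.abs(np.nan_to_num(cross, nan=0.0)) <= noise_floor] = 0
    if not sign.any():
        logger.warning("field sign is zero everywhere (constant retinotopy?)")
    return FieldSignMap(sign=sign, smooth_sigma_px=smooth_sigma_px)


def _name_components(
    comp_labels: np.ndarray,
    component_ids: list[int],
    v1_id: int,
    template: dict[str, tuple[float, float]],
    medial_positive_x: bool,
) -> dict[int, str]:
    """Assign HVA names to components by nearest-template matching."""
    centroids = {cid: ndimage.center_of_mass(comp_labels == cid)
                 for cid in component_ids}
    v1_area = int((comp_labels == v1_id).sum())
    scale = float(np.sqrt(v1_area))
    cy, cx = centroids[v1_id]
    hvas = [cid for cid in component_ids if cid != v1_id]
    names = {v1_id: "V1"}
    if not hvas:
        return names
    template_names = list(template)
    cost = np.zeros((len(hvas), len(template_names)))
    for i, cid in enumerate(hvas):
        yy, xx = centroids[cid]
        dx = (xx - cx) / scale
        if not medial_positive_x:
            dx = -dx
        dy = (yy - cy) / scale
        for j, tname in enumerate(template_names):
            tx, ty = template[tname]
            cost[i, j] = np.hypot(dx - tx, dy - ty)
    rows, cols = linear_sum_assignment(cost)
    for i, j in zip(rows, cols):
        names[hvas[i]] = template_names[j]
    for cid in hvas:
        if cid not in names:
            logger.warning("component %d unassignable to any template area; "
                           "labeling as background", cid)
            names[cid] = "background"
    return names


def segment_areas(
    fs: FieldSignMap,
    responsive_mask: np.ndarray,
    min_size_px: int = 100,
    template: dict[str, tuple[float, float]] | None = None,
    medial_positive_x: bool = True,
    fill_mask: bool = True,
) -> AreaLabelMap:
    """Partition the responsive mask into named areas.

    Connected components of constant nonzero field sign within the mask
    are extracted, size-filtered, and named: the largest is V1, the rest
    by template position relative to the V1 centroid.  With ``fill_mask``
    every responsive pixel is assigned to its nearest component, undoing
    the erosion the field-sign smoothing causes at patch edges.
    """
    responsive_mask = np.asarray(responsive_mask, dtype=bool)
    if not responsive_mask.any():
        raise ValueError("responsive mask is empty")
    template = DEFAULT_TEMPLATE if template is None else template

    comp_labels = np.zeros(fs.sign.shape, dtype=np.int32)
    next_id = 1
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for s in (-1, 1):
        lab, n = ndimage.label((fs.sign == s) & responsive_mask, structure=structure)
        for i in range(1, n + 1):
            comp = lab == i
            if comp.sum() >= min_size_px:
                comp_labels[comp] = next_id
                next_id += 1
    component_ids = list(range(1, next_id))
    if not component_ids:
        raise ValueError(
            f"no field-sign components of at least {min_size_px} px found")

    sizes = {cid: int((comp_labels == cid).sum()) for cid in component_ids}
    v1_id = max(sizes, key=sizes.get)

    if fill_mask:
        # grow components over the whole mask: nearest-component assignment
        missing = responsive_mask & (comp_labels == 0)
        if missing.any():
            _, (iy, ix) = ndimage.distance_transform_edt(
                comp_labels == 0, return_indices=True)
            comp_labels[missing] = comp_labels[iy[missing], ix[missing]]

    names_by_component = _name_components(comp_labels, component_ids, v1_id,
                                          template, medial_positive_x)
    # compact labels: V1 first, then template order, drop background comps
    order = ["V1"] + [n for n in template if n in names_by_component.values()]
    labels = np.zeros_like(comp_labels)
    names: dict[int, str] = {0: "background"}
    for new_id, area_name in enumerate(order, start=1):
        cids = [c for c, n in names_by_component.items() if n == area_name]
        for cid in cids:
            labels[comp_labels == cid] = new_id
        names[new_id] = area_name
    return AreaLabelMap(labels=labels, names=names)


def export_labels(label_map: AreaLabelMap, tif_path: str | Path) -> None:
    """Write labels as an integer TIFF plus a JSON name table alongside."""
    import tifffile

    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, label_map.labels.astype(np.int32))
    name_path = tif_path.with_suffix(".json")
    name_path.write_text(json.dumps({str(k): v for k, v in label_map.names.items()},
                                    indent=1))


def import_labels(tif_path: str | Path, merge_ampm: bool = True) -> AreaLabelMap:
    """Read a label TIFF + JSON name table (e.g. manually drawn ROIs).

    With ``merge_ampm``, separate AM and PM labels are combined into a
    single AMPM label.  The table must include V1 (required downstream
    for normalization) and must not repeat names.
    """
    import tifffile

    tif_path = Path(tif_path)
    labels = tifffile.imread(tif_path)
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise ValueError("label image has non-integer pixel values")
        labels = np.round(labels).astype(np.int32)
    names_raw = json.loads(tif_path.with_suffix(".json").read_text())
    names = {int(k): v for k, v in names_raw.items()}

    if merge_ampm and ("AM" in names.values() or "PM" in names.values()):
        am_pm = [lbl for lbl, n in names.items() if n in ("AM", "PM")]
        keep = min(am_pm)
        labels = labels.copy()
        for lbl in am_pm:
            if lbl != keep:
                labels[labels == lbl] = keep
                del names[lbl]
        names[keep] = "AMPM"

    label_map = AreaLabelMap(labels=labels, names=names)
    if label_map.label_of("V1") is None:
        raise ValueError("name table has no V1 label; V1 is required for "
                         "normalization")
    return label_map


def dice_by_area(predicted: AreaLabelMap, truth_labels: np.ndarray,
                 truth_names: dict[int, str]) -> dict[str, float]:
    """Per-area Dice overlap between a segmentation and ground truth."""
    out: dict[str, float] = {}
    for lbl, name in truth_names.items():
        if name == "background":
            continue
        t = truth_labels == lbl
        p_lbl = predicted.label_of(name)
        p = (predicted.labels == p_lbl) if p_lbl is not None else np.zeros_like(t)
        denom = t.sum() + p.sum()
        out[name] = float(2.0 * (t & p).sum() / denom) if denom else 0.0
    return out
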