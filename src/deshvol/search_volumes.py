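"""Rule-based construction of the three CSF search volumes.

The qDESH workflow searches for CSF inside three anatomically defined
regions, all expressed relative to the posterior commissure (PC) on an
ACPC-aligned volume:

* **coronal band** — the slab of coronal slices from the PC to 20 mm
  anterior of it (half-open: the PC slice is included, the far edge is not);
  both the high-convexity and Sylvian-fissure search volumes live inside it.
* **high convexities (HC)** — the topmost cranial 30 cm^3 of combined
  CSF + brain (the intracranial mask) within the band, accumulated whole
  axial layer by whole axial layer from the vertex downward.
* **Sylvian fissures (SF)** — per hemisphere, the part of the band within
  +/-10 mm (the opercular margin) of the Sylvian-fissure center height,
  lateral to a medial limit placed at the lateral-most convexity of the
  cerebellar hemisphere; the dura (head-mask boundary) is the outer limit.
* **lateral ventricle (LV)** — a flood fill (6-connected region growing
  under the CSF intensity predicate) from a seed voxel inside a ventricle.

Landmarks (PC, SF center height, medial limits, LV seed) are inputs — the
workflow is semiautomatic by design, and the phantom generator knows its own
landmarks exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging_io import BinaryMask, ImageVolume, read_mask, write_mask

__all__ = [
    "SearchVolumeSpec",
    "SearchVolumeSet",
    "coronal_band",
    "build_hc_search_volume",
    "build_sf_search_volume",
    "flood_fill_lv",
    "build_search_volumes",
    "load_manual_rois",
    "save_rois",
]

_FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)  # 6-neighborhood


@dataclass
class SearchVolumeSpec:
    """Geometric parameters of the rule-based search volumes.

    ``sf_center_z_mm`` and ``medial_limit_x_mm`` map hemisphere label
    ("left"/"right") to a physical coordinate in mm (voxel center = index x
    spacing). ``lv_seed`` is a voxel coordinate inside a lateral ventricle.
    """

    sf_center_z_mm: dict = field(default_factory=dict)
    medial_limit_x_mm: dict = field(default_factory=dict)
    lv_seed: tuple[int, int, int] | None = None
    band_length_mm: float = 20.0
    hc_target_cm3: float = 30.0
    opercular_half_height_mm: float = 10.0

    def __post_init__(self):
        if self.band_length_mm <= 0:
            raise ValueError("band_length_mm must be positive")
        if self.hc_target_cm3 <= 0:
            raise ValueError("hc_target_cm3 must be positive")
        if self.opercular_half_height_mm <= 0:
            raise ValueError("opercular_half_height_mm must be positive")

    def to_dict(self) -> dict:
        return {
            "band_length_mm": self.band_length_mm,
            "hc_target_cm3": self.hc_target_cm3,
            "opercular_half_height_mm": self.opercular_half_height_mm,
            "sf_center_z_mm": dict(self.sf_center_z_mm),
            "medial_limit_x_mm": dict(self.medial_limit_x_mm),
            "lv_seed": list(self.lv_seed) if self.lv_seed is not None else None,
        }


@dataclass
class SearchVolumeSet:
    """The three search volumes plus how each was obtained."""

    hc_mask: BinaryMask
    sf_mask: BinaryMask
    lv_mask: BinaryMask
    provenance: dict = field(
        default_factory=lambda: {"hc": "rule_based", "sf": "rule_based",
                                 "lv": "rule_based"}
    )
    hc_achieved_cm3: float | None = None

    def union(self) -> BinaryMask:
        return self.hc_mask.union(self.sf_mask).union(self.lv_mask)


def coronal_band(image: ImageVolume, band_length_mm: float = 20.0) -> BinaryMask:
    """Mask of voxels with y-center in ``[y_PC, y_PC + band_length_mm)``.

    At 1 mm spacing and the default 20 mm length this is exactly 20 coronal
    slices starting at the PC slice.
    """
    pc = image.require_pc()
    sy = image.spacing[1]
    y_pc = pc[1] * sy
    y = image.axis_coords_mm(1)
    if y_pc + band_length_mm > image.shape[1] * sy:
        raise ValueError(
            f"coronal band [{y_pc}, {y_pc + band_length_mm}) mm extends past the grid"
        )
    in_band = (y >= y_pc) & (y < y_pc + band_length_mm)
    data = np.zeros(image.shape, dtype=bool)
    data[:, in_band, :] = True
    return BinaryMask(data, image.spacing)


def build_hc_search_volume(
    intracranial_mask: BinaryMask,
    band: BinaryMask,
    target_cm3: float = 30.0,
) -> tuple[BinaryMask, float, int]:
    """Topmost cranial ``target_cm3`` of intracranial volume within the band.

    Whole axial layers are accumulated from the most superior layer downward
    while the running volume stays below the target; the first layer that
    reaches or crosses the target is included iff doing so leaves the
    achieved volume closer to the target than leaving it out.

    Returns ``(mask, achieved_cm3, n_layers)``; the achieved volume can
    differ from the target by at most one axial layer.
    """
    intracranial_mask.check_compatible(band)
    region = intracranial_mask.data & band.data
    voxvol_cm3 = np.prod(intracranial_mask.spacing) / 1000.0
    layer_counts = region.sum(axis=(0, 1))
    total = float(layer_counts.sum()) * voxvol_cm3
    if total < target_cm3:
        raise ValueError(
            f"head too small for requested HC volume: {total:.3f} cm^3 available "
            f"inside the band, {target_cm3:.3f} cm^3 requested"
        )
    out = np.zeros_like(region)
    cumulative = 0.0
    n_layers = 0
    for z in range(region.shape[2] - 1, -1, -1):
        layer_cm3 = float(layer_counts[z]) * voxvol_cm3
        if cumulative + layer_cm3 < target_cm3:
            if layer_counts[z]:
                out[:, :, z] = region[:, :, z]
                n_layers += 1
            cumulative += layer_cm3
            continue
        # this layer reaches/crosses the target: nearest-to-target rule
        if abs(cumulative + layer_cm3 - target_cm3) < abs(cumulative - target_cm3):
            out[:, :, z] = region[:, :, z]
            cumulative += layer_cm3
            n_layers += 1
        break
    return BinaryMask(out, intracranial_mask.spacing), cumulative, n_layers


def build_sf_search_volume(
    band: BinaryMask,
    head_mask: BinaryMask,
    spec: SearchVolumeSpec,
) -> BinaryMask:
    """Sylvian-fissure search volume: opercular margin x medial limit, per side.

    For each hemisphere, voxels inside ``band & head`` whose z-center lies
    within ``+/-opercular_half_height_mm`` (inclusive) of the fissure center
    height and whose x-center is lateral to the medial limit (``<=`` for the
    left side, ``>=`` for the right). The head mask's boundary (the dura) is
    the outer limit. The two hemispheric regions are disjoint because the
    left medial limit lies medial-ward of the right one.
    """
    band.check_compatible(head_mask)
    for side in ("left", "right"):
        if side not in spec.sf_center_z_mm or side not in spec.medial_limit_x_mm:
            raise ValueError(f"missing Sylvian-fissure geometry for {side} hemisphere")
    if not spec.medial_limit_x_mm["left"] < spec.medial_limit_x_mm["right"]:
        raise ValueError("left medial limit must be less than right medial limit")

    sx, _, sz = band.spacing
    nx, _, nz = band.shape
    x = np.arange(nx) * sx
    z = np.arange(nz) * sz
    base = band.data & head_mask.data
    out = np.zeros_like(base)
    for side in ("left", "right"):
        center = spec.sf_center_z_mm[side]
        z_ok = np.abs(z - center) <= spec.opercular_half_height_mm
        if side == "left":
            x_ok = x <= spec.medial_limit_x_mm["left"]
        else:
            x_ok = x >= spec.medial_limit_x_mm["right"]
        hemi = base & x_ok[:, None, None] & z_ok[None, None, :]
        if not hemi.any():
            raise ValueError(
                f"empty {side} Sylvian-fissure search volume — center height "
                f"{center} mm outside the head or medial limit too lateral"
            )
        out |= hemi
    return BinaryMask(out, band.spacing)


def flood_fill_lv(
    image: ImageVolume,
    seed: tuple[int, int, int],
    threshold: float,
) -> BinaryMask:
    """Lateral-ventricle search volume by 6-connected flood fill.

    Grows the connected component of ``{intensity < threshold}`` containing
    the seed voxel. Face connectivity (no diagonal adjacency) prevents
    leakage through thin sub-voxel walls.
    """
    seed = tuple(int(c) for c in seed)
    data = np.asarray(image.data)
    if any(not (0 <= c < n) for c, n in zip(seed, data.shape)):
        raise ValueError(f"seed {seed} outside grid {data.shape}")
    if not data[seed] < threshold:
        raise ValueError(
            f"seed is not CSF-like: intensity {data[seed]} >= threshold {threshold}"
        )
    below = data < threshold
    labels, _ = ndimage.label(below, structure=_FACE_CONNECTIVITY)
    return BinaryMask(labels == labels[seed], image.spacing)


def build_search_volumes(
    image: ImageVolume,
    intracranial_mask: BinaryMask,
    spec: SearchVolumeSpec,
    n_bins: int | None = None,
    window_bins: int | None = None,
) -> SearchVolumeSet:
    """Construct all three rule-based search volumes.

    The LV flood fill needs a CSF threshold before the final threshold
    (which is defined over the union of all three volumes) exists, so a
    provisional threshold is computed from the SF+HC union first and used
    only to grow the ventricle region; the definitive threshold is then
    recomputed downstream over the full union.
    """
    from . import thresholding as th

    if spec.lv_seed is None:
        raise ValueError("lv_seed required for rule-based search volumes")
    band = coronal_band(image, spec.band_length_mm)
    hc_mask, achieved, _ = build_hc_search_volume(
        intracranial_mask, band, spec.hc_target_cm3
    )
    sf_mask = build_sf_search_volume(band, intracranial_mask, spec)
    provisional = th.compute_threshold(
        image,
        hc_mask.union(sf_mask),
        n_bins=n_bins or th.DEFAULT_N_BINS,
        window_bins=window_bins or th.DEFAULT_WINDOW_BINS,
    )
    lv_mask = flood_fill_lv(image, spec.lv_seed, provisional.threshold)
    return SearchVolumeSet(
        hc_mask=hc_mask,
        sf_mask=sf_mask,
        lv_mask=lv_mask,
        hc_achieved_cm3=achieved,
    )


_ROI_FILES = {"hc": "hc.nii.gz", "sf": "sf.nii.gz", "lv": "lv.nii.gz"}


def save_rois(svs: SearchVolumeSet, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, fname in _ROI_FILES.items():
        write_mask(getattr(svs, f"{key}_mask"), out_dir / fname)


def load_manual_rois(
    image: ImageVolume,
    hc_path,
    sf_path,
    lv_path,
    band: BinaryMask | None = None,
    band_mode: str = "verify",
) -> SearchVolumeSet:
    """Load manually drawn (or previously saved) search-volume masks.

    ``band_mode``: "verify" rejects HC/SF masks with voxels outside the
    coronal band; "clip" intersects them with the band instead.
    """
    if band_mode not in ("verify", "clip"):
        raise ValueError("band_mode must be 'verify' or 'clip'")
    ref = BinaryMask(np.zeros(image.shape, dtype=bool), image.spacing)
    masks = {}
    for key, path in (("hc", hc_path), ("sf", sf_path), ("lv", lv_path)):
        mask = read_mask(path)
        mask.check_compatible(ref)
        if mask.n_voxels == 0:
            raise ValueError(f"manual {key} mask is empty: {path}")
        masks[key] = mask
    if band is not None:
        for key in ("hc", "sf"):
            outside = masks[key].data & ~band.data
            if outside.any():
                if band_mode == "verify":
                    raise ValueError(
                        f"manual {key} mask has {int(outside.sum())} voxels "
                        "outside the coronal band"
                    )
                masks[key] = masks[key].intersect(band)
    return SearchVolumeSet(
        hc_mask=masks["hc"],
        sf_mask=masks["sf"],
        lv_mask=masks["lv"],
        provenance={"hc": "manual", "sf": "manual", "lv": "manual"},
        hc_achieved_cm3=masks["hc"].volume_cm3,
    )
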