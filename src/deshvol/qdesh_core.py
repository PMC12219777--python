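"""CSF segmentation, the qDESH ratio, and the per-coronal-slice profile.

qDESH is the ratio of CSF volume found in the Sylvian-fissure search volume
to CSF volume found in the high-convexity search volume,

    qDESH = V_CSF-SF / V_CSF-HC ,

computed after a single subject-specific global threshold (midway between
the CSF and gray-matter histogram peaks over the union of all three search
volumes) classifies every search-volume voxel as CSF or not. A qDESH above
1 indicates Sylvian-fissure dilation out of proportion to the high-convexity
CSF — the disproportion that defines DESH. The lateral-ventricle CSF volume
is computed and reported but never enters the ratio.

A per-slice profile (one qDESH per coronal millimetre of the band) shows
how strongly a single-slice assessment depends on where the slice is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import BinaryMask, ImageVolume
from .search_volumes import SearchVolumeSet, SearchVolumeSpec, build_search_volumes
from .thresholding import DEFAULT_N_BINS, DEFAULT_WINDOW_BINS, ThresholdResult, compute_threshold

__all__ = [
    "SliceProfile",
    "QDESHResult",
    "segment_csf",
    "compute_qdesh",
    "slice_profile",
    "run_pipeline",
]


@dataclass
class SliceProfile:
    """Per-coronal-slice CSF volumes and qDESH within the band.

    ``qdesh_slice`` entries are ``None`` exactly where the slice contains no
    high-convexity CSF; the summary statistics are over defined entries only.
    Slice volumes sum exactly (voxel-count conservation) to the global ones.
    """

    slice_index: list[int]
    mm_from_pc: list[float]
    v_sf_slice: list[float]  # cm^3
    v_hc_slice: list[float]  # cm^3
    qdesh_slice: list[float | None]

    @property
    def n_defined(self) -> int:
        return sum(q is not None for q in self.qdesh_slice)

    @property
    def mean_qdesh_slice(self) -> float | None:
        vals = [q for q in self.qdesh_slice if q is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def sd_qdesh_slice(self) -> float | None:
        vals = [q for q in self.qdesh_slice if q is not None]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else None

    def to_dict(self) -> dict:
        return {
            "slice_index": list(self.slice_index),
            "mm_from_pc": [float(v) for v in self.mm_from_pc],
            "v_sf_slice_cm3": [float(v) for v in self.v_sf_slice],
            "v_hc_slice_cm3": [float(v) for v in self.v_hc_slice],
            "qdesh_slice": [None if q is None else float(q) for q in self.qdesh_slice],
            "n_defined": self.n_defined,
            "mean_qdesh_slice": self.mean_qdesh_slice,
            "sd_qdesh_slice": self.sd_qdesh_slice,
        }

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "slice_index": self.slice_index,
                "mm_from_pc": self.mm_from_pc,
                "v_sf_cm3": self.v_sf_slice,
                "v_hc_cm3": self.v_hc_slice,
                "qdesh_slice": [np.nan if q is None else q for q in self.qdesh_slice],
            }
        )


@dataclass
class QDESHResult:
    """All quantities the pipeline reports for one subject/phantom."""

    v_csf_sf: float  # cm^3
    v_csf_hc: float  # cm^3
    v_lv: float  # cm^3
    qdesh: float
    threshold: ThresholdResult
    hc_achieved_cm3: float | None
    profile: SliceProfile
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "v_csf_sf_cm3": float(self.v_csf_sf),
            "v_csf_hc_cm3": float(self.v_csf_hc),
            "v_lv_cm3": float(self.v_lv),
            "qdesh": float(self.qdesh),
            "hc_achieved_cm3": None
            if self.hc_achieved_cm3 is None
            else float(self.hc_achieved_cm3),
            "threshold": self.threshold.to_dict(),
            "profile": self.profile.to_dict(),
            "config": dict(self.config),
        }


def segment_csf(
    image: ImageVolume, mask: BinaryMask, threshold: float
) -> tuple[BinaryMask, float]:
    """CSF voxels inside ``mask``: intensity strictly below the threshold.

    Returns the segmented mask and its volume in cm^3 (voxel count x voxel
    volume / 1000). An empty result warns but is not an error.
    """
    ref = BinaryMask(np.zeros(image.shape, dtype=bool), image.spacing)
    mask.check_compatible(ref)
    seg = BinaryMask(mask.data & (np.asarray(image.data) < threshold), image.spacing)
    if seg.n_voxels == 0:
        warnings.warn("no CSF voxels below threshold inside mask", stacklevel=2)
    return seg, seg.volume_cm3


def compute_qdesh(v_csf_sf: float, v_csf_hc: float) -> float:
    """qDESH = V_CSF-SF / V_CSF-HC, the exact quotient."""
    if v_csf_sf < 0 or v_csf_hc < 0:
        raise ValueError("CSF volumes must be non-negative")
    if v_csf_hc == 0:
        raise ValueError("undefined qDESH (no high-convexity CSF detected)")
    return v_csf_sf / v_csf_hc


def slice_profile(
    image: ImageVolume,
    sf_mask: BinaryMask,
    hc_mask: BinaryMask,
    threshold: float,
) -> SliceProfile:
    """qDESH_slice for every coronal slice spanned by the search volumes.

    The slice range is the contiguous y-extent of ``sf_mask | hc_mask`` (the
    coronal band for rule-based volumes); ``mm_from_pc`` uses the image's PC
    landmark when available, otherwise the first profiled slice as origin.
    """
    sf_mask.check_compatible(hc_mask)
    sf_seg, _ = segment_csf(image, sf_mask, threshold)
    hc_seg, _ = segment_csf(image, hc_mask, threshold)
    occupied = np.flatnonzero((sf_mask.data | hc_mask.data).any(axis=(0, 2)))
    if occupied.size == 0:
        raise ValueError("empty search volumes — no slices to profile")
    y0, y1 = int(occupied[0]), int(occupied[-1])
    sy = image.spacing[1]
    origin = image.pc_index[1] if image.pc_index is not None else y0
    voxvol_cm3 = image.voxel_volume_mm3 / 1000.0

    idx, mm, v_sf, v_hc, q = [], [], [], [], []
    for y in range(y0, y1 + 1):
        vs = float(sf_seg.data[:, y, :].sum()) * voxvol_cm3
        vh = float(hc_seg.data[:, y, :].sum()) * voxvol_cm3
        idx.append(y)
        mm.append((y - origin) * sy)
        v_sf.append(vs)
        v_hc.append(vh)
        q.append(None if vh == 0 else vs / vh)
    return SliceProfile(idx, mm, v_sf, v_hc, q)


def run_pipeline(
    image: ImageVolume,
    search_volumes: SearchVolumeSet | SearchVolumeSpec,
    intracranial_mask: BinaryMask | None = None,
    n_bins: int = DEFAULT_N_BINS,
    window_bins: int = DEFAULT_WINDOW_BINS,
) -> QDESHResult:
    """Full qDESH computation for one subject.

    Steps: construct (or accept) the three search volumes; compute the
    global threshold over their union; segment CSF in each; form the qDESH
    ratio; profile it per coronal slice. Deterministic for fixed inputs.

    ``search_volumes`` may be a ready :class:`SearchVolumeSet` (e.g. loaded
    manual ROIs) or a :class:`SearchVolumeSpec`, in which case
    ``intracranial_mask`` (combined CSF + brain) is required to build the
    rule-based volumes.
    """
    if isinstance(search_volumes, SearchVolumeSpec):
        if intracranial_mask is None:
            raise ValueError(
                "intracranial_mask required to build rule-based search volumes"
            )
        svs = build_search_volumes(
            image, intracranial_mask, search_volumes,
            n_bins=n_bins, window_bins=window_bins,
        )
        spec_echo = search_volumes.to_dict()
    else:
        svs = search_volumes
        spec_echo = None

    thr = compute_threshold(image, svs.union(), n_bins=n_bins, window_bins=window_bins)
    _, v_sf = segment_csf(image, svs.sf_mask, thr.threshold)
    _, v_hc = segment_csf(image, svs.hc_mask, thr.threshold)
    _, v_lv = segment_csf(image, svs.lv_mask, thr.threshold)
    qdesh = compute_qdesh(v_sf, v_hc)
    profile = slice_profile(image, svs.sf_mask, svs.hc_mask, thr.threshold)
    return QDESHResult(
        v_csf_sf=v_sf,
        v_csf_hc=v_hc,
        v_lv=v_lv,
        qdesh=qdesh,
        threshold=thr,
        hc_achieved_cm3=svs.hc_achieved_cm3,
        profile=profile,
        config={
            "n_bins": n_bins,
            "window_bins": window_bins,
            "provenance": dict(svs.provenance),
            "search_volume_spec": spec_echo,
        },
    )
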