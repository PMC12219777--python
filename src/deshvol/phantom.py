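"""Synthetic ACPC-aligned head phantoms with known CSF compartments.

The phantom emulates the features of a bias-corrected T1 head image that
the qDESH pipeline actually uses: two tissue classes (dark CSF, bright
gray-matter-like "brain"), an intracranial (CSF + brain) envelope, paired
Sylvian-fissure CSF slabs reaching the lateral dura, thin vertical
high-convexity sulcal sheets reaching the vertex, a lateral-ventricle CSF
blob in the interior, and additive i.i.d. Gaussian noise. It deliberately
omits cortical folding, white matter, partial-volume blur and scanner
artifacts, so that noiseless runs have exact voxel-level oracles.

Every phantom carries its own landmarks (PC, Sylvian-fissure center height,
medial limits, ventricle seed) and ground truth: per-compartment masks and
volumes, and the true qDESH of the compartments restricted to the search
geometry the rules would construct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging_io import BinaryMask, ImageVolume
from .search_volumes import (
    SearchVolumeSpec,
    build_hc_search_volume,
    build_sf_search_volume,
    coronal_band,
)

__all__ = [
    "Box",
    "Ellipsoid",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "preset",
    "PRESET_NAMES",
    "perturb_mask",
    "simulate_rater_study",
    "simulate_cohort",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in mm, half-open on every axis: [lo, hi) x 3.

    A voxel belongs to the box iff its center (index x spacing) does.
    """

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]

    def mask(self, shape, spacing) -> np.ndarray:
        axes = []
        for (lo, hi), n, s in zip((self.x, self.y, self.z), shape, spacing):
            c = np.arange(n) * s
            axes.append((c >= lo) & (c < hi))
        return axes[0][:, None, None] & axes[1][None, :, None] & axes[2][None, None, :]

    def volume_mm3(self) -> float:
        return (
            (self.x[1] - self.x[0]) * (self.y[1] - self.y[0]) * (self.z[1] - self.z[0])
        )


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in mm (center, semi-axes)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape, spacing) -> np.ndarray:
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        acc = np.zeros(shape, dtype=float)
        for g, s, c, r in zip(grids, spacing, self.center, self.radii):
            acc = acc + ((g * s - c) / r) ** 2
        return acc <= 1.0


@dataclass
class PhantomSpec:
    """Full description of one phantom: geometry, intensities, noise, seed."""

    grid_shape: tuple[int, int, int] = (96, 64, 80)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pc_index: tuple[int, int, int] = (48, 20, 30)
    head: Box | Ellipsoid = field(
        default_factory=lambda: Box(x=(10, 85), y=(4, 60), z=(6, 66))
    )
    sf_compartments: tuple = ()
    hc_compartments: tuple = ()
    lv_compartment: Box | Ellipsoid | None = None
    intensity_csf: float = 100.0
    intensity_gm: float = 300.0
    intensity_background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    # landmark geometry the semiautomatic workflow would receive as input
    sf_center_z_mm: dict = field(default_factory=lambda: {"left": 30.0, "right": 30.0})
    medial_limit_x_mm: dict = field(default_factory=lambda: {"left": 38.0, "right": 57.0})
    lv_seed: tuple[int, int, int] = (47, 30, 16)
    band_length_mm: float = 20.0
    hc_target_cm3: float = 30.0
    opercular_half_height_mm: float = 10.0

    def __post_init__(self):
        if not self.intensity_csf < self.intensity_gm:
            raise ValueError("T1 contrast requires intensity_csf < intensity_gm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def search_spec(self) -> SearchVolumeSpec:
        """The SearchVolumeSpec a rater would supply for this phantom."""
        return SearchVolumeSpec(
            sf_center_z_mm=dict(self.sf_center_z_mm),
            medial_limit_x_mm=dict(self.medial_limit_x_mm),
            lv_seed=self.lv_seed,
            band_length_mm=self.band_length_mm,
            hc_target_cm3=self.hc_target_cm3,
            opercular_half_height_mm=self.opercular_half_height_mm,
        )


@dataclass
class PhantomTruth:
    """Ground truth: compartment masks/volumes and the true qDESH.

    ``true_qdesh`` is the SF/HC compartment-volume ratio after restricting
    each compartment to the rule-based search geometry (coronal band,
    opercular margin + medial limit, topmost-cranial HC volume) built from
    the noiseless head mask — i.e. exactly what a perfect segmentation
    inside those search volumes would measure.
    """

    masks: dict  # keys: "head", "sf", "hc", "lv" -> BinaryMask
    volumes_cm3: dict  # same keys -> float
    true_qdesh: float
    v_sf_in_search_cm3: float
    v_hc_in_search_cm3: float
    search_spec: SearchVolumeSpec

    def to_dict(self) -> dict:
        return {
            "volumes_cm3": {k: float(v) for k, v in self.volumes_cm3.items()},
            "true_qdesh": float(self.true_qdesh),
            "v_sf_in_search_cm3": float(self.v_sf_in_search_cm3),
            "v_hc_in_search_cm3": float(self.v_hc_in_search_cm3),
            "search_spec": self.search_spec.to_dict(),
        }


def _compartment_masks(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    shape, spacing = spec.grid_shape, spec.spacing
    head = spec.head.mask(shape, spacing)
    if not head.any():
        raise ValueError("empty head mask")
    comps = {}
    sf = np.zeros(shape, dtype=bool)
    for box in spec.sf_compartments:
        sf |= box.mask(shape, spacing)
    hc = np.zeros(shape, dtype=bool)
    for box in spec.hc_compartments:
        hc |= box.mask(shape, spacing)
    lv = (
        spec.lv_compartment.mask(shape, spacing)
        if spec.lv_compartment is not None
        else np.zeros(shape, dtype=bool)
    )
    comps = {"sf": sf, "hc": hc, "lv": lv}
    for name, m in comps.items():
        if (m & ~head).any():
            raise ValueError(f"{name} compartment extends outside the head mask")
    for a, b in (("sf", "hc"), ("sf", "lv"), ("hc", "lv")):
        if (comps[a] & comps[b]).any():
            raise ValueError(f"{a} and {b} compartments overlap")
    return head, comps


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Render the phantom image and its ground truth.

    Image: GM intensity inside head minus CSF compartments, CSF intensity
    inside the compartments, background outside the head, plus seeded
    N(0, noise_sd^2) noise. Identical (spec, seed) gives bit-identical
    output; truth masks are always the noiseless geometry.
    """
    head, comps = _compartment_masks(spec)
    csf = comps["sf"] | comps["hc"] | comps["lv"]
    data = np.full(spec.grid_shape, spec.intensity_background, dtype=np.float64)
    data[head] = spec.intensity_gm
    data[csf] = spec.intensity_csf
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    image = ImageVolume(data, spec.spacing, pc_index=spec.pc_index)

    voxvol_cm3 = image.voxel_volume_mm3 / 1000.0
    masks = {"head": BinaryMask(head, spec.spacing)}
    for k, m in comps.items():
        masks[k] = BinaryMask(m, spec.spacing)
    volumes = {k: m.volume_cm3 for k, m in masks.items()}

    sspec = spec.search_spec()
    band = coronal_band(image, sspec.band_length_mm)
    hc_search, _, _ = build_hc_search_volume(masks["head"], band, sspec.hc_target_cm3)
    sf_search = build_sf_search_volume(band, masks["head"], sspec)
    v_sf_in = float((comps["sf"] & sf_search.data).sum()) * voxvol_cm3
    v_hc_in = float((comps["hc"] & hc_search.data).sum()) * voxvol_cm3
    truth = PhantomTruth(
        masks=masks,
        volumes_cm3=volumes,
        true_qdesh=(v_sf_in / v_hc_in) if v_hc_in > 0 else float("nan"),
        v_sf_in_search_cm3=v_sf_in,
        v_hc_in_search_cm3=v_hc_in,
        search_spec=sspec,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Presets
#
# All presets share a prism head on a 96 x 64 x 80 grid at 1 mm isotropic
# spacing: x in [10, 85), y in [4, 60), z in [6, 66), PC at voxel
# (48, 20, 30). Inside the 20 mm coronal band every 1-mm axial layer then
# holds exactly 75 x 20 = 1500 mm^2 of intracranial cross-section, so the
# topmost-cranial 30 cm^3 rule selects exactly 20 layers.
#
# Compartment sizes are chosen so the presets reproduce the clinical
# ordering of the ratio (control < 1 < iNPH-like), not any cohort value:
# the Sylvian slabs reach the lateral dura and the convexity sheets reach
# the vertex, as the real anatomy does.

PRESET_NAMES = ("control", "inph", "slab_30cc")


def preset(name: str, noise_sd: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Named phantom configurations.

    * ``control`` — generous high-convexity sulcal CSF, thin Sylvian
      fissures: true qDESH ~ 0.61.
    * ``inph`` — effaced convexity sulci, dilated Sylvian fissures and a
      large ventricle: true qDESH = 2.5.
    * ``slab_30cc`` — same prism head with minimal compartments; its
      constant 1500 mm^2 per-layer cross-section makes the 30 cm^3
      high-convexity rule exact (20 layers x 1.5 cm^3).
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    common = dict(noise_sd=noise_sd, seed=seed)
    if name == "control":
        return PhantomSpec(
            sf_compartments=(
                Box(x=(10, 14), y=(20, 40), z=(25, 36)),
                Box(x=(81, 85), y=(20, 40), z=(25, 36)),
            ),
            hc_compartments=(
                Box(x=(20, 22), y=(20, 40), z=(48, 66)),
                Box(x=(35, 37), y=(20, 40), z=(48, 66)),
                Box(x=(55, 57), y=(20, 40), z=(48, 66)),
                Box(x=(70, 72), y=(20, 40), z=(48, 66)),
            ),
            lv_compartment=Box(x=(40, 56), y=(14, 46), z=(12, 22)),
            **common,
        )
    if name == "inph":
        return PhantomSpec(
            sf_compartments=(
                Box(x=(10, 15), y=(20, 40), z=(27, 33)),
                Box(x=(80, 85), y=(20, 40), z=(27, 33)),
            ),
            hc_compartments=(
                Box(x=(30, 31), y=(20, 40), z=(54, 66)),
                Box(x=(64, 65), y=(20, 40), z=(54, 66)),
            ),
            lv_compartment=Box(x=(39, 57), y=(12, 48), z=(10, 24)),
            **common,
        )
    # slab_30cc: geometry fixture for the exact 30 cm^3 construction
    return PhantomSpec(
        sf_compartments=(
            Box(x=(10, 14), y=(20, 40), z=(26, 34)),
            Box(x=(81, 85), y=(20, 40), z=(26, 34)),
        ),
        hc_compartments=(
            Box(x=(40, 42), y=(20, 40), z=(50, 66)),
        ),
        lv_compartment=Box(x=(44, 52), y=(22, 38), z=(12, 20)),
        **common,
    )


# ---------------------------------------------------------------------------
# Rater and cohort simulation


def perturb_mask(mask: BinaryMask, magnitude_mm: float, seed: int) -> BinaryMask:
    """Simulate rater delineation variability on a search-volume mask.

    Each 6-connected region of the mask is independently dilated or eroded
    by a random whole-voxel amount whose physical extent is bounded by
    ``magnitude_mm``; magnitude 0 is the identity. Deterministic per seed.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be non-negative")
    if mask.n_voxels == 0:
        raise ValueError("cannot perturb an empty mask")
    if magnitude_mm == 0:
        return BinaryMask(mask.data.copy(), mask.spacing)
    struct = ndimage.generate_binary_structure(3, 1)
    kmax = int(magnitude_mm / max(mask.spacing))
    rng = np.random.default_rng(seed)
    labels, n = ndimage.label(mask.data, structure=struct)
    out = np.zeros_like(mask.data)
    for lab in range(1, n + 1):
        region = labels == lab
        k = int(rng.integers(-kmax, kmax + 1)) if kmax > 0 else 0
        if k > 0:
            region = ndimage.binary_dilation(region, structure=struct, iterations=k)
        elif k < 0:
            region = ndimage.binary_erosion(region, structure=struct, iterations=-k)
        out |= region
    return BinaryMask(out, mask.spacing)


def _vary_preset(base: str, rng: np.random.Generator, seed: int,
                 noise_sd: float) -> PhantomSpec:
    """Per-subject anatomical variation around a preset (slab/sheet sizes)."""
    if base == "inph":
        w = int(rng.integers(4, 8))  # Sylvian slab width, mm
        h = int(rng.integers(5, 9))  # Sylvian slab height, mm
        e = int(rng.integers(10, 13))  # convexity sheet z-extent, mm
        z0, z1 = 30 - h // 2, 30 - h // 2 + h
        return replace(
            preset("inph", noise_sd=noise_sd, seed=seed),
            sf_compartments=(
                Box(x=(10, 10 + w), y=(20, 40), z=(z0, z1)),
                Box(x=(85 - w, 85), y=(20, 40), z=(z0, z1)),
            ),
            hc_compartments=(
                Box(x=(30, 31), y=(20, 40), z=(66 - e, 66)),
                Box(x=(64, 65), y=(20, 40), z=(66 - e, 66)),
            ),
        )
    w = int(rng.integers(3, 6))
    h = int(rng.integers(8, 13))
    e = int(rng.integers(14, 19))
    z0, z1 = 30 - h // 2, 30 - h // 2 + h
    return replace(
        preset("control", noise_sd=noise_sd, seed=seed),
        sf_compartments=(
            Box(x=(10, 10 + w), y=(20, 40), z=(z0, z1)),
            Box(x=(85 - w, 85), y=(20, 40), z=(z0, z1)),
        ),
        hc_compartments=tuple(
            Box(x=(x0, x0 + 2), y=(20, 40), z=(66 - e, 66))
            for x0 in (20, 35, 55, 70)
        ),
    )


def simulate_rater_study(
    n_subjects: int = 30,
    magnitude_mm: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Two simulated raters measure qDESH on a varied phantom cohort.

    For each subject a varied iNPH-like or control-like phantom is
    generated; each rater's hand-drawn SF and HC search volumes are
    simulated by perturbing the rule-based ones by up to ``magnitude_mm``,
    and qDESH is computed from each rater's volumes. Returns an
    (n_subjects x 2) array of qDESH scores.
    """
    from .qdesh_core import run_pipeline
    from .search_volumes import SearchVolumeSet, build_search_volumes

    master = np.random.default_rng(seed)
    scores = np.empty((n_subjects, 2))
    for i in range(n_subjects):
        base = "inph" if i % 2 == 0 else "control"
        sub_seed = int(master.integers(0, 2**31 - 1))
        spec = _vary_preset(base, master, sub_seed, noise_sd)
        image, truth = generate_phantom(spec)
        svs = build_search_volumes(image, truth.masks["head"], spec.search_spec())
        head = truth.masks["head"]
        for r in range(2):
            pert_seed = int(master.integers(0, 2**31 - 1))
            # the dura (head boundary) stays the outer limit of a rater's ROI
            rater_svs = SearchVolumeSet(
                hc_mask=perturb_mask(svs.hc_mask, magnitude_mm, pert_seed).intersect(head),
                sf_mask=perturb_mask(svs.sf_mask, magnitude_mm, pert_seed + 1).intersect(head),
                lv_mask=svs.lv_mask,
                provenance={"hc": "manual", "sf": "manual", "lv": "rule_based"},
            )
            scores[i, r] = run_pipeline(image, rater_svs).qdesh
    return scores


def simulate_cohort(
    n_inph: int = 20,
    n_control: int = 20,
    noise_sd: float = 20.0,
    seed: int = 0,
):
    """qDESH scores for a varied phantom cohort (labels: 1 = iNPH-like).

    Returns ``(scores, labels, true_qdesh)`` arrays, pipeline-measured on
    noisy phantoms with per-subject anatomical variation.
    """
    from .qdesh_core import run_pipeline

    master = np.random.default_rng(seed)
    scores, labels, truths = [], [], []
    for grp, n in (("inph", n_inph), ("control", n_control)):
        for _ in range(n):
            sub_seed = int(master.integers(0, 2**31 - 1))
            spec = _vary_preset(grp, master, sub_seed, noise_sd)
            image, truth = generate_phantom(spec)
            res = run_pipeline(
                image, spec.search_spec(), intracranial_mask=truth.masks["head"]
            )
            scores.append(res.qdesh)
            labels.append(1 if grp == "inph" else 0)
            truths.append(truth.true_qdesh)
    return np.asarray(scores), np.asarray(labels), np.asarray(truths)
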