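"""Procedural synthetic pelvic voxel phantoms.

Licensed whole-body anatomical models cannot be redistributed, so the study
runs on procedurally generated pelvic phantoms that reproduce the anatomical
*topology and dielectric contrast structure* the segmentation-sensitivity
question depends on: an elliptical-cylinder torso with a subcutaneous fat
(SAT) shell and muscle bulk, spine and two lateral bone groups each split
into cortical shell / cancellous interior / marrow core, a bladder (wall
shell around urine), small- and large-intestine loop structures (wall around
lumen), visceral fat pockets, and a gross target volume (GTV) ellipsoid at a
cervix-, prostate- or rectum-like position in three nested sizes.  The
hyperthermia target volume (HTV) is the GTV dilated by a fixed margin; it is
an evaluation region, not a material — HTV voxels outside the GTV keep their
native tissue labels.

Coordinate convention: 0-based voxel indices, axis order (x: left-right,
y: anterior-posterior with +y posterior, z: caudal-cranial), isotropic
spacing, world coordinates in mm from the origin corner of voxel (0,0,0).

Everything is deterministic given (params, seed); the intestine loops are
seeded random-walk tubes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .tissues import DETAILED_LABELS

__all__ = [
    "LABEL_CODES",
    "CODE_LABELS",
    "PhantomParams",
    "VoxelPhantom",
    "VolumeStats",
    "GenerationError",
    "generate_phantom",
    "compute_volume_stats",
    "generate_population",
    "save_phantom_nifti",
    "load_phantom_nifti",
]

# Integer label codes for the NIfTI label volume; 0 = unlabeled exterior.
# "fat" is not an anatomical label of the detailed phantom (which separates
# SAT and visceral fat) but reduced schemes retain it, so it owns a code.
LABEL_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(DETAILED_LABELS)}
LABEL_CODES["fat"] = len(LABEL_CODES) + 1
CODE_LABELS: dict[int, str] = {v: k for k, v in LABEL_CODES.items()}

GTV_RADII_MM = {"small": 12.0, "medium": 17.0, "large": 22.0}

_SITE_SEX = {
    "cervix": {"female"},
    "prostate": {"male"},
    "rectum": {"female", "male"},
}


class GenerationError(RuntimeError):
    """A structure could not be placed inside the torso."""


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters for one phantom.

    ``fat_fraction`` is the requested fat volume fraction (SAT + visceral)
    of the labeled body; when given, the SAT shell thickness is solved from
    the torso ellipse analytically and ``sat_thickness_mm`` is ignored.
    Defaults mirror a mid-cohort pelvic anatomy (fat fraction 0.37,
    200 ml bladder).
    """

    spacing_mm: float = 5.0
    body_rx_mm: float = 150.0
    body_ry_mm: float = 105.0
    length_mm: float = 300.0
    sat_thickness_mm: float = 25.0
    fat_fraction: float | None = 0.37
    bladder_volume_ml: float = 200.0
    site: str = "cervix"
    gtv_size: str = "medium"
    sex: str = "female"
    htv_margin_mm: float = 10.0
    include_organs: bool = True

    def validate(self) -> None:
        if not (2.5 <= self.spacing_mm <= 10.0):
            raise ValueError(f"spacing_mm must be in [2.5, 10], got {self.spacing_mm}")
        if self.site not in _SITE_SEX:
            raise ValueError(f"unknown tumor site {self.site!r}")
        if self.sex not in {"female", "male"}:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.sex not in _SITE_SEX[self.site]:
            raise ValueError(
                f"site {self.site!r} is anatomically inconsistent with sex {self.sex!r}"
            )
        if self.gtv_size not in GTV_RADII_MM:
            raise ValueError(f"gtv_size must be one of {tuple(GTV_RADII_MM)}")
        if self.fat_fraction is not None and not (0.02 <= self.fat_fraction <= 0.75):
            raise ValueError("fat_fraction outside plausible range [0.02, 0.75]")


@dataclass
class VoxelPhantom:
    """A labeled uniform voxel grid with GTV/HTV masks.

    ``labels`` holds the integer codes of :data:`LABEL_CODES` (0 outside the
    body).  ``gtv_mask`` is always a subset of ``htv_mask``.
    """

    labels: np.ndarray  # int16 (nx, ny, nz)
    spacing_mm: float
    origin_mm: tuple[float, float, float]
    gtv_mask: np.ndarray
    htv_mask: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.labels.shape == self.gtv_mask.shape == self.htv_mask.shape):
            raise ValueError("labels and masks must share one grid shape")
        if np.any(self.gtv_mask & ~self.htv_mask):
            raise ValueError("gtv_mask must be a subset of htv_mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels > 0

    def label_mask(self, tissue_id: str) -> np.ndarray:
        return self.labels == LABEL_CODES[tissue_id]

    def axial_slice_index(self, z_mm: float | None = None) -> int:
        """Voxel z-index of a world z position (default: GTV centroid)."""
        if z_mm is None:
            zs = np.nonzero(self.gtv_mask)[2]
            return int(np.round(zs.mean()))
        k = int(np.round((z_mm - self.origin_mm[2]) / self.spacing_mm - 0.5))
        return min(max(k, 0), self.shape[2] - 1)

    def relabel(self, scheme) -> np.ndarray:
        """Apply a segmentation scheme, returning a new label-code volume.

        Conserves the labeled voxel count: every nonzero code maps to the
        nonzero code of the retained tissue.
        """
        lut = np.zeros(max(CODE_LABELS) + 1, dtype=np.int16)
        present = np.unique(self.labels)
        for code in present:
            if code == 0:
                continue
            lut[code] = LABEL_CODES[scheme.apply(CODE_LABELS[int(code)])]
        return lut[self.labels]


def _ellipsoid_mask(xx, yy, zz, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    return (
        ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2
    ) <= 1.0


def _cylinder_mask(xx, yy, center, radius) -> np.ndarray:
    cx, cy = center
    return ((xx - cx) ** 2 + (yy - cy) ** 2) <= radius**2


def _sat_thickness_for_fraction(rx: float, ry: float, f: float) -> float:
    """SAT shell thickness giving fat fraction ``f`` of the torso ellipse.

    Solves (rx-t)(ry-t) = (1-f)·rx·ry; the visceral fat pockets add ~1 % on
    top, which stays inside the generator's quantization tolerance.
    """
    a, b, c = 1.0, -(rx + ry), f * rx * ry
    disc = b * b - 4 * a * c
    t = (-b - np.sqrt(disc)) / 2
    if not (0 < t < min(rx, ry)):
        raise GenerationError(f"no valid SAT thickness for fat fraction {f}")
    return float(t)


def _walk_tube(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: float,
    box_lo: np.ndarray,
    box_hi: np.ndarray,
    n_steps: int,
    step_mm: float,
    radius_mm: float,
    xx, yy, zz,
) -> np.ndarray:
    """Seeded random-walk tube: a persistent 3D walk rasterized and thickened
    to ``radius_mm`` with a Euclidean distance transform."""
    pos = box_lo + rng.random(3) * (box_hi - box_lo)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    path = np.zeros(shape, dtype=bool)
    for _ in range(n_steps):
        turn = rng.normal(scale=0.6, size=3)
        direction = direction + turn
        direction /= np.linalg.norm(direction)
        pos = pos + direction * step_mm
        # reflect off the allowed box
        for ax in range(3):
            if pos[ax] < box_lo[ax]:
                pos[ax] = 2 * box_lo[ax] - pos[ax]
                direction[ax] = abs(direction[ax])
            elif pos[ax] > box_hi[ax]:
                pos[ax] = 2 * box_hi[ax] - pos[ax]
                direction[ax] = -abs(direction[ax])
        idx = np.round(pos / spacing - 0.5).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        path[tuple(idx)] = True
    dist = ndimage.distance_transform_edt(~path, sampling=spacing)
    return dist <= radius_mm


def generate_phantom(params: PhantomParams, seed: int) -> VoxelPhantom:
    """Generate a detailed pelvic phantom, deterministic given (params, seed).

    When ``fat_fraction`` is requested, the torso radii scale with fatness
    (a fatter body is a larger body) so the inner muscle compartment — and
    with it the organ layout — stays roughly constant across the cohort.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    s = params.spacing_mm
    L = params.length_mm
    rx, ry = params.body_rx_mm, params.body_ry_mm
    if params.fat_fraction is not None:
        # keep inner (muscle) cross-section area constant vs the reference
        # fatness 0.37 while the requested fat fraction sets the SAT shell
        g = float(np.sqrt((1 - 0.37) / (1 - params.fat_fraction)))
        rx, ry = rx * g, ry * g
        t_sat = _sat_thickness_for_fraction(rx, ry, params.fat_fraction)
    else:
        t_sat = params.sat_thickness_mm

    pad = s  # one empty voxel ring around the torso
    # odd grid sizes put a voxel center exactly on the torso axis, so a
    # left-right symmetric anatomy is symmetric on the voxel grid too
    nhx = int(np.ceil((rx + pad) / s))
    nhy = int(np.ceil((ry + pad) / s))
    nx, ny = 2 * nhx + 1, 2 * nhy + 1
    nz = int(np.ceil(L / s))
    cx, cy = (nhx + 0.5) * s, (nhy + 0.5) * s
    # voxel-center world coordinates
    x = (np.arange(nx) + 0.5) * s
    y = (np.arange(ny) + 0.5) * s
    z = (np.arange(nz) + 0.5) * s
    xx, yy, zz = np.meshgrid(x - cx, y - cy, z, indexing="ij")
    z_mid = nz * s / 2

    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    # torso: muscle bulk inside a SAT shell
    body = ((xx / rx) ** 2 + (yy / ry) ** 2) <= 1.0
    inner = ((xx / (rx - t_sat)) ** 2 + (yy / (ry - t_sat)) ** 2) <= 1.0
    labels[body] = LABEL_CODES["sat"]
    labels[inner] = LABEL_CODES["muscle"]

    irx, iry = rx - t_sat, ry - t_sat  # inner (muscle) ellipse radii

    def _require_inside(mask: np.ndarray, what: str) -> None:
        if np.any(mask & ~inner):
            raise GenerationError(f"{what} exceeds the muscle compartment of the torso")

    # visceral fat pockets (small, so the SAT solve stays accurate)
    if params.include_organs:
        for _ in range(5):
            ang = rng.random() * 2 * np.pi
            rad = rng.random() * 0.35
            c = (
                rad * irx * np.cos(ang),
                -0.1 * iry + rad * iry * np.sin(ang) * 0.5,
                z_mid + (rng.random() - 0.5) * 0.6 * L,
            )
            blob = _ellipsoid_mask(xx, yy, zz, c, (14.0, 10.0, 18.0))
            labels[blob & inner & (labels == LABEL_CODES["muscle"])] = LABEL_CODES[
                "visceral_fat"
            ]

    # bone groups: spine (posterior) and two lateral iliac/femoral columns,
    # each cortical shell / cancellous interior / marrow core, full z extent
    def _bone_column(center_xy, r_outer, r_canc, r_marrow, what):
        outer = _cylinder_mask(xx, yy, center_xy, r_outer)
        _require_inside(outer, what)
        canc = _cylinder_mask(xx, yy, center_xy, r_canc)
        marrow = _cylinder_mask(xx, yy, center_xy, r_marrow)
        labels[outer] = LABEL_CODES["cortical_bone"]
        labels[canc] = LABEL_CODES["cancellous_bone"]
        labels[marrow] = LABEL_CODES["bone_marrow"]

    _bone_column((0.0, 0.68 * iry), 16.0, 11.0, 5.0, "spine")
    _bone_column((-0.55 * irx, 0.10 * iry), 15.0, 10.0, 4.5, "left pelvic bone")
    _bone_column((+0.55 * irx, 0.10 * iry), 15.0, 10.0, 4.5, "right pelvic bone")

    bone_mask = (
        (labels == LABEL_CODES["cortical_bone"])
        | (labels == LABEL_CODES["cancellous_bone"])
        | (labels == LABEL_CODES["bone_marrow"])
    )
    soft = inner & ~bone_mask  # room for organs

    # intestine loops: seeded random-walk tubes in the abdominal box
    if params.include_organs:
        # loops descend into the pelvis so they intersect the target slice
        box_lo = np.array([cx - 0.45 * irx, cy - 0.55 * iry, 0.35 * L])
        box_hi = np.array([cx + 0.45 * irx, cy + 0.15 * iry, 0.95 * L])
        for prefix, radius, n_steps in (
            ("small_intestine", 9.0, 160),
            ("large_intestine", 12.0, 110),
        ):
            tube = _walk_tube(
                rng, labels.shape, s, box_lo, box_hi, n_steps, 6.0, radius,
                xx, yy, zz,
            )
            lumen = tube & soft
            wall = ndimage.binary_dilation(lumen) & soft & ~lumen
            soft_now = labels == LABEL_CODES["muscle"]
            labels[wall & soft_now] = LABEL_CODES[f"{prefix}_wall"]
            labels[lumen & (soft_now | (labels == LABEL_CODES["visceral_fat"]))] = (
                LABEL_CODES[f"{prefix}_lumen"]
            )

    # bladder: urine volume (flattened ellipsoid, anterior) wrapped in a
    # one-voxel wall shell; the shell is closed by construction because the
    # wall is the full dilation of the urine mask
    bladder_struct = np.zeros_like(inner)
    if params.bladder_volume_ml > 0:
        a = (3 * params.bladder_volume_ml * 1e3 / (4 * np.pi)) ** (1 / 3)
        radii = (1.3 * a, 0.7 * a, 1.1 * a)  # flattened in anterior-posterior
        bl_center = (0.0, -(0.52 * iry), z_mid - 0.05 * L)
        urine = _ellipsoid_mask(xx, yy, zz, bl_center, radii)
        _require_inside(ndimage.binary_dilation(urine), "bladder")
        if np.any(urine & bone_mask):
            raise GenerationError("bladder overlaps a bone structure")
        wall = ndimage.binary_dilation(urine) & ~urine
        labels[wall] = LABEL_CODES["bladder_wall"]
        labels[urine] = LABEL_CODES["urine"]
        bladder_struct = urine | wall

    # GTV ellipsoid at the site-appropriate position; nested across sizes.
    # The tumor may invade soft tissue and intestine but is clipped against
    # bone and the bladder so the urine shell stays closed.
    r_gtv = GTV_RADII_MM[params.gtv_size]
    site_centers = {
        "cervix": (0.0, +0.15 * iry, z_mid),
        "prostate": (0.0, 0.0, z_mid - 0.14 * L),
        "rectum": (0.0, +0.26 * iry, z_mid),
    }
    site_radii = {
        "cervix": (r_gtv, 0.9 * r_gtv, 1.25 * r_gtv),
        "prostate": (r_gtv, 0.9 * r_gtv, 1.1 * r_gtv),
        "rectum": (r_gtv, 0.8 * r_gtv, 1.25 * r_gtv),
    }
    gc = site_centers[params.site]
    gtv_full = _ellipsoid_mask(xx, yy, zz, gc, site_radii[params.site])
    _require_inside(gtv_full, "GTV")
    gtv = gtv_full & ~bone_mask & ~ndimage.binary_dilation(bladder_struct)
    if gtv.sum() < 0.6 * gtv_full.sum() or not gtv.any():
        raise GenerationError("GTV does not fit at the requested site")
    labels[gtv] = LABEL_CODES["gtv"]

    # HTV: GTV dilated by the margin, clipped to the body
    n_dil = max(1, int(round(params.htv_margin_mm / s)))
    htv = ndimage.binary_dilation(gtv, iterations=n_dil) & (labels > 0)

    return VoxelPhantom(
        labels=labels,
        spacing_mm=s,
        origin_mm=(0.0, 0.0, 0.0),
        gtv_mask=gtv,
        htv_mask=htv,
        params={**asdict(params), "seed": int(seed)},
    )


@dataclass(frozen=True)
class VolumeStats:
    """Per-tissue voxel counts and volume percentages inside an axial extent.

    Percentages are over labeled voxels only (the body inside the
    applicator's axial span).  ``fat_pct`` pools SAT and visceral fat,
    ``bone_pct`` pools all three bone compartments.
    """

    counts: dict[str, int]
    percentages: dict[str, float]
    fat_pct: float
    muscle_pct: float
    bone_pct: float


def compute_volume_stats(
    phantom: VoxelPhantom, applicator_extent_mm: tuple[float, float]
) -> VolumeStats:
    """Tissue volume percentages restricted to the applicator axial extent."""
    z0, z1 = applicator_extent_mm
    s = phantom.spacing_mm
    zc = phantom.origin_mm[2] + (np.arange(phantom.shape[2]) + 0.5) * s
    sel = (zc >= z0) & (zc <= z1)
    if not np.any(sel):
        raise ValueError("applicator extent does not intersect the phantom")
    sub = phantom.labels[:, :, sel]
    codes, counts = np.unique(sub[sub > 0], return_counts=True)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no labeled voxels inside the applicator extent")
    count_map = {CODE_LABELS[int(c)]: int(n) for c, n in zip(codes, counts)}
    pct = {k: 100.0 * n / total for k, n in count_map.items()}
    fat = sum(pct.get(k, 0.0) for k in ("sat", "visceral_fat"))
    bone = sum(
        pct.get(k, 0.0) for k in ("cortical_bone", "cancellous_bone", "bone_marrow")
    )
    return VolumeStats(
        counts=count_map,
        percentages=pct,
        fat_pct=fat,
        muscle_pct=pct.get("muscle", 0.0),
        bone_pct=bone,
    )


@dataclass(frozen=True)
class PopulationSummary:
    """OLS regression of muscle% on fat% over a phantom population."""

    slope: float
    intercept: float
    r_squared: float
    fat_pct: tuple[float, ...]
    muscle_pct: tuple[float, ...]


def generate_population(
    n: int,
    fat_fraction_range: tuple[float, float] = (0.25, 0.55),
    seed: int = 0,
    base_params: PhantomParams | None = None,
    extent_mm: tuple[float, float] | None = None,
) -> tuple[list[VoxelPhantom], PopulationSummary]:
    """Generate ``n`` phantoms spanning a fat-fraction range and regress
    muscle% against fat% (ordinary least squares).

    A degenerate range (no fat variance) yields NaN slope/R² with a warning.
    """
    if n < 3:
        raise ValueError("population needs n >= 3")
    base = base_params or PhantomParams()
    lo, hi = fat_fraction_range
    fracs = np.linspace(lo, hi, n)
    phantoms: list[VoxelPhantom] = []
    fat_pct, muscle_pct = [], []
    ss = np.random.SeedSequence(entropy=int(seed))
    child_seeds = ss.generate_state(n) % (2**31)
    for f, sub_seed in zip(fracs, child_seeds):
        p = replace(base, fat_fraction=float(f))
        ph = generate_phantom(p, int(sub_seed))
        phantoms.append(ph)
        ext = extent_mm or (0.0, base.length_mm)
        stats = compute_volume_stats(ph, ext)
        fat_pct.append(stats.fat_pct)
        muscle_pct.append(stats.muscle_pct)
    if abs(hi - lo) < 1e-12:
        # the requested range cannot span any fat contrast; organ-placement
        # noise alone must not masquerade as a cohort trend
        warnings.warn(
            "degenerate fat-fraction range: regression undefined", RuntimeWarning
        )
        return phantoms, PopulationSummary(
            float("nan"), float("nan"), float("nan"),
            tuple(fat_pct), tuple(muscle_pct),
        )
    return phantoms, population_regression(fat_pct, muscle_pct)


def population_regression(fat_pct, muscle_pct) -> PopulationSummary:
    """OLS of muscle% on fat%; NaN summary (with warning) when the fat
    percentages are degenerate."""
    fat_arr = np.asarray(fat_pct, float)
    mus_arr = np.asarray(muscle_pct, float)
    if np.ptp(fat_arr) < 1e-12 or np.var(fat_arr) == 0:
        warnings.warn(
            "degenerate fat-fraction range: regression undefined", RuntimeWarning
        )
        return PopulationSummary(
            float("nan"), float("nan"), float("nan"),
            tuple(fat_arr), tuple(mus_arr),
        )
    res = sstats.linregress(fat_arr, mus_arr)
    return PopulationSummary(
        float(res.slope), float(res.intercept), float(res.rvalue**2),
        tuple(fat_arr), tuple(mus_arr),
    )


def save_phantom_nifti(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write the label volume as NIfTI plus a JSON sidecar (codes, masks
    as extra codes are not used — GTV/HTV masks get their own files)."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([phantom.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = phantom.origin_mm
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), affine), str(path))
    base = path.name.removesuffix(".gz").removesuffix(".nii")
    for name, mask in (("gtv", phantom.gtv_mask), ("htv", phantom.htv_mask)):
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), affine),
            str(path.with_name(f"{base}_{name}.nii.gz")),
        )
    sidecar = {
        "label_codes": LABEL_CODES,
        "spacing_mm": phantom.spacing_mm,
        "origin_mm": list(phantom.origin_mm),
        "params": phantom.params,
    }
    path.with_name(f"{base}.json").write_text(json.dumps(sidecar, indent=1))


def load_phantom_nifti(path: str | Path) -> VoxelPhantom:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    base = path.name.removesuffix(".gz").removesuffix(".nii")
    sidecar = json.loads(path.with_name(f"{base}.json").read_text())
    masks = {}
    for name in ("gtv", "htv"):
        m = nib.load(str(path.with_name(f"{base}_{name}.nii.gz")))
        masks[name] = np.asarray(m.dataobj).astype(bool)
    return VoxelPhantom(
        labels=labels,
        spacing_mm=float(sidecar["spacing_mm"]),
        origin_mm=tuple(sidecar["origin_mm"]),
        gtv_mask=masks["gtv"],
        htv_mask=masks["htv"],
        params=sidecar.get("params", {}),
    )
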