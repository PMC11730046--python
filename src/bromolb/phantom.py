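"""Synthetic thoracic CT phantoms and synthetic biopsy cohorts.

The phantom emulates the imaging substrate of a pre-biopsy planning CT:
heterogeneous lung parenchyma around -750 HU, a gravity-dependent vertical
density gradient, a central-to-peripheral gradient, focal emphysematous
low-attenuation clusters near -940 HU, a soft-tissue target lesion kept
more than 10 mm from the pleura, and a straight coaxial needle path from
the body surface to the lesion.

The cohort generator draws per-case covariates from the distributions of a
typical biopsy population and assigns outcome labels (pneumothorax yes/no,
hemorrhage grade 0-4) from binomial logistic risk models, so that refitting
those models to a simulated cohort is a parameter-recovery exercise.

Axis order is (z, y, x): z = axial slice (cranio-caudal), y = anterior to
posterior, x = patient right to left. World coordinates are voxel index
times spacing, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, ndtri

from .errors import GeometryError, ValidationError

HU_MIN = -1024.0
HU_MAX = 3071.0
SOFT_TISSUE_HU = 40.0

PatientPosition = Literal["supine", "prone", "lateral"]

#: gravity points toward the dependent (down) side of the patient
GRAVITY_BY_POSITION: dict[str, tuple[float, float, float]] = {
    "supine": (0.0, 1.0, 0.0),   # posterior down
    "prone": (0.0, -1.0, 0.0),   # anterior down
    "lateral": (0.0, 0.0, 1.0),  # left side down
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A 3-D attenuation grid in Hounsfield units with physical metadata."""

    voxels: np.ndarray            # (z, y, x) float HU
    spacing: tuple[float, float, float]  # mm per voxel along (z, y, x)
    gravity_axis: np.ndarray      # unit vector in (z, y, x) order
    lung_mask: np.ndarray         # bool
    pleura_surface: np.ndarray    # bool, boundary shell of lung_mask

    def validate(self) -> None:
        if self.voxels.min() < HU_MIN or self.voxels.max() > HU_MAX:
            raise ValidationError("HU values outside [-1024, 3071]")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be strictly positive")
        if not self.lung_mask.any():
            raise ValidationError("lung_mask is empty")
        shell = self.lung_mask & ~ndimage.binary_erosion(self.lung_mask)
        if (self.pleura_surface & ~shell).any():
            raise ValidationError("pleura_surface is not a subset of the lung boundary shell")


@dataclass
class TruthMasks:
    """Ground-truth tissue labels for a phantom (pairwise disjoint, all in lung)."""

    lesion: np.ndarray
    emphysema: np.ndarray
    ground_glass: np.ndarray
    normal_parenchyma: np.ndarray

    def validate(self, lung_mask: np.ndarray) -> None:
        named = {
            "lesion": self.lesion,
            "emphysema": self.emphysema,
            "ground_glass": self.ground_glass,
            "normal_parenchyma": self.normal_parenchyma,
        }
        for name, m in named.items():
            if (m & ~lung_mask).any():
                raise ValidationError(f"{name} mask extends outside the lung")
        keys = list(named)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if (named[a] & named[b]).any():
                    raise ValidationError(f"masks {a} and {b} overlap")


@dataclass
class NeedlePath:
    """Straight entry-to-target needle segment in world mm."""

    entry_point: np.ndarray       # (z, y, x) mm, at the body surface
    target_point: np.ndarray      # (z, y, x) mm, lesion centre
    pleura_to_lesion_distance: float  # mm, pleural crossing to lesion surface
    skin_to_lesion_distance: float    # mm

    def direction(self) -> np.ndarray:
        d = self.target_point - self.entry_point
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class PhantomParams:
    """Generator knobs. Defaults emulate a 1-mm reconstruction planning CT."""

    grid_shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_position: str = "supine"
    normal_mean_hu: float = -750.0
    normal_sd_hu: float = 20.0
    vertical_gradient_hu_per_cm: float = 10.0
    radial_gradient_hu: float = 10.0
    emphysema_mean_hu: float = -940.0
    n_emphysema_clusters: int = 3
    cluster_radius_mm: tuple[float, float] = (3.0, 6.0)
    emphysema_placement: Literal["random", "on_route", "off_route"] = "random"
    n_ground_glass_clusters: int = 0
    ground_glass_mean_hu: float = -350.0
    lesion_hu: float = 30.0
    lesion_radius_mm: float = 6.0
    min_route_depth_mm: float = 18.0
    route_clearance_mm: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.normal_mean_hu <= self.emphysema_mean_hu:
            raise ValidationError("normal_mean_hu must exceed emphysema_mean_hu")
        if any(s <= 0 for s in self.spacing) or any(n < 8 for n in self.grid_shape):
            raise ValidationError("invalid grid geometry")
        if self.patient_position not in GRAVITY_BY_POSITION:
            raise ValidationError(f"unknown patient position {self.patient_position!r}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def world_grid(shape: Sequence[int], spacing: Sequence[float]) -> tuple[np.ndarray, ...]:
    """Per-axis world coordinates (mm) of voxel centres, broadcastable to `shape`."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


def sphere_mask(shape: Sequence[int], spacing: Sequence[float],
                center_mm: Sequence[float], radius_mm: float) -> np.ndarray:
    zz, yy, xx = world_grid(shape, spacing)
    d2 = ((zz - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2 + (xx - center_mm[2]) ** 2)
    return d2 <= radius_mm ** 2


def segment_distance(points_mm: np.ndarray, a_mm: np.ndarray, b_mm: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point (…, 3) to the segment a-b."""
    ab = b_mm - a_mm
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points_mm - a_mm, axis=-1)
    t = np.clip(((points_mm - a_mm) @ ab) / denom, 0.0, 1.0)
    proj = a_mm + t[..., None] * ab
    return np.linalg.norm(points_mm - proj, axis=-1)


def _two_lung_masks(shape, spacing):
    """Two superellipsoidal lungs; the needle always traverses the right lung
    (low x). The quartic exponents along z and y keep the cross-section wide
    near the anterior/posterior faces, as in a real thorax, so matched-level
    comparison ROIs exist wherever the needle can enter."""
    nz, ny, nx = shape
    zz, yy, xx = world_grid(shape, spacing)
    cz, cy = nz * spacing[0] / 2.0, ny * spacing[1] / 2.0
    az, ay = 0.44 * nz * spacing[0], 0.44 * ny * spacing[1]
    ax = 0.19 * nx * spacing[2]
    cx_r, cx_l = 0.30 * nx * spacing[2], 0.70 * nx * spacing[2]

    def ell(cx):
        return (((zz - cz) / az) ** 4 + ((yy - cy) / ay) ** 4
                + ((xx - cx) / ax) ** 2) <= 1.0

    right, left = ell(cx_r), ell(cx_l)
    return right, left


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(params: PhantomParams) -> tuple[CTVolume, TruthMasks, NeedlePath]:
    """Build one phantom: HU volume, truth masks and a feasible needle path.

    The output is a pure function of ``params`` (including ``seed``).
    Raises :class:`GeometryError` when the lesion cannot be placed with the
    required pleural margin and route depth in the requested grid.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape, spacing = params.grid_shape, params.spacing
    sz, sy, sx = spacing

    right, left = _two_lung_masks(shape, spacing)
    lung = right | left
    edt_lung = ndimage.distance_transform_edt(lung, sampling=spacing)

    # --- lesion placement in the right lung --------------------------------
    r_les = params.lesion_radius_mm
    # first lung voxel index along +y for every (z, x) column of the right lung
    has_lung = right.any(axis=1)
    y_first = np.where(has_lung, np.argmax(right, axis=1), -1)  # (z, x)

    idx = np.argwhere(right & (edt_lung > r_les + 2.0))
    if idx.size == 0:
        raise GeometryError("no interior lesion position fits the requested grid")
    depth_ok = np.array([
        y_first[z, x] >= 0
        and (y - y_first[z, x]) * sy - r_les >= params.min_route_depth_mm
        for z, y, x in idx
    ])
    idx = idx[depth_ok]
    if idx.size == 0:
        raise GeometryError(
            "lesion cannot satisfy the >10 mm pleural margin and route depth")
    lz, ly, lx = idx[rng.integers(len(idx))]
    lesion_center = np.array([lz * sz, ly * sy, lx * sx])
    lesion = sphere_mask(shape, spacing, lesion_center, r_les)

    # --- needle path: straight anterior approach along +y ------------------
    entry = np.array([lz * sz, 0.0, lx * sx])
    y_pleura = y_first[lz, lx] * sy
    pleura_to_lesion = (ly * sy - r_les) - y_pleura
    path = NeedlePath(
        entry_point=entry,
        target_point=lesion_center,
        pleura_to_lesion_distance=float(pleura_to_lesion),
        skin_to_lesion_distance=float(ly * sy),
    )
    seg_a = np.array([lz * sz, y_pleura, lx * sx])          # pleural crossing
    seg_b = np.array([lz * sz, ly * sy - r_les, lx * sx])   # lesion surface

    # --- emphysema / ground-glass clusters ---------------------------------
    emph = np.zeros(shape, dtype=bool)
    gg = np.zeros(shape, dtype=bool)
    vox_mm = np.stack(np.broadcast_arrays(*world_grid(shape, spacing)), axis=-1)

    def _sample_cluster(radius: float, keep_off_route: bool) -> np.ndarray | None:
        cand = lung & (edt_lung > radius + 1.0)
        cand &= ~sphere_mask(shape, spacing, lesion_center,
                             r_les + radius + 4.0)
        if keep_off_route:
            d = segment_distance(vox_mm, seg_a, seg_b)
            cand &= d > params.route_clearance_mm + radius
        pos = np.argwhere(cand)
        if pos.size == 0:
            return None
        z, y, x = pos[rng.integers(len(pos))]
        return np.array([z * sz, y * sy, x * sx])

    n_cl = params.n_emphysema_clusters
    placed_on_route = False
    for k in range(n_cl):
        radius = rng.uniform(*params.cluster_radius_mm)
        if params.emphysema_placement == "on_route" and not placed_on_route:
            # centre the first cluster on the intrapulmonary segment, deep
            # enough that a 5-mm ROI in its core sees cluster tissue only
            radius = max(radius, 4.5)
            lo = y_pleura + radius + 1.0
            hi = (ly * sy - r_les) - radius - 1.0
            if hi <= lo:
                raise GeometryError("route too shallow for an on-route cluster")
            yc = lo + rng.uniform(0.35, 0.65) * (hi - lo)
            center = np.array([lz * sz, yc, lx * sx])
            placed_on_route = True
        else:
            center = _sample_cluster(
                radius, keep_off_route=params.emphysema_placement != "random")
            if center is None:
                continue
        emph |= sphere_mask(shape, spacing, center, radius)
    if params.emphysema_placement == "on_route" and not placed_on_route and n_cl > 0:
        raise GeometryError("requested on-route cluster could not be placed")
    emph &= lung & ~lesion

    for _ in range(params.n_ground_glass_clusters):
        radius = rng.uniform(*params.cluster_radius_mm)
        center = _sample_cluster(radius, keep_off_route=True)
        if center is not None:
            gg |= sphere_mask(shape, spacing, center, radius)
    gg &= lung & ~lesion & ~emph

    # --- attenuation field --------------------------------------------------
    g = np.asarray(GRAVITY_BY_POSITION[params.patient_position], dtype=float)
    zz, yy, xx = world_grid(shape, spacing)
    height = g[0] * zz + g[1] * yy + g[2] * xx            # mm along gravity
    h_lung = np.broadcast_to(height, shape)[lung]
    height0 = h_lung.min()

    hu = np.full(shape, SOFT_TISSUE_HU, dtype=float)
    parenchyma = (
        params.normal_mean_hu
        + params.vertical_gradient_hu_per_cm * (np.broadcast_to(height, shape) - height0) / 10.0
        + params.radial_gradient_hu * edt_lung / max(edt_lung.max(), 1e-9)
    )
    hu[lung] = parenchyma[lung]

    for mask, mean in ((emph, params.emphysema_mean_hu),
                       (gg, params.ground_glass_mean_hu)):
        if mask.any():
            w = ndimage.gaussian_filter(mask.astype(float), sigma=1.0, truncate=3.0)
            w = np.clip(w, 0.0, 1.0)
            hu = (1.0 - w) * hu + w * mean

    if params.normal_sd_hu > 0:
        hu += rng.normal(0.0, params.normal_sd_hu, size=shape)
    hu[lesion] = params.lesion_hu
    np.clip(hu, HU_MIN, HU_MAX, out=hu)

    abnormal = lesion | emph | gg
    dist_abn = ndimage.distance_transform_edt(~abnormal, sampling=spacing)
    normal = lung & (dist_abn > 3.0)

    pleura = lung & ~ndimage.binary_erosion(lung)
    volume = CTVolume(voxels=hu, spacing=spacing, gravity_axis=g,
                      lung_mask=lung, pleura_surface=pleura)
    masks = TruthMasks(lesion=lesion, emphysema=emph, ground_glass=gg,
                       normal_parenchyma=normal)
    return volume, masks, path


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimParams:
    """Cohort simulator truth values and covariate distributions.

    The logistic coefficients default to the fitted pneumothorax model
    (log-odds 3.341 for a positive BROM-OLB MinIP call, 0.025 per minute of
    procedure time) and the fitted hemorrhage model (-0.008 per HU of
    lung-window density). Intercepts are calibrated so the marginal event
    rates match the source cohort (pneumothorax 45.8%, grade >= 2 hemorrhage
    27.8%). Route density values are drawn from normal distributions matched
    to the reported means +/- SD; that distributional form is an assumption.
    """

    n_cases: int = 72
    seed: int = 0
    # pneumothorax model: logit p = a + b1 * I[BROM-OLB MinIP+] + b2 * time
    ptx_intercept: float = -2.428
    ptx_coef_bromolb: float = 3.341
    ptx_coef_time: float = 0.025
    # hemorrhage (grade >= 2) model: logit p = a + b * lw_value
    hem_intercept: float = -6.92
    hem_coef_lw: float = -0.008
    # covariate distributions (route-density values in HU)
    minip_mean: float = -866.9
    minip_sd: float = 132.78
    lw_mean: float = -745.9
    lw_sd: float = 130.49
    lw_minip_corr: float = 0.95
    time_mean: float = 27.72
    time_sd: float = 8.46
    lesion_size_mean: float = 20.51
    lesion_size_sd: float = 9.80
    p_positions: tuple[float, float, float] = (0.25, 0.40, 0.35)
    brom_minip_rate: float = 32.0 / 72.0
    brom_lw_rate: float = 29.0 / 72.0
    p_general_emphysema: float = 29.0 / 72.0
    p_lar_given_general: float = 22.0 / 29.0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValidationError("n_cases must be nonnegative")
        if not 0.0 < self.brom_minip_rate < 1.0 or not 0.0 < self.brom_lw_rate < 1.0:
            raise ValidationError("positivity rates must lie in (0, 1)")
        if abs(sum(self.p_positions) - 1.0) > 1e-9:
            raise ValidationError("position probabilities must sum to 1")


@dataclass
class CaseRecord:
    """One simulated biopsy case (column dictionary of the cohort CSV)."""

    case_id: str
    patient_position: str
    lesion_size: float            # mm
    procedure_time: float         # min
    lw_value: float               # HU, route reference on the lung-window image
    minip_value: float            # HU, same reference on the 10-mm MinIP
    brom_olb_lw: bool
    brom_olb_minip: bool
    minip_le_850: bool
    lw_le_850: bool
    general_emphysema: bool
    emphysema_lar: bool
    pneumothorax: bool
    hemorrhage_grade: int         # 0..4

    def validate(self) -> None:
        if self.hemorrhage_grade not in (0, 1, 2, 3, 4):
            raise ValidationError(f"hemorrhage_grade {self.hemorrhage_grade} outside 0-4")
        if self.lw_value < self.minip_value:
            raise ValidationError("lw_value below minip_value for the same route")
        if self.minip_le_850 != (self.minip_value <= -850.0):
            raise ValidationError("minip_le_850 inconsistent with minip_value")
        if self.lw_le_850 != (self.lw_value <= -850.0):
            raise ValidationError("lw_le_850 inconsistent with lw_value")
        if self.emphysema_lar and not self.general_emphysema:
            raise ValidationError("emphysema at the access route implies general emphysema")


def generate_cohort(params: CohortSimParams) -> list[CaseRecord]:
    """Draw a synthetic cohort; outcomes follow the logistic risk models.

    Reproducible: identical ``params`` (including ``seed``) give identical
    records. The generated event probabilities are strictly inside (0, 1).
    """
    params.validate()
    if params.n_cases < 1:
        raise ValidationError("n_cases must be >= 1")
    rng = np.random.default_rng(params.seed)
    n = params.n_cases

    positions = rng.choice(["supine", "lateral", "prone"], size=n, p=params.p_positions)
    time = np.maximum(rng.normal(params.time_mean, params.time_sd, n), 5.0)
    size = np.maximum(rng.normal(params.lesion_size_mean, params.lesion_size_sd, n), 5.0)

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = params.lw_minip_corr
    minip = params.minip_mean + params.minip_sd * z1
    lw = params.lw_mean + params.lw_sd * (rho * z1 + np.sqrt(1.0 - rho ** 2) * z2)
    lw = np.maximum(lw, minip)              # MinIP is a lower envelope
    minip = np.clip(minip, HU_MIN, 0.0)
    lw = np.clip(lw, HU_MIN, 0.0)

    brom_minip = minip <= params.minip_mean + params.minip_sd * ndtri(params.brom_minip_rate)
    brom_lw = lw <= params.lw_mean + params.lw_sd * ndtri(params.brom_lw_rate)

    general = rng.random(n) < params.p_general_emphysema
    lar = general & (rng.random(n) < params.p_lar_given_general)

    p_ptx = expit(params.ptx_intercept
                  + params.ptx_coef_bromolb * brom_minip.astype(float)
                  + params.ptx_coef_time * time)
    ptx = rng.random(n) < p_ptx

    p_hem = expit(params.hem_intercept + params.hem_coef_lw * lw)
    hem2 = rng.random(n) < p_hem
    grade = np.where(
        hem2,
        rng.choice([2, 3, 4], size=n, p=[17 / 20, 2 / 20, 1 / 20]),
        rng.choice([0, 1], size=n, p=[1 / 52, 51 / 52]),
    )

    records = [
        CaseRecord(
            case_id=f"case-{i:05d}",
            patient_position=str(positions[i]),
            lesion_size=float(size[i]),
            procedure_time=float(time[i]),
            lw_value=float(lw[i]),
            minip_value=float(minip[i]),
            brom_olb_lw=bool(brom_lw[i]),
            brom_olb_minip=bool(brom_minip[i]),
            minip_le_850=bool(minip[i] <= -850.0),
            lw_le_850=bool(lw[i] <= -850.0),
            general_emphysema=bool(general[i]),
            emphysema_lar=bool(lar[i]),
            pneumothorax=bool(ptx[i]),
            hemorrhage_grade=int(grade[i]),
        )
        for i in range(n)
    ]
    return records


COHORT_COLUMNS = [f.name for f in CaseRecord.__dataclass_fields__.values()]


def cohort_to_frame(records: Sequence[CaseRecord]) -> pd.DataFrame:
    """Tabulate CaseRecords as a typed DataFrame (one row per case)."""
    return pd.DataFrame([vars(r) for r in records])
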