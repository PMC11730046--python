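"""The BROM-OLB relative radiodensity measurement.

Procedure: a 5-mm spherical reference ROI (R) is placed at the lowest mean
density along the needle corridor (the intrapulmonary path plus a lateral
tolerance for needle error). Three comparison ROIs of identical size are
then placed, in a fixed order: at the same vertical (gravity) level (1.H),
at the lesion's distance from the pleura (2.PD), and in visually normal
parenchyma, in the other lung if the same-level parenchyma was already
sampled (3.P). Comparison ROIs must avoid emphysema, ground-glass and
lesion tissue and must agree with each other within 20 HU of their common
mean; otherwise they are repositioned, and after too many attempts the case
is flagged unevaluable. The call is positive when the reference mean is
strictly lower than the majority (at least 2 of 3) of the comparison means,
evaluated independently on the source-HU (lung-window) image and on the
10-mm MinIP. An absolute classifier (<= -850 HU) is provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import RoiPlacementError, ValidationError
from .phantom import CTVolume, NeedlePath, TruthMasks, segment_distance
from .projection import minip_slab


@dataclass(frozen=True)
class BromOlbConfig:
    """Measurement parameters (all lengths in mm, densities in HU)."""

    roi_diameter: float = 5.0
    corridor_radius: float = 5.0          # lateral tolerance of coaxial needles
    deviation_tolerance: float = 20.0     # comparison-ROI agreement bound
    absolute_threshold: float = -850.0
    vertical_band_halfwidth: float = 2.0
    pleural_distance_tolerance: float = 3.0
    abnormal_clearance_mm: float = 3.0    # extra margin around abnormal tissue
    max_reposition_attempts: int = 10
    minip_slab_mm: float = 10.0
    minip_statistic: Literal["mean", "min"] = "mean"

    def validate(self) -> None:
        if self.roi_diameter <= 0 or self.deviation_tolerance <= 0:
            raise ValidationError("ROI diameter and deviation tolerance must be positive")
        if not -1024.0 <= self.absolute_threshold <= 3071.0:
            raise ValidationError("absolute threshold outside the HU range")


@dataclass
class RoiMeasurement:
    """A 5-mm spherical ROI and its density statistics on one image."""

    center: np.ndarray        # (z, y, x) world mm
    diameter: float
    role: str                 # "R", "H1", "PD2" or "P3"
    mean_hu: float
    sd_hu: float
    min_hu: float
    image_kind: str           # "LW" (source HU) or "MinIP"


@dataclass
class BromOlbAssessment:
    """Full per-case result of the BROM-OLB procedure."""

    reference: RoiMeasurement             # on the source-HU (LW) image
    reference_minip: RoiMeasurement
    comparisons: list[RoiMeasurement]     # H1, PD2, P3 on the source image
    comparisons_minip: list[RoiMeasurement]
    consistency_ok: bool
    positive_lw: bool
    positive_minip: bool
    lw_value: float
    minip_value: float
    minip_le_850: bool
    lw_le_850: bool
    n_repositions: int = 0
    unevaluable_reason: str | None = None

    @property
    def evaluable(self) -> bool:
        return self.unevaluable_reason is None


# ---------------------------------------------------------------------------
# ROI rasterization and statistics
# ---------------------------------------------------------------------------

def sphere_offsets(diameter_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Integer voxel offsets whose centres lie within the ROI sphere."""
    r = diameter_mm / 2.0
    half = [int(np.floor(r / s)) for s in spacing]
    ranges = [np.arange(-h, h + 1) for h in half]
    zz, yy, xx = np.meshgrid(*ranges, indexing="ij")
    d2 = (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    keep = d2 <= r ** 2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def roi_stats(voxels: np.ndarray, center_idx: Sequence[int],
              offsets: np.ndarray) -> tuple[float, float, float]:
    """(mean, sd, min) HU over the ROI voxels centred at ``center_idx``."""
    idx = np.asarray(center_idx, dtype=int) + offsets
    if (idx < 0).any() or (idx >= np.array(voxels.shape)).any():
        raise RoiPlacementError("ROI extends outside the image grid")
    vals = voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(vals.mean()), float(vals.std(ddof=0)), float(vals.min())


def _candidate_means(voxels: np.ndarray, centers: np.ndarray,
                     offsets: np.ndarray) -> np.ndarray:
    idx = centers[:, None, :] + offsets[None, :, :]
    return voxels[idx[..., 0], idx[..., 1], idx[..., 2]].mean(axis=1)


# ---------------------------------------------------------------------------
# reference ROI search
# ---------------------------------------------------------------------------

def _intrapulmonary_segment(volume: CTVolume, path: NeedlePath,
                            lesion_mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """World-mm endpoints of the needle segment inside lung (pleura to lesion)."""
    spacing = np.asarray(volume.spacing)
    d = path.direction()
    length = float(np.linalg.norm(path.target_point - path.entry_point))
    step = 0.5 * float(spacing.min())
    ts = np.arange(0.0, length + step, step)
    pts = path.entry_point + ts[:, None] * d
    idx = np.round(pts / spacing).astype(int)
    inside = ((idx >= 0) & (idx < np.array(volume.voxels.shape))).all(axis=1)
    in_lung = np.zeros(len(ts), dtype=bool)
    in_lung[inside] = volume.lung_mask[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    if not in_lung.any():
        raise RoiPlacementError("needle corridor lies entirely outside the lung")
    first = int(np.argmax(in_lung))
    if lesion_mask is not None:
        in_les = np.zeros(len(ts), dtype=bool)
        in_les[inside] = lesion_mask[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        hits = np.nonzero(in_les & (ts > ts[first]))[0]
        last = int(hits[0]) - 1 if hits.size else len(ts) - 1
    else:
        last = len(ts) - 1
    if last <= first:
        raise RoiPlacementError("intrapulmonary needle segment has zero length")
    return pts[first], pts[last]


def find_reference_roi(volume: CTVolume, path: NeedlePath, cfg: BromOlbConfig,
                       *, image: np.ndarray | None = None,
                       lesion_mask: np.ndarray | None = None) -> RoiMeasurement:
    """Lowest-mean 5-mm ROI over candidate centres in the needle corridor.

    Candidates are voxel centres within ``corridor_radius`` of the
    intrapulmonary segment whose ROI lies fully inside the lung (and clear
    of the lesion). Ties are broken toward the pleural entry, then by
    lexicographic voxel index.
    """
    cfg.validate()
    vox = volume.voxels if image is None else image
    spacing = np.asarray(volume.spacing)
    r = cfg.roi_diameter / 2.0
    offsets = sphere_offsets(cfg.roi_diameter, spacing)

    seg_a, seg_b = _intrapulmonary_segment(volume, path, lesion_mask)
    edt_lung = ndimage.distance_transform_edt(volume.lung_mask, sampling=volume.spacing)

    lo = np.maximum(np.floor((np.minimum(seg_a, seg_b) - cfg.corridor_radius - r) / spacing), 0).astype(int)
    hi = np.minimum(np.ceil((np.maximum(seg_a, seg_b) + cfg.corridor_radius + r) / spacing) + 1,
                    np.array(vox.shape)).astype(int)
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    grid = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    pts = grid * spacing
    ok = segment_distance(pts, seg_a, seg_b) <= cfg.corridor_radius + 1e-6
    ok &= edt_lung[grid[:, 0], grid[:, 1], grid[:, 2]] > r
    if lesion_mask is not None and lesion_mask.any():
        d_les = ndimage.distance_transform_edt(~lesion_mask, sampling=volume.spacing)
        ok &= d_les[grid[:, 0], grid[:, 1], grid[:, 2]] > r
    centers = grid[ok]
    if centers.size == 0:
        raise RoiPlacementError("no full ROI fits inside the needle corridor")

    means = _candidate_means(vox, centers, offsets)
    best = means.min()
    near = np.nonzero(means <= best + 1e-9)[0]
    if near.size > 1:
        d_pleura = np.linalg.norm(centers[near] * spacing - seg_a, axis=1)
        near = near[np.lexsort((centers[near, 2], centers[near, 1],
                                centers[near, 0], np.round(d_pleura, 6)))]
    pick = int(near[0])
    mean, sd, mn = roi_stats(vox, centers[pick], offsets)
    return RoiMeasurement(center=centers[pick] * spacing, diameter=cfg.roi_diameter,
                          role="R", mean_hu=mean, sd_hu=sd, min_hu=mn, image_kind="LW")


# ---------------------------------------------------------------------------
# comparison-ROI placement
# ---------------------------------------------------------------------------

def _candidate_orderings(volume: CTVolume, masks: TruthMasks,
                         reference: RoiMeasurement, lesion_pleural_distance: float,
                         cfg: BromOlbConfig,
                         path: NeedlePath | None) -> dict[str, np.ndarray]:
    """Ordered candidate centre lists (voxel indices) for roles H1, PD2, P3."""
    spacing = np.asarray(volume.spacing)
    r = cfg.roi_diameter / 2.0
    lung = volume.lung_mask
    edt_lung = ndimage.distance_transform_edt(lung, sampling=volume.spacing)
    abnormal = masks.lesion | masks.emphysema | masks.ground_glass
    if abnormal.any():
        # comparison ROIs are re-evaluated on the MinIP, where a 10-mm slab
        # projects abnormal tissue up to half a slab along the viewing axis;
        # clear that shadow too, not just the abnormal voxels themselves
        n_slab = max(1, int(round(cfg.minip_slab_mm / volume.spacing[0])))
        shadow = ndimage.maximum_filter1d(abnormal.astype(np.uint8), size=n_slab,
                                          axis=0, mode="nearest") > 0
        d_abn = ndimage.distance_transform_edt(~shadow, sampling=volume.spacing)
    else:
        d_abn = np.full(lung.shape, np.inf)

    base = (edt_lung > r) & (d_abn > r + cfg.abnormal_clearance_mm)
    grid = np.argwhere(base)
    pts = grid * spacing

    if path is not None:
        seg_a, seg_b = _intrapulmonary_segment(volume, path, masks.lesion)
        keep = segment_distance(pts, seg_a, seg_b) > cfg.corridor_radius + 1e-6
        grid, pts = grid[keep], pts[keep]

    g = volume.gravity_axis
    glevel = pts @ g
    ref_g = float(reference.center @ g)
    dg = np.abs(glevel - ref_g)
    dist_ref = np.linalg.norm(pts - reference.center, axis=1)

    lung_pts_g = (np.argwhere(lung) * spacing) @ g
    gmin, gmax = lung_pts_g.min(), lung_pts_g.max()
    terc = np.clip((3.0 * (glevel - gmin) / max(gmax - gmin, 1e-9)).astype(int), 0, 2)
    ref_terc = int(np.clip(3.0 * (ref_g - gmin) / max(gmax - gmin, 1e-9), 0, 2))

    out: dict[str, np.ndarray] = {}

    in_band = dg <= cfg.vertical_band_halfwidth
    h1 = np.nonzero(in_band)[0]
    out["H1"] = grid[h1[np.lexsort((dist_ref[h1], np.round(dg[h1], 6)))]]

    pd = edt_lung[grid[:, 0], grid[:, 1], grid[:, 2]]
    pd_ok = np.abs(pd - lesion_pleural_distance) <= cfg.pleural_distance_tolerance
    p2 = np.nonzero(pd_ok)[0]
    key_band = (~in_band[p2]).astype(int)
    key_terc = (terc[p2] != ref_terc).astype(int)
    out["PD2"] = grid[p2[np.lexsort((dist_ref[p2], np.round(dg[p2], 6),
                                     key_terc, key_band))]]

    # P3: fully inside visually normal parenchyma, preferring the other lung
    # at the mirrored (gradient-matched) location
    d_nonnormal = ndimage.distance_transform_edt(masks.normal_parenchyma,
                                                 sampling=volume.spacing)
    in_normal = d_nonnormal[grid[:, 0], grid[:, 1], grid[:, 2]] > r
    labels, n_lab = ndimage.label(lung)
    ref_idx = np.round(reference.center / spacing).astype(int)
    ref_lab = labels[tuple(ref_idx)]
    cand_lab = labels[grid[:, 0], grid[:, 1], grid[:, 2]]
    if n_lab >= 2:
        centroids = ndimage.center_of_mass(lung, labels, range(1, n_lab + 1))
        x_mid = float(np.mean([c[2] for c in centroids])) * spacing[2]
        mirror = reference.center.copy()
        mirror[2] = 2.0 * x_mid - mirror[2]
        # matched gravity level first (it controls the dominant density
        # gradient); at equal level prefer the other lung near the mirrored
        # position, else stay in the same lung
        cand = np.nonzero(in_normal & (cand_lab > 0))[0]
        is_other = cand_lab[cand] != ref_lab
        d_anchor = np.where(is_other,
                            np.linalg.norm(pts[cand] - mirror, axis=1),
                            dist_ref[cand])
        ordered = cand[np.lexsort((d_anchor, ~is_other, np.round(dg[cand], 6)))]
        out["P3"] = grid[ordered]
    else:
        same = np.nonzero(in_normal)[0]
        out["P3"] = grid[same[np.lexsort((dist_ref[same], np.round(dg[same], 6)))]]
    return out


def _select(cands: np.ndarray, start: int, taken: list[np.ndarray],
            spacing: np.ndarray, min_sep: float) -> int:
    """Index (into cands) of the first admissible centre not overlapping taken ROIs."""
    for k in range(start, len(cands)):
        c = cands[k] * spacing
        if all(np.linalg.norm(c - t) >= min_sep for t in taken):
            return k
    return -1


def place_comparison_rois(volume: CTVolume, masks: TruthMasks,
                          reference: RoiMeasurement, lesion_pleural_distance: float,
                          cfg: BromOlbConfig,
                          path: NeedlePath | None = None) -> list[RoiMeasurement]:
    """Rule-based placement of the three comparison ROIs (order H1 -> PD2 -> P3)."""
    rois, _, _ = _place_with_cursors(volume, masks, reference,
                                     lesion_pleural_distance, cfg, path)
    return rois


def _place_with_cursors(volume, masks, reference, lesion_pd, cfg, path):
    if not masks.normal_parenchyma.any():
        raise RoiPlacementError("normal parenchyma mask is empty")
    spacing = np.asarray(volume.spacing)
    offsets = sphere_offsets(cfg.roi_diameter, spacing)
    cands = _candidate_orderings(volume, masks, reference, lesion_pd, cfg, path)
    cursors: dict[str, int] = {}
    taken = [reference.center]
    rois: list[RoiMeasurement] = []
    for role in ("H1", "PD2", "P3"):
        k = _select(cands[role], 0, taken, spacing, cfg.roi_diameter)
        if k < 0:
            raise RoiPlacementError(
                f"no admissible placement for comparison ROI {role} "
                "(rule: inside lung, clear of distorted/ground-glass tissue)")
        cursors[role] = k
        center = cands[role][k]
        mean, sd, mn = roi_stats(volume.voxels, center, offsets)
        rois.append(RoiMeasurement(center=center * spacing, diameter=cfg.roi_diameter,
                                   role=role, mean_hu=mean, sd_hu=sd, min_hu=mn,
                                   image_kind="LW"))
        taken.append(center * spacing)
    return rois, cands, cursors


# ---------------------------------------------------------------------------
# rules and classifiers
# ---------------------------------------------------------------------------

def consistency_check(comparisons: Sequence[RoiMeasurement | float],
                      cfg: BromOlbConfig | None = None) -> bool:
    """True iff each comparison mean is within the tolerance of their common mean."""
    tol = (cfg or BromOlbConfig()).deviation_tolerance
    means = np.array([c.mean_hu if isinstance(c, RoiMeasurement) else float(c)
                      for c in comparisons])
    if means.size != 3:
        raise ValidationError("exactly three comparison ROIs are required")
    return bool(np.all(np.abs(means - means.mean()) <= tol))


def classify_brom_olb(reference: RoiMeasurement | float,
                      comparisons: Sequence[RoiMeasurement | float]) -> bool:
    """Positive iff the reference mean is strictly lower than >= 2 of the 3
    comparison means (ties count against positivity)."""
    ref = reference.mean_hu if isinstance(reference, RoiMeasurement) else float(reference)
    means = [c.mean_hu if isinstance(c, RoiMeasurement) else float(c) for c in comparisons]
    if len(means) != 3:
        raise ValidationError("exactly three comparison ROIs are required")
    return sum(ref < m for m in means) >= 2


def classify_absolute(value: float, threshold: float = -850.0) -> bool:
    """Absolute classifier: positive iff the density is at or below the threshold."""
    return bool(value <= threshold)


# ---------------------------------------------------------------------------
# full per-case assessment
# ---------------------------------------------------------------------------

def _minip_stat(meas: RoiMeasurement, cfg: BromOlbConfig) -> float:
    return meas.min_hu if cfg.minip_statistic == "min" else meas.mean_hu


def assess_case(volume: CTVolume, masks: TruthMasks, path: NeedlePath,
                cfg: BromOlbConfig | None = None) -> BromOlbAssessment:
    """Run the full BROM-OLB procedure on one case.

    Orchestrates: MinIP rendering, reference search on source HU, comparison
    placement, MinIP re-evaluation with repositioning of inconsistent
    comparison ROIs, the 20-HU consistency rule and both positivity calls.
    Enhanced display images never contribute HU values. Failures surface as
    an unevaluable assessment with the violated rule as the reason.
    """
    cfg = cfg or BromOlbConfig()
    spacing = np.asarray(volume.spacing)
    offsets = sphere_offsets(cfg.roi_diameter, spacing)
    minip = minip_slab(volume, cfg.minip_slab_mm, axis=0).voxels

    reference = find_reference_roi(volume, path, cfg, lesion_mask=masks.lesion)
    ref_idx = np.round(reference.center / spacing).astype(int)
    m_mean, m_sd, m_min = roi_stats(minip, ref_idx, offsets)
    reference_minip = RoiMeasurement(center=reference.center, diameter=cfg.roi_diameter,
                                     role="R", mean_hu=m_mean, sd_hu=m_sd,
                                     min_hu=m_min, image_kind="MinIP")

    # PD2 matches the lesion's shortest distance to the pleura, measured the
    # same way as candidate depth (distance transform of the lung mask)
    if masks.lesion.any():
        edt_lung = ndimage.distance_transform_edt(volume.lung_mask,
                                                  sampling=volume.spacing)
        centroid = np.round(ndimage.center_of_mass(masks.lesion)).astype(int)
        lesion_pd = float(edt_lung[tuple(centroid)])
    else:
        lesion_pd = path.pleura_to_lesion_distance
    try:
        rois, cands, cursors = _place_with_cursors(volume, masks, reference,
                                                   lesion_pd, cfg, path)
    except RoiPlacementError as err:
        return _unevaluable(reference, reference_minip, cfg, str(err))

    def minip_rois(lw_rois):
        out = []
        for roi in lw_rois:
            c = np.round(roi.center / spacing).astype(int)
            mm, ms, mn = roi_stats(minip, c, offsets)
            out.append(RoiMeasurement(center=roi.center, diameter=cfg.roi_diameter,
                                      role=roi.role, mean_hu=mm, sd_hu=ms,
                                      min_hu=mn, image_kind="MinIP"))
        return out

    n_repositions = 0
    reason = None
    for _ in range(cfg.max_reposition_attempts + 1):
        comp_minip = minip_rois(rois)
        lw_ok = consistency_check(rois, cfg)
        minip_ok = consistency_check(comp_minip, cfg)
        if lw_ok and minip_ok:
            break
        # reposition the worst offender on the failing image into the next
        # admissible centre of its ordered candidate list
        if n_repositions >= cfg.max_reposition_attempts:
            reason = "comparison ROIs never satisfied the 20-HU consistency rule"
            break
        ms = [r.mean_hu for r in (rois if not lw_ok else comp_minip)]
        dev = np.abs(np.array(ms) - np.mean(ms))
        worst = int(np.argmax(dev))
        role = ("H1", "PD2", "P3")[worst]
        taken = [reference.center] + [r.center for i, r in enumerate(rois) if i != worst]
        k = _select(cands[role], cursors[role] + 1, taken, spacing, cfg.roi_diameter)
        if k < 0:
            reason = f"no admissible repositioning left for comparison ROI {role}"
            break
        cursors[role] = k
        center = cands[role][k]
        mean, sd, mn = roi_stats(volume.voxels, center, offsets)
        rois[worst] = RoiMeasurement(center=center * spacing, diameter=cfg.roi_diameter,
                                     role=role, mean_hu=mean, sd_hu=sd, min_hu=mn,
                                     image_kind="LW")
        n_repositions += 1

    comp_minip = minip_rois(rois)
    consistency_ok = consistency_check(rois, cfg) and consistency_check(comp_minip, cfg)
    lw_value = reference.mean_hu
    minip_value = _minip_stat(reference_minip, cfg)
    return BromOlbAssessment(
        reference=reference,
        reference_minip=reference_minip,
        comparisons=rois,
        comparisons_minip=comp_minip,
        consistency_ok=consistency_ok,
        positive_lw=classify_brom_olb(reference.mean_hu, [r.mean_hu for r in rois]),
        positive_minip=classify_brom_olb(minip_value,
                                         [_minip_stat(r, cfg) for r in comp_minip]),
        lw_value=lw_value,
        minip_value=minip_value,
        minip_le_850=classify_absolute(minip_value, cfg.absolute_threshold),
        lw_le_850=classify_absolute(lw_value, cfg.absolute_threshold),
        n_repositions=n_repositions,
        unevaluable_reason=reason,
    )


def _unevaluable(reference, reference_minip, cfg, reason) -> BromOlbAssessment:
    lw_value = reference.mean_hu
    minip_value = _minip_stat(reference_minip, cfg)
    return BromOlbAssessment(
        reference=reference, reference_minip=reference_minip,
        comparisons=[], comparisons_minip=[], consistency_ok=False,
        positive_lw=False, positive_minip=False,
        lw_value=lw_value, minip_value=minip_value,
        minip_le_850=classify_absolute(minip_value, cfg.absolute_threshold),
        lw_le_850=classify_absolute(lw_value, cfg.absolute_threshold),
        unevaluable_reason=reason,
    )
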