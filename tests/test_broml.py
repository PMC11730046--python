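"""BROM-OLB procedure: reference search, rule-based comparison placement,
consistency rule, majority vote, and the full per-case assessment."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from bromolb import (BromOlbConfig, PhantomParams, RoiPlacementError,
                     ValidationError, assess_case, classify_absolute,
                     classify_brom_olb, consistency_check, find_reference_roi,
                     generate_phantom, place_comparison_rois)
from bromolb.broml import sphere_offsets


# ---------------------------------------------------------------------------
# independent corridor-scan oracle
# ---------------------------------------------------------------------------

def corridor_candidates(vol, masks, path, cfg):
    """Exhaustive candidate scan for the reference ROI (phantom needles run
    along +y, so the intrapulmonary segment is recovered by marching the
    column). Returns (centers, means, pleural_point)."""
    sz, sy, sx = vol.spacing
    z0 = int(round(path.entry_point[0] / sz))
    x0 = int(round(path.entry_point[2] / sx))
    col_lung = vol.lung_mask[z0, :, x0]
    y_a = int(np.argmax(col_lung))
    col_les = masks.lesion[z0, :, x0]
    y_b = int(np.argmax(col_les)) - 1 if col_les.any() else len(col_les) - 1
    a = np.array([z0 * sz, y_a * sy, x0 * sx])
    b = np.array([z0 * sz, y_b * sy, x0 * sx])

    edt_lung = ndimage.distance_transform_edt(vol.lung_mask, sampling=vol.spacing)
    d_les = ndimage.distance_transform_edt(~masks.lesion, sampling=vol.spacing)
    offsets = sphere_offsets(cfg.roi_diameter, vol.spacing)
    r = cfg.roi_diameter / 2.0

    pad = int(np.ceil(cfg.corridor_radius + r)) + 1
    centers, means = [], []
    for iz in range(max(0, z0 - pad), min(vol.voxels.shape[0], z0 + pad + 1)):
        for iy in range(vol.voxels.shape[1]):
            for ix in range(max(0, x0 - pad), min(vol.voxels.shape[2], x0 + pad + 1)):
                p = np.array([iz * sz, iy * sy, ix * sx])
                t = np.clip(np.dot(p - a, b - a) / max(np.dot(b - a, b - a), 1e-12), 0, 1)
                if np.linalg.norm(p - (a + t * (b - a))) > cfg.corridor_radius + 1e-6:
                    continue
                if edt_lung[iz, iy, ix] <= r or d_les[iz, iy, ix] <= r:
                    continue
                idx = np.array([iz, iy, ix]) + offsets
                centers.append((iz, iy, ix))
                means.append(vol.voxels[idx[:, 0], idx[:, 1], idx[:, 2]].mean())
    return np.array(centers), np.array(means), a


def test_reference_tiebreak_prefers_pleural_entry(homogeneous_case):
    vol, masks, path = homogeneous_case
    cfg = BromOlbConfig()
    centers, means, pleura = corridor_candidates(vol, masks, path, cfg)
    assert np.ptp(means) < 1e-12          # constant lung: every candidate ties
    ref = find_reference_roi(vol, path, cfg, lesion_mask=masks.lesion)
    d = np.linalg.norm(centers * np.array(vol.spacing) - pleura, axis=1)
    assert np.linalg.norm(ref.center - pleura) <= d.min() + 1e-9


def test_reference_found_by_exhaustive_scan(onroute_case):
    vol, masks, path = onroute_case
    cfg = BromOlbConfig()
    centers, means, _ = corridor_candidates(vol, masks, path, cfg)
    ref = find_reference_roi(vol, path, cfg, lesion_mask=masks.lesion)
    assert ref.mean_hu == pytest.approx(means.min(), abs=1e-9)
    iz, iy, ix = np.round(ref.center / np.array(vol.spacing)).astype(int)
    assert masks.emphysema[iz, iy, ix]    # lowest ROI sits in the planted cluster


def test_zero_corridor_radius_restricts_to_path_line(gradient_case):
    vol, masks, path = gradient_case
    cfg = BromOlbConfig(corridor_radius=1e-9)
    ref = find_reference_roi(vol, path, cfg, lesion_mask=masks.lesion)
    assert ref.center[0] == path.entry_point[0]   # same z as the needle line
    assert ref.center[2] == path.entry_point[2]   # same x


def test_reference_fails_outside_lung(homogeneous_case):
    vol, masks, path = homogeneous_case
    import dataclasses
    bad = dataclasses.replace(path, entry_point=np.array([1.0, 0.0, 1.0]),
                              target_point=np.array([1.0, 5.0, 1.0]))
    with pytest.raises(RoiPlacementError):
        find_reference_roi(vol, bad, BromOlbConfig(), lesion_mask=masks.lesion)


# ---------------------------------------------------------------------------
# comparison placement
# ---------------------------------------------------------------------------

def test_placement_in_homogeneous_lung_matches_parenchyma(homogeneous_case):
    vol, masks, path = homogeneous_case
    cfg = BromOlbConfig()
    ref = find_reference_roi(vol, path, cfg, lesion_mask=masks.lesion)
    rois = place_comparison_rois(vol, masks, ref, 10.0, cfg, path=path)
    assert [r.role for r in rois] == ["H1", "PD2", "P3"]
    for r in rois:
        assert r.mean_hu == pytest.approx(-750.0, abs=1e-9)


def test_placement_fails_with_empty_normal_mask(homogeneous_case):
    vol, masks, path = homogeneous_case
    import copy
    m = copy.deepcopy(masks)
    m.normal_parenchyma = np.zeros_like(m.normal_parenchyma)
    ref = find_reference_roi(vol, path, BromOlbConfig(), lesion_mask=m.lesion)
    with pytest.raises(RoiPlacementError):
        place_comparison_rois(vol, m, ref, 10.0, BromOlbConfig(), path=path)


def test_vertical_gradient_is_tracked_by_placement(gradient_case):
    # on a vertical-gradient-only phantom every ROI mean is an exact linear
    # function of its gravity level (1 HU per mm at 10 HU/cm)
    vol, masks, path = gradient_case
    a = assess_case(vol, masks, path)
    g = vol.gravity_axis
    ref_level = float(a.reference.center @ g)
    for roi in [a.reference] + a.comparisons:
        level = float(roi.center @ g)
        expected = a.reference.mean_hu + 1.0 * (level - ref_level)
        assert roi.mean_hu == pytest.approx(expected, abs=1e-6)
    h1 = a.comparisons[0]
    assert abs(float(h1.center @ g) - ref_level) <= BromOlbConfig().vertical_band_halfwidth


# ---------------------------------------------------------------------------
# rules and classifiers
# ---------------------------------------------------------------------------

def test_consistency_rule_arithmetic():
    assert consistency_check([-750.0, -755.0, -760.0]) is True
    assert consistency_check([-700.0, -750.0, -800.0]) is False
    assert consistency_check([-750.0, -750.0, -750.0]) is True
    with pytest.raises(ValidationError):
        consistency_check([-750.0, -751.0])


def test_majority_vote_examples_and_enumeration():
    assert classify_brom_olb(-900.0, [-750.0, -760.0, -770.0]) is True
    assert classify_brom_olb(-760.0, [-750.0, -765.0, -770.0]) is False
    assert classify_brom_olb(-750.0, [-750.0, -750.0, -750.0]) is False
    # exhaustive: vote equals the brute-force count over all sign patterns
    for deltas in itertools.product([-5.0, 0.0, 5.0], repeat=3):
        comps = [-750.0 + d for d in deltas]
        expected = sum(-750.0 < c for c in comps) >= 2
        assert classify_brom_olb(-750.0, comps) is expected
        for perm in itertools.permutations(comps):
            assert classify_brom_olb(-750.0, list(perm)) is expected


def test_absolute_threshold_is_inclusive():
    assert classify_absolute(-851.0) is True
    assert classify_absolute(-850.0) is True
    assert classify_absolute(-769.0) is False


# ---------------------------------------------------------------------------
# full assessment
# ---------------------------------------------------------------------------

def test_assess_homogeneous_phantom_negative(homogeneous_case):
    vol, masks, path = homogeneous_case
    a = assess_case(vol, masks, path)
    assert a.evaluable and a.consistency_ok
    assert a.positive_lw is False and a.positive_minip is False
    assert a.lw_value == pytest.approx(-750.0, abs=1e-9)
    assert a.minip_value == pytest.approx(-750.0, abs=1e-9)


def test_assess_cluster_on_route_positive(onroute_case):
    vol, masks, path = onroute_case
    a = assess_case(vol, masks, path)
    assert a.evaluable
    assert a.positive_lw and a.positive_minip
    assert a.minip_value <= a.lw_value


def test_assess_clusters_off_route_negative_despite_low_density(offroute_case):
    vol, masks, path = offroute_case
    a = assess_case(vol, masks, path)
    assert a.evaluable
    assert a.positive_lw is False and a.positive_minip is False


def test_minip_value_never_exceeds_lw_value():
    for seed in (21, 22, 23):
        vol, masks, path = generate_phantom(PhantomParams(seed=seed))
        a = assess_case(vol, masks, path)
        assert a.minip_value <= a.lw_value + 1e-12
        for lw, mp in zip(a.comparisons, a.comparisons_minip):
            assert mp.mean_hu <= lw.mean_hu + 1e-12


def test_minip_minimum_statistic_option(onroute_case):
    vol, masks, path = onroute_case
    mean_call = assess_case(vol, masks, path, BromOlbConfig(minip_statistic="mean"))
    min_call = assess_case(vol, masks, path, BromOlbConfig(minip_statistic="min"))
    assert min_call.minip_value <= mean_call.minip_value
    assert min_call.positive_minip    # an on-route cluster stays positive


def test_unresolvable_consistency_flags_unevaluable(noisy_case):
    vol, masks, path = noisy_case
    a = assess_case(vol, masks, path, BromOlbConfig(deviation_tolerance=0.001))
    assert not a.evaluable
    assert "consistency" in a.unevaluable_reason or "repositioning" in a.unevaluable_reason
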