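"""Segmentation and the assembly decision table."""

import math

import numpy as np
import pytest

from tdpquant.segment import (
    ClassifierParams,
    ImageScene,
    SegmentationResult,
    build_cell_records,
    detect_assemblies,
    line_profile,
    segment_cells,
    segment_nuclei,
)

from conftest import PX, SAT, classify_oracle, match_to_detected, object_scene


# --------------------------------------------------------------------------
# nuclei / cells


def test_nuclei_match_ground_truth(nuclear_oracle_scene):
    cfg, scene, gt, seg, cells, assemblies = nuclear_oracle_scene
    assert seg.nucleus_labels.max() == cfg.n_cells
    for _, c in gt.cells.iterrows():
        true = gt.nucleus_labels == c.cell_id
        lab = seg.nucleus_labels[int(c.row), int(c.col)]
        assert lab > 0
        det = seg.nucleus_labels == lab
        iou = (true & det).sum() / (true | det).sum()
        assert iou >= 0.7


def test_blank_image_yields_no_labels():
    scene = ImageScene(np.zeros((128, 128)), np.zeros((128, 128)))
    assert segment_nuclei(scene).max() == 0
    assert segment_cells(scene, np.zeros((128, 128), np.int32)).max() == 0


def test_touching_nuclei_are_split():
    """Two ellipses meeting at a tangent point resolve to two labels."""
    img = np.zeros((200, 260))
    yy, xx = np.mgrid[:200, :260]
    r = 6.0 / PX  # 6 µm radius nuclei
    for cx in (100 - r, 100 + r):  # tangent at x=100
        img[((yy - 100) ** 2 + (xx - cx) ** 2) <= r * r] = 8000.0
    scene = ImageScene(img, np.zeros_like(img))
    labels = segment_nuclei(scene)
    assert labels.max() == 2
    assert labels[100, int(100 - r)] != labels[100, int(100 + r)]


def test_every_nucleus_pixel_belongs_to_its_cell(nuclear_oracle_scene):
    _, scene, gt, seg, *_ = nuclear_oracle_scene
    nz = seg.nucleus_labels > 0
    np.testing.assert_array_equal(seg.cell_labels[nz], seg.nucleus_labels[nz])


# --------------------------------------------------------------------------
# decision table


@pytest.mark.parametrize("diameter_um", [0.4, 0.5, 2.0, 4.0, 5.0])
@pytest.mark.parametrize("frac", [0.24, 0.26, 0.59, 0.61, 0.70])
def test_disk_classification_battery(diameter_um, frac):
    """Homogeneous disks classify per the printed thresholds, bit-exactly."""
    scene, seg = object_scene(
        [{"center": (100, 100), "diameter_um": diameter_um, "value": frac * SAT}],
        nucleus=((100, 100), 8.0),
    )
    recs = detect_assemblies(scene, seg)
    if frac < 0.25:
        assert recs == []
        return
    mask = scene.exogenous >= 0.25 * SAT
    expected = classify_oracle(mask.sum(), frac, core_rim_ratio=1.0)
    if expected is None:
        assert recs == []
    else:
        assert [r.cls for r in recs] == [expected]


@pytest.mark.parametrize("ratio", [0.2, 0.8])
def test_ring_core_rim_rule(ratio):
    """Dark-cored rings are anisosomes; bright-cored disks are puncta."""
    rim = 0.4 * SAT
    scene, seg = object_scene(
        [
            {
                "center": (100, 100), "diameter_um": 2.0, "value": rim,
                "core_frac": 0.4, "core_value": ratio * rim,
            }
        ],
        nucleus=((100, 100), 8.0),
    )
    # a core below the detection threshold leaves a hole; filling recovers it
    (rec,) = detect_assemblies(scene, seg)
    assert rec.cls == ("anisosome" if ratio <= 0.5 else "punctum")
    assert rec.core_rim_ratio == pytest.approx(ratio, abs=0.05)


def test_core_rim_boundary_is_inclusive():
    """An exact core/rim ratio of 0.5 classifies as anisosome (<=)."""
    from tdpquant.segment import CORE_RADIUS_FRAC

    shape = (120, 120)
    exo = np.zeros(shape)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    d2 = (yy - 60.0) ** 2 + (xx - 60.0) ** 2
    r = 1.0 / PX  # 2 µm disk
    disk = d2 <= r * r
    eq_r = math.sqrt(disk.sum() / math.pi)
    core = d2 <= (CORE_RADIUS_FRAC * eq_r) ** 2
    exo[disk] = 0.4 * SAT
    exo[disk & core] = 0.2 * SAT  # exactly half of the rim value
    nuc = np.zeros(shape, np.int32)
    nuc[d2 <= (8.0 / PX) ** 2] = 1
    scene = ImageScene(np.zeros(shape), exo, pixel_size_um=PX)
    params = ClassifierParams(puncta_intensity_frac=0.15)  # keep the core detected
    (rec,) = detect_assemblies(scene, SegmentationResult(nuc, np.ones(shape, np.int32)), params)
    assert rec.core_rim_ratio == pytest.approx(0.5, abs=1e-12)
    assert rec.cls == "anisosome"


def test_inclusion_requires_both_size_and_intensity():
    """>= 4 µm objects failing the 60% criterion are discarded into QC."""
    scene, seg = object_scene(
        [{"center": (100, 100), "diameter_um": 6.0, "value": 0.4 * SAT}],
        nucleus=((100, 100), 8.0),
    )
    recs, qc = detect_assemblies(scene, seg, return_qc=True)
    assert recs == []
    assert qc["unclassified_large"] == 1


def test_scale_covariance():
    """Same µm-scale object at doubled pixel size classifies identically."""
    for px in (PX, 2 * PX):
        scene, seg = object_scene(
            [{"center": (60, 60), "diameter_um": 3.0, "value": 0.3 * SAT}],
            shape=(120, 120), nucleus=((60, 60), 8.0), px=px,
        )
        (rec,) = detect_assemblies(scene, seg)
        assert rec.cls == "punctum"
        # rasterization at the coarser grid costs a fraction of a pixel
        assert rec.equivalent_diameter_um == pytest.approx(3.0, abs=0.2)


def test_compartment_assignment_and_tie():
    """> 50% of pixels in the nucleus means nuclear; an exact tie is nuclear."""
    shape = (120, 120)
    exo = np.zeros(shape)
    exo[50:60, 55:65] = 0.4 * SAT  # 10x10 square straddling the boundary
    nuc = np.zeros(shape, np.int32)
    nuc[:, :60] = 1  # nucleus = left half-plane: exactly 50 of 100 pixels
    cell = np.ones(shape, np.int32)
    scene = ImageScene(np.zeros(shape), exo, pixel_size_um=PX)
    (rec,) = detect_assemblies(scene, SegmentationResult(nuc, cell))
    assert rec.compartment == "nuclear"
    nuc2 = np.zeros(shape, np.int32)
    nuc2[:, :58] = 1  # 30% inside
    (rec,) = detect_assemblies(scene, SegmentationResult(nuc2, cell))
    assert rec.compartment == "cytoplasmic"


def test_border_objects_flagged():
    scene, seg = object_scene(
        [{"center": (0, 60), "diameter_um": 2.0, "value": 0.4 * SAT}],
        shape=(120, 120), nucleus=((60, 60), 8.0),
    )
    (rec,) = detect_assemblies(scene, seg)
    assert rec.on_border


def test_oracle_classification_on_rendered_scene(nuclear_oracle_scene):
    _, scene, gt, seg, cells, assemblies = nuclear_oracle_scene
    pairs = match_to_detected(gt, assemblies, scene.endogenous.shape)
    assert pairs
    for truth, det in pairs:
        assert det is not None
        assert det.cls == truth.true_class


# --------------------------------------------------------------------------
# cell records and profiles


def test_cell_record_partition_is_exact(nuclear_oracle_scene):
    _, scene, gt, seg, cells, assemblies = nuclear_oracle_scene
    for c in cells:
        seq = sum(a.endogenous_sum_nuclear for a in assemblies if a.cell_id == c.id)
        assert c.nuclear_diffuse_sum + seq == c.nuclear_total_sum


def test_line_profile_shapes():
    rim = 0.4 * SAT
    scene, _ = object_scene(
        [
            {"center": (100, 60), "diameter_um": 3.0, "value": rim,
             "core_frac": 0.5, "core_value": 0.1 * rim},
            {"center": (100, 150), "diameter_um": 2.0, "value": rim},
        ],
        shape=(200, 220), nucleus=((100, 100), 12.0),
    )
    # across the ring: two shell maxima with a central dip
    prof = line_profile(scene, (100, 40), (100, 80))
    vals = prof.exogenous.to_numpy()
    centre = vals[len(vals) // 2]
    assert vals.max() == pytest.approx(rim)
    assert centre < 0.5 * vals.max()
    # across the homogeneous punctum: a single plateau, no dip
    prof = line_profile(scene, (100, 140), (100, 160))
    vals = prof.exogenous.to_numpy()
    assert vals[len(vals) // 2] == pytest.approx(vals.max())
    # uniform background: constant profile
    prof = line_profile(scene, (10, 10), (10, 200))
    assert np.ptp(prof.exogenous.to_numpy()) == 0
    # control-mean normalization rescales channels
    prof = line_profile(scene, (100, 140), (100, 160), control_means=(1.0, rim))
    assert prof.exogenous.max() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        line_profile(scene, (10, 10), (10, 10))
    with pytest.raises(ValueError):
        line_profile(scene, (-5, 10), (10, 10))


def test_classifier_params_validation():
    with pytest.raises(ValueError):
        ClassifierParams(puncta_intensity_frac=0.7)
    with pytest.raises(ValueError):
        ClassifierParams(puncta_min_diameter_um=5.0)
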