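"""Control references, pool partitioning, summaries, regressions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdpquant import quantify
from tdpquant.quantify import (
    build_control_reference,
    flag_sequestering,
    partition_endogenous,
    regress_concentration,
    summarize_image,
)
from tdpquant.segment import AssemblyRecord, CellRecord

from conftest import NUCLEAR_ORACLE
from tdpquant.io import process_scene
from tdpquant.synthetic import SceneConfig, render_scene


def make_cell(cid=1, diffuse_mean=1.0, total_mean=None, exo=0.0, nucleus_px=1000,
              total_sum=None, diffuse_sum=None, diffuse_px=None):
    total_mean = diffuse_mean if total_mean is None else total_mean
    return CellRecord(
        id=cid,
        nucleus_area_px=nucleus_px,
        cell_area_px=2 * nucleus_px,
        nuclear_endogenous_total_mean=total_mean,
        nuclear_endogenous_diffuse_mean=diffuse_mean,
        nuclear_total_sum=total_mean * nucleus_px if total_sum is None else total_sum,
        nuclear_diffuse_sum=diffuse_mean * nucleus_px if diffuse_sum is None else diffuse_sum,
        diffuse_area_px=nucleus_px if diffuse_px is None else diffuse_px,
        exogenous_level=exo,
    )


def make_assembly(aid=1, cid=1, cls="punctum", comp="nuclear", mean_endo=0.0,
                  seq_nuc=0.0, seq_cyt=0.0, px_nuc=0, px_cyt=0, area=1.0):
    return AssemblyRecord(
        id=aid, cell_id=cid, cls=cls, compartment=comp,
        rows=np.empty(0, int), cols=np.empty(0, int),
        area_um2=area, equivalent_diameter_um=2 * math.sqrt(area / math.pi),
        mean_exogenous=0.0, max_exogenous=0.0, mean_endogenous=mean_endo,
        core_rim_ratio=math.nan, on_border=False,
        endogenous_sum_nuclear=seq_nuc, endogenous_sum_cytoplasmic=seq_cyt,
        n_px_nuclear=px_nuc, n_px_cytoplasmic=px_cyt,
    )


# --------------------------------------------------------------------------
# control reference


def test_quartile_interpolation():
    """Diffuse means {1,2,3,4} give Q1 = 1.75 by linear interpolation."""
    cells = [make_cell(cid=i, diffuse_mean=v) for i, v in enumerate([1, 2, 3, 4])]
    ref = build_control_reference(cells)
    assert ref.control_diffuse_Q1 == pytest.approx(1.75)


def test_quartile_of_identical_values():
    cells = [make_cell(cid=i, diffuse_mean=3.5) for i in range(6)]
    assert build_control_reference(cells).control_diffuse_Q1 == 3.5


def test_permutation_invariance():
    vals = [5.0, 1.0, 9.0, 2.0, 7.0]
    a = build_control_reference([make_cell(cid=i, diffuse_mean=v) for i, v in enumerate(vals)])
    b = build_control_reference(
        [make_cell(cid=i, diffuse_mean=v) for i, v in enumerate(sorted(vals))]
    )
    assert a == b


def test_too_few_control_cells():
    with pytest.raises(ValueError):
        build_control_reference([make_cell(), make_cell(cid=2)])


@given(st.lists(st.floats(0, 1e5), min_size=4, max_size=40))
@settings(max_examples=200, deadline=None)
def test_quartile_matches_bruteforce(values):
    """Q1 agrees with the sort-based interpolation formula."""
    cells = [make_cell(cid=i, diffuse_mean=v) for i, v in enumerate(values)]
    ref = build_control_reference(cells)
    xs = sorted(values)
    pos = 0.25 * (len(xs) - 1)
    lo, frac = int(math.floor(pos)), pos - math.floor(pos)
    expected = xs[lo] if frac == 0 else xs[lo] * (1 - frac) + xs[lo + 1] * frac
    assert ref.control_diffuse_Q1 == pytest.approx(expected, rel=1e-12, abs=1e-9)


# --------------------------------------------------------------------------
# sequestration flags and partitioning


def test_sequestering_flag_is_strict():
    ref = quantify.ControlReference(2.0, 1.0, 1.0, 0.5)
    recs = [
        make_assembly(aid=1, mean_endo=2.0),  # exactly Q1: not sequestering
        make_assembly(aid=2, mean_endo=4.0),
    ]
    flag_sequestering(recs, ref)
    assert [r.sequestering for r in recs] == [False, True]


def test_partition_no_assemblies():
    q = partition_endogenous(make_cell(diffuse_mean=2.0), [])
    assert q.proportion_sequestered == 0.0
    assert q.diffuse_signal == q.sequestered_signal + q.diffuse_signal


def test_partition_closed_form():
    """One assembly over 10% of the nucleus at 5x diffuse: 5/14 sequestered."""
    c = 2.0  # diffuse concentration
    nucleus_px = 1000
    asm_px = 100
    cell = make_cell(
        nucleus_px=nucleus_px,
        total_sum=c * 900 + 5 * c * asm_px,
        diffuse_sum=c * 900,
        diffuse_px=900,
        total_mean=(c * 900 + 5 * c * 100) / 1000,
        diffuse_mean=c,
    )
    asm = make_assembly(seq_nuc=5 * c * asm_px, px_nuc=asm_px)
    q = partition_endogenous(cell, [asm])
    assert q.proportion_sequestered == pytest.approx(5.0 / 14.0, abs=1e-12)
    assert q.diffuse_signal + q.sequestered_nuclear_signal == cell.nuclear_total_sum


def test_partition_requires_nucleus():
    bad = make_cell(nucleus_px=0)
    with pytest.raises(ValueError):
        partition_endogenous(bad, [])


def test_partition_recovers_ground_truth(nuclear_oracle_scene):
    """Noiseless scene: measured proportion within 2% of generator truth."""
    _, scene, gt, seg, cells, assemblies = nuclear_oracle_scene
    for _, truth in gt.cells.iterrows():
        lab = seg.nucleus_labels[int(truth.row), int(truth.col)]
        cell = next(c for c in cells if c.id == lab)
        q = partition_endogenous(cell, assemblies)
        assert q.proportion_sequestered == pytest.approx(
            truth.proportion_sequestered, abs=0.02
        )


def test_control_neutrality(control_scene):
    """GFP-only cells: mean diffuse fold-change is 1 within noise."""
    _, scene, gt, seg, cells, assemblies = control_scene
    ref = build_control_reference(cells)
    quants = [partition_endogenous(c, assemblies, ref) for c in cells]
    assert np.mean([q.fold_diffuse_nuclear for q in quants]) == pytest.approx(1.0, abs=0.05)
    assert all(q.proportion_sequestered == 0 for q in quants)


def test_monotone_response_across_coefficients():
    """Higher partition coefficient: lower diffuse fold, more sequestered."""
    diffuse_frac, seq_prop = [], []
    for k in (1.0, 4.0, 8.0):
        cfg = SceneConfig(
            n_cells=8, image_shape_px=(512, 512), seed=31,
            **{**NUCLEAR_ORACLE, "sequestration_coefficient": k},
        )
        scene, gt = render_scene(cfg)
        _, cells, assemblies, _ = process_scene(scene)
        quants = [partition_endogenous(c, assemblies) for c in cells]
        expressing = [q for q in quants if q.sequestered_signal > 0]
        diffuse_frac.append(np.mean([q.diffuse_signal for q in expressing]))
        seq_prop.append(np.mean([q.proportion_sequestered for q in expressing]))
    assert diffuse_frac[0] > diffuse_frac[1] > diffuse_frac[2]
    assert seq_prop[0] < seq_prop[1] < seq_prop[2]


# --------------------------------------------------------------------------
# summaries and regressions


def test_summary_frequencies():
    cells = [make_cell(cid=i) for i in range(1, 11)]
    assemblies = [
        make_assembly(aid=j, cid=j, cls="punctum") for j in range(1, 5)
    ]  # 4 of 10 cells have a punctum
    s = summarize_image(cells, assemblies)
    assert s.pct_cells_with_puncta == pytest.approx(40.0)
    assert s.puncta_per_cell == pytest.approx(0.4)
    assert math.isnan(s.pct_transfected_with_inclusions)  # nobody gated


def test_summary_without_transfected_cells_is_nan_not_zero():
    cells = [make_cell(cid=i) for i in range(1, 5)]
    for c in cells:
        c.transfected = False
    s = summarize_image(cells, [])
    assert math.isnan(s.pct_transfected_with_inclusions)
    assert math.isnan(s.inclusions_per_transfected_cell)


def test_summary_empty():
    s = summarize_image([], [])
    assert s.n_cells == 0 and math.isnan(s.pct_cells_with_puncta)


def test_regression_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    r = regress_concentration(x, -0.5 * x + 2.0)
    assert r.slope == pytest.approx(-0.5)
    assert r.intercept == pytest.approx(2.0)
    assert r.r_squared == pytest.approx(1.0)


def test_regression_errors():
    with pytest.raises(ValueError):
        regress_concentration([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        regress_concentration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def test_regression_slope_ordering_by_coefficient():
    """Steeper diffuse depletion for the higher partition coefficient."""
    slopes = {}
    for k in (2.0, 6.0):
        exos, diffs, seqs = [], [], []
        for seed in (300, 301, 302):
            cfg = SceneConfig(
                variant="WT", n_cells=10, image_shape_px=(640, 640),
                assembly_rates={"punctum": 2.0}, sequestration_coefficient=k,
                noise_sd=150.0, overlap_policy="drop", seed=seed,
            )
            scene, gt = render_scene(cfg)
            _, cells, assemblies, _ = process_scene(scene)
            for c in cells:
                q = partition_endogenous(c, assemblies)
                exos.append(c.exogenous_level)
                diffs.append(q.diffuse_signal)
                seqs.append(q.sequestered_signal)
        exos, diffs, seqs = map(np.array, (exos, diffs, seqs))
        sel = exos > 500  # transfected cells
        slopes[k] = (
            regress_concentration(exos[sel], diffs[sel]).slope,
            regress_concentration(exos[sel], seqs[sel]).slope,
        )
    assert slopes[2.0][0] < 0 and slopes[6.0][0] < 0
    assert slopes[2.0][1] > 0 and slopes[6.0][1] > 0
    assert abs(slopes[6.0][0]) > abs(slopes[2.0][0])
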