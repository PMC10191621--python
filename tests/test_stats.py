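"""Tests for the derived statistics: fold changes, translation
dependence, flow-cytometry medians, ensemble spread, and the nucleolar
ring-to-cell intensity ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsrkinetics import (
    CountTable,
    DomainError,
    FlowSample,
    ensemble_variation,
    fetch_geo_supplementary,
    median_reporter,
    relative_expression,
    ring_to_cell_ratio,
    translation_dependence,
    translation_dependence_from_table,
)
from hsrkinetics.simulate import Ensemble, Trajectory


def make_table(rows: dict, design=None) -> CountTable:
    """Counts from {gene: {sample: count}} with a default 2-replicate
    NHS/HS x untreated/CHX design inferred from sample names."""
    counts = pd.DataFrame(rows).T
    counts.index.name = "gene"
    meta = []
    for name in counts.columns:
        heat, chx, rep = name.split("_")
        meta.append({"sample": name, "heat": heat, "chx": chx, "replicate": rep})
    samples = pd.DataFrame(meta).set_index("sample")
    return CountTable(counts=counts, samples=samples)


def uniform_table(nhs=10, hs=100, nhs_chx=10, hs_chx=30, n_genes=4):
    rows = {
        f"g{i}": {
            "NHS_untreated_1": nhs, "NHS_untreated_2": nhs,
            "HS_untreated_1": hs, "HS_untreated_2": hs,
            "NHS_CHX_1": nhs_chx, "NHS_CHX_2": nhs_chx,
            "HS_CHX_1": hs_chx, "HS_CHX_2": hs_chx,
        }
        for i in range(n_genes)
    }
    return make_table(rows)


# ---------------------------------------------------------------------------
# relative expression
# ---------------------------------------------------------------------------


def test_fold_change_ratio_arithmetic():
    table = uniform_table(nhs=10, hs=100)
    folds = relative_expression(table, pseudocount=0.0, depth_normalize=False)
    assert np.allclose(folds["untreated"], 10.0)
    assert np.allclose(folds["CHX"], 3.0)


def test_identical_counts_give_unit_fold():
    table = uniform_table(nhs=50, hs=50, nhs_chx=50, hs_chx=50)
    folds = relative_expression(table, pseudocount=0.0, depth_normalize=False)
    assert np.allclose(folds.to_numpy(), 1.0)


def test_pseudocount_guards_zero_denominator():
    table = uniform_table(nhs=0, hs=49.5, nhs_chx=1, hs_chx=1)
    folds = relative_expression(table, pseudocount=0.5, depth_normalize=False)
    assert np.allclose(folds["untreated"], 100.0)


def test_missing_stratum_named_in_error():
    table = uniform_table()
    kept = [c for c in table.counts.columns if not c.startswith("NHS_CHX")]
    broken = CountTable(counts=table.counts[kept], samples=table.samples.loc[kept])
    with pytest.raises(DomainError, match="NHS"):
        relative_expression(broken)


def test_depth_normalization_invariant_to_library_scaling():
    """With normalization on, multiplying any library by a constant
    (deeper sequencing of that sample) leaves all fold changes intact."""
    rng = np.random.default_rng(2)
    rows = {
        f"g{i}": {
            name: int(c)
            for name, c in zip(
                ["NHS_untreated_1", "NHS_untreated_2", "HS_untreated_1",
                 "HS_untreated_2", "NHS_CHX_1", "NHS_CHX_2", "HS_CHX_1", "HS_CHX_2"],
                rng.integers(20, 400, size=8),
            )
        }
        for i in range(6)
    }
    table = make_table(rows)
    base = relative_expression(table, pseudocount=0.0, depth_normalize=True)
    counts = table.counts.copy()
    counts["HS_untreated_1"] *= 3
    counts["NHS_CHX_2"] *= 2
    scaled = CountTable(counts=counts, samples=table.samples)
    rescaled = relative_expression(scaled, pseudocount=0.0, depth_normalize=True)
    assert np.allclose(base.to_numpy(), rescaled.to_numpy(), rtol=1e-12)


# ---------------------------------------------------------------------------
# translation dependence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fu,fc,expected",
    [(10.0, 3.0, 0.7), (4.0, 4.0, 0.0), (10.0, 1e-9, 1.0)],
)
def test_dependence_formula(fu, fc, expected):
    genes = ["a", "b"]
    dep, summary = translation_dependence(
        pd.Series(fu, index=genes), pd.Series(fc, index=genes)
    )
    assert np.allclose(dep, expected, atol=1e-8)
    assert summary["mean"] == pytest.approx(expected, abs=1e-8)


def test_dependence_gene_mismatch_rejected():
    with pytest.raises(DomainError):
        translation_dependence(
            pd.Series([2.0], index=["a"]), pd.Series([1.0], index=["b"])
        )


@given(scale=st.floats(0.01, 100))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_dependence_invariant_to_common_rescaling(scale):
    genes = ["a", "b", "c"]
    fu = pd.Series([10.0, 5.0, 2.0], index=genes)
    fc = pd.Series([3.0, 5.0, 1.0], index=genes)
    base, _ = translation_dependence(fu, fc)
    scaled, _ = translation_dependence(fu * scale, fc * scale)
    assert np.allclose(base, scaled, rtol=1e-9)


def test_end_to_end_dependence_from_toy_table():
    dep, summary = translation_dependence_from_table(
        uniform_table(), pseudocount=0.0, depth_normalize=False
    )
    assert summary["mean"] == pytest.approx(0.7)
    assert summary["median"] == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------


def test_median_reporter_constant_ratio():
    sample = FlowSample(fluorescence=np.full(10, 6.0), scatter=np.full(10, 2.0))
    assert median_reporter(sample) == 3.0


def test_median_reporter_robust_to_outlier():
    sample = FlowSample(fluorescence=np.array([1.0, 2.0, 100.0]), scatter=np.ones(3))
    assert median_reporter(sample) == 2.0


def test_median_reporter_invariant_to_per_cell_size_factor():
    rng = np.random.default_rng(0)
    fl = rng.uniform(1, 5, 50)
    sc = rng.uniform(1, 3, 50)
    factor = rng.uniform(0.5, 2.0, 50)
    a = median_reporter(FlowSample(fluorescence=fl, scatter=sc))
    b = median_reporter(FlowSample(fluorescence=fl * factor, scatter=sc * factor))
    assert a == pytest.approx(b, rel=1e-12)


def test_flow_sample_requires_positive_scatter():
    with pytest.raises(DomainError):
        FlowSample(fluorescence=np.ones(3), scatter=np.array([1.0, 0.0, 2.0]))


# ---------------------------------------------------------------------------
# ensemble variation
# ---------------------------------------------------------------------------


def constant_ensemble(yfp_values):
    times = np.array([0.0, 10.0])
    trajs = []
    for v in yfp_values:
        states = np.zeros((2, 6))
        states[:, 5] = v
        states[:, 3] = 1250.0
        trajs.append(Trajectory(times=times, states=states, condition_names=("baseline",) * 2))
    return Ensemble(trajectories=tuple(trajs), draws=np.ones(len(yfp_values)), seed=0)


def test_variation_hand_values():
    spread = ensemble_variation(constant_ensemble([80.0, 100.0, 120.0]), time=5.0)
    assert spread["range_over_mean"] == pytest.approx(0.4)
    assert spread["cv"] == pytest.approx(np.sqrt(800.0 / 3.0) / 100.0)  # ~0.1633


def test_variation_zero_for_identical_trajectories():
    spread = ensemble_variation(constant_ensemble([50.0, 50.0, 50.0]), time=5.0)
    assert spread["cv"] == 0.0
    assert spread["range_over_mean"] == 0.0


def test_variation_scale_invariant():
    a = ensemble_variation(constant_ensemble([80.0, 100.0, 120.0]), time=5.0)
    b = ensemble_variation(constant_ensemble([160.0, 200.0, 240.0]), time=5.0)
    assert a["cv"] == pytest.approx(b["cv"])
    assert a["range_over_mean"] == pytest.approx(b["range_over_mean"])


def test_variation_requires_two_trajectories():
    with pytest.raises(DomainError):
        ensemble_variation(constant_ensemble([100.0]), time=5.0)


# ---------------------------------------------------------------------------
# ring-to-cell ratio
# ---------------------------------------------------------------------------


def test_uniform_intensity_gives_unit_ratio():
    img = np.full((10, 10), 7.0)
    cell = np.ones_like(img, dtype=bool)
    ring = np.zeros_like(cell)
    ring[4:6, 4:6] = True
    assert ring_to_cell_ratio(img, ring, cell) == pytest.approx(1.0)


def test_signal_concentrated_in_ring():
    img = np.zeros((10, 10))
    cell = np.ones_like(img, dtype=bool)
    ring = np.zeros_like(cell)
    ring.flat[:10] = True  # ring = 10% of cell pixels
    img[ring] = 5.0
    assert ring_to_cell_ratio(img, ring, cell) == pytest.approx(10.0)


def test_ratio_scale_invariant_but_not_offset_invariant():
    rng = np.random.default_rng(1)
    img = rng.uniform(1, 4, (8, 8))
    cell = np.ones_like(img, dtype=bool)
    ring = np.zeros_like(cell)
    ring[2:4, 2:4] = True
    base = ring_to_cell_ratio(img, ring, cell)
    assert ring_to_cell_ratio(img * 3.5, ring, cell) == pytest.approx(base, rel=1e-12)
    offset = ring_to_cell_ratio(img + 10.0, ring, cell)
    assert offset != pytest.approx(base, rel=1e-6)


def test_empty_ring_rejected():
    img = np.ones((4, 4))
    with pytest.raises(DomainError):
        ring_to_cell_ratio(img, np.zeros((4, 4), bool), np.ones((4, 4), bool))


def test_ring_outside_cell_rejected():
    img = np.ones((4, 4))
    ring = np.zeros((4, 4), bool)
    ring[0, 0] = True
    cell = np.zeros((4, 4), bool)
    cell[2:, 2:] = True
    with pytest.raises(DomainError):
        ring_to_cell_ratio(img, ring, cell)


# ---------------------------------------------------------------------------
# CountTable I/O and network gating
# ---------------------------------------------------------------------------


def test_count_table_csv_round_trip(tmp_path):
    table = uniform_table()
    path = tmp_path / "counts.csv"
    table.to_csv(path)
    loaded = CountTable.from_csv(path)
    assert np.array_equal(loaded.counts.to_numpy(), table.counts.to_numpy())
    assert list(loaded.samples["heat"]) == list(table.samples["heat"])


def test_geo_fetch_refused_without_network_flag(tmp_path):
    with pytest.raises(DomainError, match="allow_network"):
        fetch_geo_supplementary(dest_dir=tmp_path, allow_network=False)
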