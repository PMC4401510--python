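"""EHH, iHH and XP-EHH against exhaustive pair-enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan import (
    DomainError,
    SimConfig,
    SweepSpec,
    build_ehh_curve,
    ehh_at_interval,
    integrate_ihh,
    simulate_panel,
    standardize_scores,
    xpehh_raw,
)

from conftest import make_panel


def ehh_oracle(rows: np.ndarray, lo: int, hi: int) -> float:
    """Probability two distinct rows agree over [lo, hi], by enumeration."""
    n = rows.shape[0]
    hits = sum(
        1
        for i, j in combinations(range(n), 2)
        if np.array_equal(rows[i, lo : hi + 1], rows[j, lo : hi + 1])
    )
    return hits / (n * (n - 1) / 2)


class TestEhhAtInterval:
    def test_identical_rows_give_one(self):
        rows = np.ones((5, 4), dtype=np.uint8)
        assert ehh_at_interval(rows, (0, 3)) == 1.0

    def test_multiplicities_2_1_1(self):
        rows = np.array([[0, 0], [0, 0], [0, 1], [1, 0]], dtype=np.uint8)
        assert ehh_at_interval(rows, (0, 1)) == pytest.approx(1 / 6)

    def test_all_distinct_gives_zero(self):
        rows = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        assert ehh_at_interval(rows, (0, 1)) == 0.0

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(DomainError):
            ehh_at_interval(np.ones((1, 3), dtype=np.uint8), (0, 2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        m = int(rng.integers(1, 21))
        rows = rng.integers(0, 2, size=(n, m)).astype(np.uint8)
        lo = int(rng.integers(0, m))
        hi = int(rng.integers(lo, m))
        assert ehh_at_interval(rows, (lo, hi)) == pytest.approx(
            ehh_oracle(rows, lo, hi), abs=0
        )


class TestBuildCurve:
    def test_identical_haplotypes_never_truncate(self):
        panel = make_panel(np.ones((6, 5), dtype=np.uint8))
        # make the core segregating: flip one row at the core column only
        a = panel.alleles.copy()
        a[0, 2] = 0
        panel = make_panel(a, positions=panel.positions)
        curve = build_ehh_curve(panel, ("A", "B"), core_index=2)
        # one imperfect column: pooled EHH drops once then stays flat
        assert curve.right_pooled.min() >= (5 * 4) / (6 * 5)
        assert curve.truncated_by_chromosome_end == (True, True)

    def test_first_flank_below_threshold_keeps_terminal_point(self):
        # classes {2,2,1,1} over core+first flank: pooled EHH = 2/15 < 0.2
        alleles = np.array(
            [
                [0, 0, 0, 0],
                [0, 0, 0, 1],
                [0, 1, 1, 0],
                [0, 1, 1, 1],
                [1, 0, 0, 0],
                [1, 1, 0, 1],
            ],
            dtype=np.uint8,
        )
        panel = make_panel(alleles)
        curve = build_ehh_curve(panel, ("A", "B"), core_index=0, truncation_threshold=0.2)
        assert len(curve.right_dist) == 2  # core + one terminal sub-threshold SNP
        assert curve.right_pooled[-1] == pytest.approx(2 / 15)

    def test_monomorphic_core_is_skip_signal(self):
        alleles = np.zeros((4, 3), dtype=np.uint8)
        alleles[:, 1] = [0, 1, 0, 1]
        panel = make_panel(alleles)
        assert build_ehh_curve(panel, ("A", "B"), core_index=0) is None

    def test_curve_matches_pair_enumeration_everywhere(self):
        rng = np.random.default_rng(42)
        alleles = rng.integers(0, 2, size=(6, 5)).astype(np.uint8)
        alleles[:, 2] = [0, 0, 0, 1, 1, 1]  # segregating core
        panel = make_panel(alleles)
        curve = build_ehh_curve(panel, ("A", "B"), core_index=2, truncation_threshold=0.0)
        for k, d in enumerate(curve.right_dist[1:], start=1):
            j = 2 + k
            assert curve.right_pooled[k] == pytest.approx(ehh_oracle(alleles, 2, j))
            assert curve.right_a[k] == pytest.approx(ehh_oracle(alleles[:3], 2, j))
            assert curve.right_b[k] == pytest.approx(ehh_oracle(alleles[3:], 2, j))
        for k, d in enumerate(curve.left_dist[1:], start=1):
            j = 2 - k
            assert curve.left_pooled[k] == pytest.approx(ehh_oracle(alleles, j, 2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_ehh_non_increasing_with_distance(self, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 2, size=(8, 12)).astype(np.uint8)
        core = int(rng.integers(0, 12))
        if alleles[:, core].min() == alleles[:, core].max():
            alleles[0, core] = 1 - alleles[0, core]
        panel = make_panel(alleles)
        curve = build_ehh_curve(panel, ("A", "B"), core_index=core, truncation_threshold=0.0)
        for arr in (curve.left_pooled, curve.right_pooled, curve.left_a, curve.right_b):
            assert (np.diff(arr) <= 1e-15).all()


class TestIntegrate:
    def test_rectangle(self):
        assert integrate_ihh((np.array([0.0, 250.0]), np.array([1.0, 1.0]))) == 250.0

    def test_hand_trapezoid(self):
        d = np.array([0.0, 100.0, 200.0])
        e = np.array([1.0, 0.5, 0.05])
        assert integrate_ihh((d, e)) == pytest.approx(102.5)

    def test_fine_grid_agreement(self):
        d = np.array([0.0, 100.0, 200.0])
        e = np.array([1.0, 0.5, 0.05])
        grid = np.linspace(0, 200, 2_000_001)
        fine = np.trapezoid(np.interp(grid, d, e), grid)
        assert integrate_ihh((d, e)) == pytest.approx(fine, rel=1e-9)

    def test_core_only_side_contributes_zero(self):
        assert integrate_ihh((np.array([0.0]), np.array([1.0]))) == 0.0

    def test_must_start_at_origin(self):
        with pytest.raises(DomainError):
            integrate_ihh((np.array([10.0, 20.0]), np.array([0.9, 0.5])))


@pytest.fixture(scope="module")
def small_study():
    cfg = SimConfig(2, 16, 500_000, 5e-4, seed=8)
    from sweepscan import simulate_neutral_panel

    return simulate_neutral_panel(cfg)


class TestXpehh:
    def test_identical_population_matrices_score_zero(self):
        rng = np.random.default_rng(1)
        half = rng.integers(0, 2, size=(6, 30)).astype(np.uint8)
        alleles = np.vstack([half, half])
        panel = make_panel(alleles, positions=np.arange(1, 31) * 1000)
        df = xpehh_raw(panel, ("A", "B"))
        assert (df["raw"] == 0.0).all()
        assert len(df) > 0

    def test_swapping_populations_negates_scores_exactly(self, small_study):
        ab = xpehh_raw(small_study, ("P1", "P2"))
        ba = xpehh_raw(small_study, ("P2", "P1"))
        assert (ab["position"] == ba["position"]).all()
        assert np.array_equal(ab["raw"].to_numpy(), -ba["raw"].to_numpy())

    def test_ln2_from_worked_ihh_values(self):
        assert np.log(102.5 / 51.25) == pytest.approx(np.log(2))

    def test_distance_scaling_cancels_in_ratio(self, small_study):
        from dataclasses import replace

        scaled = replace(
            small_study, positions=small_study.positions * 10, length=small_study.length * 10
        )
        a = xpehh_raw(small_study, ("P1", "P2"), max_extension=np.inf)
        b = xpehh_raw(scaled, ("P1", "P2"), max_extension=np.inf)
        assert np.allclose(a["raw"].to_numpy(), b["raw"].to_numpy(), rtol=1e-12)

    def test_sweep_shifts_scores_up_near_sweep(self):
        cfg = SimConfig(
            2, 20, 2_000_000, 1e-3,
            sweep_specs=(SweepSpec("P1", 1_000_000, 0.9, 2e5),), seed=13,
        )
        panel = simulate_panel(cfg)
        scores = standardize_scores(xpehh_raw(panel, ("P1", "P2")))
        near = scores[(scores.position >= 975_000) & (scores.position <= 1_025_000)]
        assert near["std"].mean() > scores["std"].mean() + 2.0


class TestStandardize:
    def test_worked_example(self):
        df = pd.DataFrame({"raw": [1.0, 2.0, 3.0]})
        out = standardize_scores(df)
        assert np.allclose(out["std"], [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, small_study):
        out = standardize_scores(xpehh_raw(small_study, ("P1", "P2")))
        assert abs(out["std"].mean()) < 1e-12
        assert abs(out["std"].std(ddof=1) - 1.0) < 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            standardize_scores(pd.DataFrame({"raw": [1.0]}))
        with pytest.raises(DomainError):
            standardize_scores(pd.DataFrame({"raw": [2.0, 2.0, 2.0]}))
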