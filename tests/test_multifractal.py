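import math

import numpy as np
import pytest

from cgrfractal import (
    CountPyramid,
    binomial_cascade_weights,
    build_count_pyramid,
    compute_spectrum,
    default_q_grid,
    fit_generalized_dimension,
    log_partition_sum,
    pyramid_from_points,
)

from conftest import random_reads

LN2 = math.log(2.0)


def uniform_pyramid(max_level: int, per_cell: int = 4) -> CountPyramid:
    """Exactly uniform measure: every finest cell holds the same count."""
    side = 2**max_level
    levels = {}
    for lv in range(max_level, 0, -1):
        factor = 4 ** (max_level - lv)
        levels[lv] = np.full((2**lv, 2**lv), per_cell * factor, dtype=np.int64)
    return CountPyramid(levels=levels, total=per_cell * side * side)


def column_pyramid(max_level: int, per_cell: int = 8) -> CountPyramid:
    """Measure uniform on the left-edge column of cells (support dimension 1)."""
    levels = {}
    for lv in range(max_level, 0, -1):
        grid = np.zeros((2**lv, 2**lv), dtype=np.int64)
        grid[:, 0] = per_cell * 2 ** (max_level - lv)
        levels[lv] = grid
    return CountPyramid(levels=levels, total=per_cell * 2**max_level)


def cascade_level_pairs(p: float, q: float, levels=range(6, 14)):
    """(ln eps, partition value) ladder of the 2-D product binomial cascade.

    The 2-D cascade is the outer product of the 1-D cascade with itself,
    so its partition value is exactly twice the 1-D value at every level.
    """
    pairs = []
    for lv in levels:
        u = binomial_cascade_weights(lv, p)
        pairs.append((-lv * LN2, 2.0 * log_partition_sum(u, 1.0, q)))
    return pairs


def cascade_closed_form(p: float, q: float) -> float:
    if abs(q - 1.0) < 1e-12:
        return -2.0 * (p * math.log2(p) + (1 - p) * math.log2(1 - p))
    return 2.0 * math.log2(p**q + (1 - p) ** q) / (1.0 - q)


class TestLogPartitionSum:
    def test_uniform_counts_q2(self):
        assert log_partition_sum(np.array([4, 4, 4, 4]), 16, 2.0) == pytest.approx(
            math.log(64), abs=1e-12
        )

    def test_q0_counts_occupied_cells_only(self):
        assert log_partition_sum(np.array([1, 0, 3]), 4, 0.0) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_q1_information_branch(self):
        assert log_partition_sum(np.array([4, 4, 4, 4]), 16, 1.0) == pytest.approx(
            -math.log(4), abs=1e-12
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            log_partition_sum(np.array([1, 2]), 0, 2.0)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            log_partition_sum(np.zeros(4), 4, 2.0)

    def test_matches_naive_sum_on_random_counts(self, rng):
        counts = rng.integers(0, 50, size=256)
        total = counts.sum()
        for q in (0.0, 0.4, 1.0, 2.0, 7.0):
            got = log_partition_sum(counts, total, q)
            occ = counts[counts > 0].astype(float)
            if q == 1.0:
                want = np.sum((occ / total) * np.log(occ / total))
            else:
                want = math.log(np.sum(occ**q))
            assert got == pytest.approx(want, abs=1e-10)


class TestFitGeneralizedDimension:
    @pytest.mark.parametrize("q", [0.0, 0.4, 1.0, 2.0, 15.0])
    def test_uniform_measure_has_dimension_two(self, q):
        pyr = uniform_pyramid(8)
        pairs = [
            (-lv * LN2, log_partition_sum(pyr.level(lv), pyr.total, q))
            for lv in range(3, 9)
        ]
        d, r2 = fit_generalized_dimension(pairs, q)
        assert d == pytest.approx(2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_left_edge_support_has_box_dimension_one(self):
        pyr = column_pyramid(8)
        pairs = [
            (-lv * LN2, log_partition_sum(pyr.level(lv), pyr.total, 0.0))
            for lv in range(3, 9)
        ]
        d, _ = fit_generalized_dimension(pairs, 0.0)
        assert d == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("q", [0.0, 0.6, 1.0, 2.0, 5.0, 11.0])
    def test_binomial_cascade_matches_closed_form(self, q):
        d, r2 = fit_generalized_dimension(cascade_level_pairs(0.7, q), q)
        assert d == pytest.approx(cascade_closed_form(0.7, q), abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_generalized_dimension([(0.0, 0.0), (-1.0, -2.0)], 2.0)

    def test_constant_values_fit_perfectly_with_zero_slope(self):
        d, r2 = fit_generalized_dimension([(-1.0, 5.0), (-2.0, 5.0), (-3.0, 5.0)], 0.0)
        assert d == 0.0 and r2 == 1.0


class TestComputeSpectrum:
    def test_default_q_grid_shape(self):
        q = default_q_grid()
        assert q.size == 76
        assert q[0] == 0.0 and q[-1] == 15.0
        assert np.allclose(np.diff(q), 0.2)

    def test_uniform_pyramid_spectrum_flat_at_two(self):
        spec = compute_spectrum(uniform_pyramid(8), levels=range(3, 9))
        np.testing.assert_allclose(spec.dimensions, 2.0, atol=1e-9)
        assert len(spec) == 76

    def test_negative_q_rejected_without_override(self):
        pyr = uniform_pyramid(4)
        with pytest.raises(ValueError, match="unstable"):
            compute_spectrum(pyr, q_values=[-1.0, 0.0], levels=(2, 3, 4))
        spec = compute_spectrum(
            pyr, q_values=[-1.0, 0.0], levels=(2, 3, 4), allow_negative_q=True
        )
        assert spec.dimensions[0] == pytest.approx(2.0, abs=1e-9)

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            compute_spectrum(uniform_pyramid(4), levels=(3, 4, 5))

    def test_unsorted_q_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrum(uniform_pyramid(4), q_values=[1.0, 0.5], levels=(2, 3, 4))

    def test_spectrum_equals_per_level_bruteforce_fits(self, rng):
        """Pyramid route == assembling the fit from per-level recounts."""
        reads = random_reads(rng, 80, 120)
        pyr = build_count_pyramid(reads, max_level=8)
        qs = [0.0, 1.0, 2.0, 6.0]
        spec = compute_spectrum(pyr, q_values=qs, levels=range(4, 9))
        xs, ys = [], []
        from cgrfractal import map_read

        for s in reads.sequences:
            pc = map_read(s)
            xs.append(pc.x)
            ys.append(pc.y)
        x, y = np.concatenate(xs), np.concatenate(ys)
        for j, q in enumerate(qs):
            pairs = []
            for lv in range(4, 9):
                edges = np.linspace(0, 1, 2**lv + 1)
                grid, _, _ = np.histogram2d(y, x, bins=[edges, edges])
                pairs.append((-lv * LN2, log_partition_sum(grid, x.size, q)))
            d, r2 = fit_generalized_dimension(pairs, q)
            assert spec.dimensions[j] == pytest.approx(d, abs=1e-9)
            assert spec.fit_r2[j] == pytest.approx(r2, abs=1e-9)

    def test_invariant_to_read_duplication(self, rng):
        """Doubling every read rescales counts but not the normalized measure."""
        reads = random_reads(rng, 40, 100)
        pyr1 = build_count_pyramid(reads, max_level=8)
        doubled = reads.sequences + reads.sequences
        pyr2 = build_count_pyramid(doubled, max_level=8)
        s1 = compute_spectrum(pyr1, q_values=[0.0, 1.0, 3.0], levels=range(4, 9))
        s2 = compute_spectrum(pyr2, q_values=[0.0, 1.0, 3.0], levels=range(4, 9))
        np.testing.assert_allclose(s1.dimensions, s2.dimensions, atol=1e-9)

    def test_exact_cascade_spectrum_monotone_nonincreasing(self):
        qs = np.round(np.arange(0, 8.1, 0.5), 6)
        dims = [
            fit_generalized_dimension(cascade_level_pairs(0.7, q), q)[0] for q in qs
        ]
        assert np.all(np.diff(dims) <= 1e-3)

    def test_box_dimension_bounded_by_embedding(self, rng):
        pyr = pyramid_from_points(rng.random(3000), rng.random(3000), 6)
        spec = compute_spectrum(pyr, q_values=[0.0], levels=(3, 4, 5, 6))
        assert 0.0 <= spec.dimensions[0] <= 2.0 + 1e-6

    def test_tsv_round_trip(self, tmp_path, rng):
        import pandas as pd

        pyr = pyramid_from_points(rng.random(2000), rng.random(2000), 5)
        spec = compute_spectrum(pyr, levels=(3, 4, 5))
        path = spec.save_tsv(tmp_path / "spec.tsv")
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["q", "D", "r_squared"]
        np.testing.assert_allclose(df["D"], spec.dimensions)


class TestCascadeWeights:
    def test_mass_conserved_and_sized(self):
        w = binomial_cascade_weights(6, 0.7)
        assert w.size == 64
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w.min() > 0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            binomial_cascade_weights(3, 1.0)
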