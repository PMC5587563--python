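import numpy as np
import pandas as pd
import pytest

from connectopy import (
    Connectome,
    apply_mask,
    build_connectome,
    default_parcellation,
    density_threshold,
    extract_hemisphere,
    median_summary,
)
from connectopy.connectome import (
    read_cohort_table,
    read_matrix,
    read_matrix_stack,
    round_half_up,
    write_matrix,
    write_matrix_stack,
)
from connectopy.parcellation import RegionParcellation, read_region_table, write_region_table

from conftest import random_symmetric


def tiny_parcellation(n_per_side=2, volumes=None):
    labels = tuple(f"L{i}" for i in range(n_per_side)) + tuple(
        f"R{i}" for i in range(n_per_side)
    )
    return RegionParcellation(
        labels=labels,
        hemisphere=("left",) * n_per_side + ("right",) * n_per_side,
        volume=tuple(volumes) if volumes is not None else (),
    )


class TestParcellation:
    def test_default_has_72_regions_36_per_hemisphere(self):
        p = default_parcellation()
        assert p.size == 72
        assert len(p.indices("left")) == len(p.indices("right")) == 36

    def test_rejects_duplicate_labels_and_bad_volumes(self):
        with pytest.raises(ValueError):
            RegionParcellation(("a", "a"), ("left", "right"))
        with pytest.raises(ValueError):
            RegionParcellation(("a", "b"), ("left", "right"), (1.0, -1.0))
        with pytest.raises(ValueError):
            RegionParcellation(("a", "b", "c"), ("left", "left", "right"))


class TestBuildConnectome:
    def test_zero_counts_give_zero_connectome(self):
        c = build_connectome(np.zeros((4, 4)), tiny_parcellation())
        assert np.all(c.weights == 0)

    def test_volume_normalised_symmetrisation_hand_value(self):
        # raw[1,2]=10, raw[2,1]=30, volumes 2 everywhere:
        # (10/4 + 30/4)/2 = 5
        raw = np.zeros((4, 4))
        raw[1, 2], raw[2, 1] = 10.0, 30.0
        c = build_connectome(raw, tiny_parcellation(volumes=[2.0] * 4))
        assert c.weights[1, 2] == pytest.approx(5.0)
        assert c.weights[2, 1] == pytest.approx(5.0)

    def test_unit_volumes_symmetric_raw_is_identity_with_zero_diag(self):
        raw = random_symmetric(4, seed=1) + np.eye(4)
        c = build_connectome(raw, tiny_parcellation())
        expected = raw.copy()
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(c.weights, expected)

    def test_errors(self):
        p = tiny_parcellation()
        with pytest.raises(ValueError):
            build_connectome(np.zeros((3, 3)), p)
        with pytest.raises(ValueError):
            build_connectome(-np.ones((4, 4)), p)


class TestExtractHemisphere:
    def test_sides_partition_intrahemispheric_edges(self):
        w = random_symmetric(72, seed=7)
        c = Connectome(w, default_parcellation(), "s")
        left = extract_hemisphere(c, "left")
        right = extract_hemisphere(c, "right")
        inter = extract_hemisphere(c, "interhemispheric")
        assert left.n_nodes == right.n_nodes == 36
        assert inter.shape == (36, 36)
        # edge bookkeeping: intra-left + intra-right + 2*inter == total
        total = np.count_nonzero(w)
        parts = (
            np.count_nonzero(left.weights)
            + np.count_nonzero(right.weights)
            + 2 * np.count_nonzero(inter)
        )
        assert parts == total

    def test_block_diagonal_has_empty_interhemispheric_block(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 2.0
        c = Connectome(w, tiny_parcellation(), "s")
        assert np.all(extract_hemisphere(c, "interhemispheric") == 0)

    def test_unknown_side_rejected(self):
        c = Connectome(np.zeros((4, 4)), tiny_parcellation(), "s")
        with pytest.raises(ValueError):
            extract_hemisphere(c, "medial")


class TestMedianSummary:
    def test_single_subject_is_identity(self):
        w = random_symmetric(6, seed=2)
        p = tiny_parcellation(3)
        np.testing.assert_allclose(median_summary([Connectome(w, p, "a")]), w)

    def test_elementwise_median_small_case(self):
        p = tiny_parcellation()
        mats = []
        for v in (1.0, 2.0, 9.0):
            w = np.zeros((4, 4))
            w[0, 1] = w[1, 0] = v
            mats.append(Connectome(w, p, f"s{v}"))
        assert median_summary(mats)[0, 1] == 2.0

    def test_matches_sort_based_oracle_on_26_subjects(self):
        p = default_parcellation()
        cohort = [
            Connectome(random_symmetric(72, seed=100 + i), p, f"s{i}")
            for i in range(26)
        ]
        med = median_summary(cohort)
        stack = np.stack([c.weights for c in cohort])
        # brute-force per-edge sort oracle
        srt = np.sort(stack, axis=0)
        oracle = (srt[12] + srt[13]) / 2.0
        np.testing.assert_allclose(med, oracle)


class TestDensityThreshold:
    @pytest.mark.parametrize(
        "n,kappa,expected",
        [(72, 0.05, 128), (72, 0.95, 2428), (36, 0.05, 32), (36, 0.95, 599)],
    )
    def test_printed_edge_counts(self, n, kappa, expected):
        summary = random_symmetric(n, seed=3)
        assert density_threshold(summary, kappa).edge_count == expected

    def test_kappa_one_is_complete(self):
        m = density_threshold(random_symmetric(10, seed=4), 1.0)
        assert m.edge_count == 45
        assert np.all(m.mask == ~np.eye(10, dtype=bool))

    def test_round_half_up_convention(self):
        assert round_half_up(127.8) == 128
        assert round_half_up(2428.2) == 2428
        assert round_half_up(31.5) == 32
        assert round_half_up(598.5) == 599
        assert round_half_up(0.95 * 630) == 599  # binary-float half case

    def test_masks_nested_across_densities(self):
        summary = random_symmetric(36, seed=5, density=0.4)
        grid = np.round(np.arange(0.05, 0.951, 0.05), 2)
        prev = None
        for k in grid:
            m = density_threshold(summary, k).mask
            if prev is not None:
                assert np.all(prev <= m)  # monotone nesting
            prev = m

    def test_sparse_summary_still_reaches_count_with_zero_edges(self):
        summary = np.zeros((36, 36))
        summary[0, 1] = summary[1, 0] = 1.0
        m = density_threshold(summary, 0.95)
        assert m.edge_count == 599
        assert m.mask[0, 1]

    def test_kappa_out_of_range(self):
        s = random_symmetric(6, seed=6)
        for bad in (0.0, -0.1, 1.01):
            with pytest.raises(ValueError):
                density_threshold(s, bad)


class TestApplyMask:
    def test_full_mask_is_identity(self):
        p = tiny_parcellation(3)
        c = Connectome(random_symmetric(6, seed=7), p, "s")
        m = density_threshold(c.weights, 1.0)
        np.testing.assert_allclose(apply_mask(c, m).weights, c.weights)

    def test_never_increases_weights_and_respects_edge_budget(self):
        p = tiny_parcellation(18)
        summary = random_symmetric(36, seed=8)
        c = Connectome(random_symmetric(36, seed=9), p, "s")
        for k in (0.1, 0.5, 0.9):
            m = density_threshold(summary, k)
            masked = apply_mask(c, m)
            assert np.all(masked.weights <= c.weights + 1e-15)
            assert np.count_nonzero(np.triu(masked.weights, 1)) <= m.edge_count
        # total strength non-increasing as kappa decreases
        strengths = [
            apply_mask(c, density_threshold(summary, k)).weights.sum()
            for k in (0.9, 0.5, 0.1)
        ]
        assert strengths[0] >= strengths[1] >= strengths[2]

    def test_symmetry_and_zero_diagonal_preserved(self):
        p = tiny_parcellation(5)
        c = Connectome(random_symmetric(10, seed=10), p, "s")
        m = density_threshold(c.weights, 0.3)
        out = apply_mask(c, m).weights
        np.testing.assert_array_equal(out, out.T)
        assert np.all(np.diag(out) == 0)


class TestIO:
    def test_matrix_roundtrip(self, tmp_path):
        w = random_symmetric(8, seed=11)
        path = tmp_path / "m.csv"
        write_matrix(w, path)
        np.testing.assert_allclose(read_matrix(path, 8), w, rtol=1e-9)

    def test_stacked_roundtrip(self, tmp_path):
        mats = {f"s{i}": random_symmetric(6, seed=20 + i) for i in range(3)}
        path = tmp_path / "stack.csv"
        write_matrix_stack(mats, path)
        back = read_matrix_stack(path)
        for sid, w in mats.items():
            np.testing.assert_allclose(back[sid], w, rtol=1e-9)

    def test_region_and_cohort_tables(self, tmp_path):
        p = default_parcellation(volumes=np.full(72, 1500.0))
        rpath = tmp_path / "regions.csv"
        write_region_table(p, rpath)
        assert read_region_table(rpath).labels == p.labels

        cpath = tmp_path / "cohort.csv"
        pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "group": ["control", "patient"],
                "age": [30, 40],
                "score": [np.nan, 55.0],
            }
        ).to_csv(cpath, index=False)
        table = read_cohort_table(cpath)
        assert list(table["group"]) == ["control", "patient"]

    def test_connectome_invariant_violations_rejected(self):
        p = tiny_parcellation()
        asym = np.zeros((4, 4))
        asym[0, 1] = 1.0
        with pytest.raises(ValueError):
            Connectome(asym, p, "s")
        neg = np.zeros((4, 4))
        neg[0, 1] = neg[1, 0] = -1.0
        with pytest.raises(ValueError):
            Connectome(neg, p, "s")
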