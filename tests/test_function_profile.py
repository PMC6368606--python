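"""KO normalization, enrichment, category subsetting, Bray-Curtis, and PCoA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import pdist, squareform

from springdiv.exceptions import InvalidInputError, InvalidParameterError
from springdiv.function_profile import (
    KOCategoryMap,
    bray_curtis,
    ko_enrichment,
    normalize_ko,
    pcoa,
    subset_category,
)


@pytest.fixture
def category_map():
    return KOCategoryMap(
        {
            "K00001": ("Metabolism", "Energy Metabolism"),
            "K00002": ("Metabolism", "Energy Metabolism"),
            "K00003": ("Metabolism", "Carbohydrate Metabolism"),
            "K00004": ("Genetic Information Processing", "Translation"),
        }
    )


class TestNormalize:
    def test_hand_arithmetic(self):
        table = pd.DataFrame([[2, 3, 5]], index=["MG1"], columns=list("abc"))
        norm = normalize_ko(table)
        assert norm.iloc[0].tolist() == pytest.approx([0.2, 0.3, 0.5])

    def test_rows_sum_to_one(self, rng):
        table = pd.DataFrame(rng.integers(0, 20, size=(6, 10)) + 1)
        assert normalize_ko(table).sum(axis=1).to_numpy() == pytest.approx(
            np.ones(6), abs=1e-12
        )

    def test_zero_total_metagenome_named_in_error(self):
        table = pd.DataFrame([[1, 2], [0, 0]], index=["good", "empty"])
        with pytest.raises(InvalidInputError, match="empty"):
            normalize_ko(table)


class TestEnrichment:
    def test_hand_arithmetic_three_metagenomes(self):
        norm = pd.DataFrame(
            {"K1": [0.2, 0.1, 0.0]}, index=["MG1", "MG2", "MG3"]
        )
        e = ko_enrichment(norm)
        assert e.loc["K1"].tolist() == pytest.approx([1.0, 0.0, -1.0])

    def test_exclusive_ko_reaches_ceiling(self):
        counts = pd.DataFrame(
            np.ones((15, 3)), index=[f"MG{i}" for i in range(15)], columns=list("abc")
        )
        counts.loc[:, "c"] = 0.0
        counts.loc["MG7", "c"] = 4.0
        e = ko_enrichment(normalize_ko(counts))
        assert e.loc["c", "MG7"] == pytest.approx(14.0)

    def test_absent_ko_is_minus_one(self):
        counts = pd.DataFrame(
            [[2, 1], [0, 1], [2, 1]], index=["MG1", "MG2", "MG3"], columns=["a", "b"]
        )
        e = ko_enrichment(normalize_ko(counts))
        assert e.loc["a", "MG2"] == pytest.approx(-1.0)

    def test_centering_and_bounds(self, rng):
        counts = pd.DataFrame(rng.integers(0, 30, size=(8, 20)))
        counts.iloc[:, 0] = 0  # an all-zero KO must be dropped, not divide by zero
        counts.iloc[:, 1:] += 1
        e = ko_enrichment(normalize_ko(counts))
        assert 0 not in e.index
        assert e.mean(axis=1).to_numpy() == pytest.approx(np.zeros(len(e)), abs=1e-12)
        assert (e.to_numpy() >= -1 - 1e-12).all()
        assert (e.to_numpy() <= 7 + 1e-12).all()  # S - 1 with S = 8


class TestSubsetCategory:
    def test_subcategory_filter(self, category_map):
        table = pd.DataFrame(
            [[1, 2, 3, 4]], index=["MG1"], columns=[f"K0000{i}" for i in range(1, 5)]
        )
        sub = subset_category(table, category_map, "Energy Metabolism")
        assert list(sub.columns) == ["K00001", "K00002"]
        top = subset_category(table, category_map, "Metabolism")
        assert list(top.columns) == ["K00001", "K00002", "K00003"]

    def test_unknown_label_rejected(self, category_map):
        table = pd.DataFrame([[1]], columns=["K00001"])
        with pytest.raises(InvalidParameterError):
            subset_category(table, category_map, "Photosynthesis")

    def test_empty_result_is_not_an_error(self, category_map):
        table = pd.DataFrame([[1]], index=["MG1"], columns=["K99999"])
        sub = subset_category(table, category_map, "Translation")
        assert sub.shape == (1, 0)

    def test_subsetting_does_not_commute_with_normalization(self, category_map):
        table = pd.DataFrame(
            [[4, 4, 2], [1, 1, 8]],
            index=["MG1", "MG2"],
            columns=["K00001", "K00002", "K00004"],
        )
        sub_then_norm = normalize_ko(subset_category(table, category_map, "Metabolism"))
        norm_then_sub = subset_category(normalize_ko(table), category_map, "Metabolism")
        assert not np.allclose(sub_then_norm.to_numpy(), norm_then_sub.to_numpy())


class TestBrayCurtis:
    def test_identity_and_disjoint_extremes(self):
        table = pd.DataFrame(
            [[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 5, 1]],
            index=["A", "B", "C"],
        )
        dm = bray_curtis(table)
        assert dm["A", "B"] == pytest.approx(0.0)
        assert dm["A", "C"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        table = pd.DataFrame([[1, 0, 3], [2, 2, 1]], index=["X", "Y"])
        dm = bray_curtis(table, use_frequencies=False)
        assert dm["X", "Y"] == pytest.approx(5 / 9)

    def test_zero_row_rejected(self):
        with pytest.raises(InvalidInputError):
            bray_curtis(pd.DataFrame([[1, 1], [0, 0]]))

    @given(
        arrays(np.float64, (5, 7), elements=dict(min_value=0, max_value=50))
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounds_and_symmetry(self, data):
        data[:, 0] += 1  # keep every row positive
        dm = bray_curtis(pd.DataFrame(data))
        mat = dm.data
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0)
        assert (mat >= -1e-12).all() and (mat <= 1 + 1e-12).all()


class TestPCoA:
    def test_zero_distances_give_zero_coordinates(self):
        ordination = pcoa(np.zeros((4, 4)))
        assert ordination.coordinates.shape[1] == 0 or np.allclose(
            ordination.coordinates.to_numpy(), 0
        )

    def test_planar_points_are_reconstructed(self):
        points = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0], [2.0, 2.0]])
        d = squareform(pdist(points))
        ordination = pcoa(d)
        recon = squareform(pdist(ordination.coordinates.to_numpy()))
        assert np.allclose(recon, d, atol=1e-8)

    def test_collinear_points_embed_on_one_axis(self):
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        ordination = pcoa(d)
        assert len(ordination.eigenvalues) == 1
        axis = ordination.coordinates.iloc[:, 0].to_numpy()
        gaps = np.abs(axis[:, None] - axis[None, :])
        assert np.allclose(gaps, d, atol=1e-8)

    def test_matches_reference_implementation(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix

        table = pd.DataFrame(rng.integers(1, 40, size=(6, 12)))
        dm = bray_curtis(table)
        ours = pcoa(dm)
        ref = skbio_pcoa(DistanceMatrix(dm.data), number_of_dimensions=0)
        k = ours.coordinates.shape[1]
        ref_coords = ref.samples.to_numpy()[:, :k]
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()), np.abs(ref_coords), atol=1e-8
        )
        assert np.allclose(ours.eigenvalues, ref.eigvals.to_numpy()[:k], atol=1e-10)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InvalidInputError):
            pcoa(bad)

    def test_axis_sign_convention(self, rng):
        table = pd.DataFrame(rng.integers(1, 40, size=(5, 8)))
        ordination = pcoa(bray_curtis(table))
        coords = ordination.coordinates.to_numpy()
        for j in range(coords.shape[1]):
            assert coords[np.argmax(np.abs(coords[:, j])), j] >= 0
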