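from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sedlipidomics.composition import (
    class_proportions,
    exclusive_counts,
    hellinger_distance,
    hellinger_transform,
    hierarchical_clustering,
    intersection_counts,
    pca_scores,
    presence_matrix,
    sample_columns,
    sum_counts,
)


def _cal(rows, samples):
    df = pd.DataFrame(rows)
    df["subclass"] = ""
    df["rf_source"] = "own-standard"
    return df.set_index("shorthand")


def test_single_class_proportion_is_one():
    cal = _cal(
        [{"shorthand": "ST 27:4", "lipid_class": "sterol", "A": 5.0, "B": 2.0}], ["A", "B"]
    )
    props = class_proportions(cal)
    assert props.loc["sterol"].tolist() == [1.0, 1.0]


def test_two_class_split():
    cal = _cal(
        [
            {"shorthand": "ST 27:4", "lipid_class": "sterol", "A": 75.0},
            {"shorthand": "TG 52:3", "lipid_class": "TAG", "A": 25.0},
        ],
        ["A"],
    )
    props = class_proportions(cal)
    assert props.loc["sterol", "A"] == pytest.approx(0.75)
    assert props.loc["TAG", "A"] == pytest.approx(0.25)


def test_minor_classes_lump_into_other():
    cal = _cal(
        [
            {"shorthand": "ST 27:4", "lipid_class": "sterol", "A": 990.0, "B": 995.0},
            {"shorthand": "TG 52:3", "lipid_class": "TAG", "A": 10.0, "B": 5.0},
        ],
        ["A", "B"],
    )
    props = class_proportions(cal, min_major_fraction=0.01)
    assert "TAG" not in props.index
    assert props.loc["other", "A"] == pytest.approx(0.01)


def test_columns_sum_to_one(default_calibrated):
    props = class_proportions(default_calibrated)
    np.testing.assert_allclose(props.sum(axis=0).to_numpy(), 1.0, atol=1e-9)


def test_all_zero_sample_names_it():
    cal = _cal(
        [{"shorthand": "ST 27:4", "lipid_class": "sterol", "A": 1.0, "B": 0.0}], ["A", "B"]
    )
    with pytest.raises(ValueError, match="B"):
        class_proportions(cal)


# ---------------------------------------------------------------------------
# Hellinger / PCA


def test_hellinger_equal_row():
    out = hellinger_transform(np.ones((1, 4)))
    np.testing.assert_allclose(out, np.sqrt(0.25))


def test_hellinger_unit_row_fixed_point():
    np.testing.assert_allclose(hellinger_transform(np.array([[1.0, 0.0, 0.0]])), [[1, 0, 0]])


def test_hellinger_rejects_negative():
    with pytest.raises(ValueError):
        hellinger_transform(np.array([[1.0, -0.5]]))


def test_euclidean_on_transform_equals_direct_hellinger():
    rng = np.random.default_rng(8)
    X = rng.uniform(0, 10, size=(6, 12))
    H = hellinger_transform(X)
    for i, j in combinations(range(6), 2):
        direct = hellinger_distance(X[i], X[j])
        assert np.linalg.norm(H[i] - H[j]) == pytest.approx(direct, abs=1e-12)


def test_pca_identical_rows_zero_scores():
    X = np.tile([1.0, 2.0, 3.0], (3, 1))
    scores, _, _ = pca_scores(X, 1)
    np.testing.assert_allclose(scores, 0.0, atol=1e-12)


def test_pca_rank1_explains_everything():
    t = np.arange(5, dtype=float)
    X = np.outer(t, [1.0, -2.0, 0.5])
    with pytest.warns(UserWarning):
        scores, loadings, evr = pca_scores(X, 3)
    assert evr[0] == pytest.approx(1.0)


def test_pca_reconstruction_identity():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(8, 5))
    scores, loadings, _ = pca_scores(X, 5)
    recon = scores @ loadings + X.mean(axis=0)
    np.testing.assert_allclose(recon, X, atol=1e-8)


def test_pca_sign_convention():
    rng = np.random.default_rng(22)
    X = rng.normal(size=(10, 4))
    _, loadings, _ = pca_scores(X, 3)
    for row in loadings:
        assert row[np.argmax(np.abs(row))] > 0


# ---------------------------------------------------------------------------
# presence / intersections


def test_presence_boundary_inclusive():
    cal = _cal(
        [
            {"shorthand": "a", "lipid_class": "sterol", "A": 0.02},
            {"shorthand": "b", "lipid_class": "sterol", "A": 99.98},
        ],
        ["A"],
    )
    pres = presence_matrix(cal, threshold_fraction=0.0002)
    assert bool(pres.loc["a", "A"]) is True  # exactly 0.02% counts as present
    cal.loc["a", "A"] = 0.0
    pres = presence_matrix(cal, threshold_fraction=0.0002)
    assert bool(pres.loc["a", "A"]) is False


def test_presence_monotone_in_threshold(default_calibrated):
    lo = presence_matrix(default_calibrated, 0.0001)
    hi = presence_matrix(default_calibrated, 0.001)
    assert not (hi & ~lo).any().any()


def test_presence_matrix_matches_hand_enumeration():
    cal = _cal(
        [
            {"shorthand": "w", "lipid_class": "sterol", "A": 50.0, "B": 0.0},
            {"shorthand": "x", "lipid_class": "sterol", "A": 49.0, "B": 99.0},
            {"shorthand": "y", "lipid_class": "TAG", "A": 1.0, "B": 0.5},
            {"shorthand": "z", "lipid_class": "TAG", "A": 0.0, "B": 0.5},
        ],
        ["A", "B"],
    )
    pres = presence_matrix(cal, threshold_fraction=0.005)
    expected = pd.DataFrame(
        {"A": [True, True, True, False], "B": [False, True, True, True]},
        index=["w", "x", "y", "z"],
    )
    pd.testing.assert_frame_equal(pres, expected, check_names=False)


def test_intersection_counts_match_enumeration():
    rng = np.random.default_rng(30)
    pres = pd.DataFrame(
        rng.integers(0, 2, size=(10, 4)).astype(bool),
        columns=["g1", "g2", "g3", "g4"],
        index=[f"sp{i}" for i in range(10)],
    )
    counts = intersection_counts(pres)
    # brute-force per-species pattern enumeration
    expected: dict[frozenset, int] = {}
    for _, row in pres.iterrows():
        key = frozenset(c for c in pres.columns if row[c])
        if key:
            expected[key] = expected.get(key, 0) + 1
    for k, v in expected.items():
        assert counts[k] == v
    assert sum(counts.values()) == int(pres.any(axis=1).sum())


def test_species_in_all_groups_counts_once_in_full_cell():
    pres = pd.DataFrame({"a": [True], "b": [True]}, index=["sp"])
    counts = intersection_counts(pres)
    assert counts[frozenset({"a", "b"})] == 1
    assert exclusive_counts(counts, "a") == 0


def test_sum_counts_plain_summation():
    assert sum_counts({"a": 2, "b": 3}) == 5
    assert sum_counts({}) == 0


# ---------------------------------------------------------------------------
# clustering


def test_first_split_separates_water_from_sediment(default_bundle, default_calibrated):
    meta = default_bundle.metadata.set_index("sample_id")
    samples = sample_columns(default_calibrated)
    abundance = default_calibrated[samples].T
    _, labels = hierarchical_clustering(abundance)
    water = {l for s, l in zip(abundance.index, labels) if meta.loc[s, "matrix"] == "water"}
    sediment = {l for s, l in zip(abundance.index, labels) if meta.loc[s, "matrix"] == "sediment"}
    assert water.isdisjoint(sediment)
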