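"""QC detection/CV filtering rules and reliability statistics."""

import numpy as np
import pandas as pd
import pytest

from lipimark.qc import (
    coefficient_of_variation,
    detection_rate,
    filter_features,
    qc_reliability,
)
from lipimark.simulate import SyntheticConfig, generate_lipidome
from lipimark.table import FeatureTable


@pytest.mark.parametrize(
    "values,floor,expected",
    [
        ([1500, 1200, np.nan, 900, 2000], 1000, 0.6),
        ([1500, 1200, 1100, 1900, 2000], 1000, 1.0),
        ([np.nan] * 5, 1000, 0.0),
    ],
)
def test_detection_rate(values, floor, expected):
    assert detection_rate(values, floor) == pytest.approx(expected)


def test_detection_rate_needs_values():
    with pytest.raises(ValueError):
        detection_rate([])


def test_coefficient_of_variation():
    assert coefficient_of_variation([10, 10, 10, 10, 10]) == 0.0
    # two-point hand oracle: sd = |8-12|/sqrt(2) = 2.828..., mean = 10
    assert coefficient_of_variation([8, 12]) == pytest.approx(0.28284271, abs=1e-6)
    assert coefficient_of_variation([1, 100]) > 0.3
    with pytest.raises(ValueError):
        coefficient_of_variation([5])
    with pytest.raises(ValueError):
        coefficient_of_variation([0, 0])


def _table(qc_rows: dict) -> FeatureTable:
    """Feature table with 2 biological + 5 QC columns from given QC cells."""
    n = len(qc_rows)
    cols = {"A_1": np.full(n, 5e4), "A_2": np.full(n, 5e4),
            "B_1": np.full(n, 5e4), "B_2": np.full(n, 5e4)}
    qc = np.array(list(qc_rows.values()), dtype=float)
    for j in range(qc.shape[1]):
        cols[f"QC_{j+1}"] = qc[:, j]
    values = pd.DataFrame(cols, index=list(qc_rows))
    groups = pd.Series({"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B",
                        **{f"QC_{j+1}": "QC" for j in range(qc.shape[1])}})
    return FeatureTable(values, groups)


def test_filter_boundary_semantics():
    """Rate exactly 0.5 and CV exactly 0.30 are kept; 'less than' / 'greater
    than' are strict."""
    base = 5e4
    rows = {
        "ok": [base] * 5,
        "rate_04": [base, base, np.nan, np.nan, np.nan],       # 2/5 detected
        "rate_05_kept": [base, base, np.nan, np.nan, base],    # 3/5 = 0.6
        "below_floor": [base, base, 500, 500, 500],            # 2/5 >= floor
        # mean 10000, sample sd exactly 3000 -> CV exactly 0.3
        "cv_030_kept": [13000, 7000, 13000, 7000, 10000],
        "cv_high": [base, 4 * base, base, 4 * base, base],
    }
    table = _table(rows)
    filtered, report = filter_features(table, rate_min=0.5, cv_max=0.3,
                                       floor=1000)
    assert report.detection_rate["rate_04"] == pytest.approx(0.4)
    assert report.reasons["rate_04"] == ["detection"]
    assert report.detection_rate["below_floor"] == pytest.approx(0.4)
    assert "below_floor" in report.reasons
    assert report.cv["cv_030_kept"] == pytest.approx(0.3, abs=1e-12)
    assert report.kept["cv_030_kept"]
    assert "cv" in report.reasons["cv_high"]
    assert set(filtered.feature_ids) == {"ok", "rate_05_kept", "cv_030_kept"}
    # sample set preserved
    assert filtered.sample_ids == table.sample_ids


def test_filter_requires_qc_columns(tiny_table):
    no_qc = FeatureTable(tiny_table.values[tiny_table.biological_samples],
                         tiny_table.groups[tiny_table.biological_samples])
    with pytest.raises(ValueError):
        filter_features(no_qc)


def test_filter_removes_exactly_planted_bad_features():
    for seed in (0, 1, 2):
        cfg = SyntheticConfig(seed=seed, n_features=200, dropout_rate=0.0,
                              n_bad_detection=4, n_bad_cv=3)
        table, truth = generate_lipidome(cfg)
        filtered, report = filter_features(table)
        removed = set(table.feature_ids) - set(filtered.feature_ids)
        assert removed == set(truth.bad_detection_ids) | set(truth.bad_cv_ids)


def test_filter_idempotent_and_order_independent():
    cfg = SyntheticConfig(seed=9, n_features=150, n_bad_detection=3,
                          n_bad_cv=3)
    table, _ = generate_lipidome(cfg)
    once, _ = filter_features(table)
    twice, _ = filter_features(once)
    assert once.feature_ids == twice.feature_ids

    rng = np.random.default_rng(0)
    perm = rng.permutation(table.feature_ids)
    shuffled = table.subset_features(list(perm))
    f2, _ = filter_features(shuffled)
    assert set(f2.feature_ids) == set(once.feature_ids)


def test_removals_monotone_in_thresholds():
    cfg = SyntheticConfig(seed=4, n_features=150, technical_cv=0.25,
                          dropout_rate=0.2)
    table, _ = generate_lipidome(cfg)
    removed = {}
    for cv_max in (0.1, 0.2, 0.3, 0.5):
        _, rep = filter_features(table, cv_max=cv_max)
        removed[cv_max] = rep.n_removed
    assert sorted(removed, reverse=True) == sorted(removed, reverse=True)
    vals = [removed[c] for c in (0.1, 0.2, 0.3, 0.5)]
    assert vals == sorted(vals, reverse=True)

    vals = []
    for rate_min in (0.2, 0.5, 0.8, 1.0):
        _, rep = filter_features(table, rate_min=rate_min)
        vals.append(rep.n_removed)
    assert vals == sorted(vals)


def test_duplicate_qc_columns_give_perfect_correlation(tiny_table):
    values = tiny_table.values.copy()
    values["QC_2"] = values["QC_1"]
    table = FeatureTable(values, tiny_table.groups)
    r, scores, dispersion, flagged = qc_reliability(table)
    assert r.loc["QC_1", "QC_2"] == pytest.approx(1.0)
    assert not flagged
    assert list(scores.columns) == ["PC1", "PC2"]


def test_qc_pairs_cluster_centrally(small_study):
    _, table, _ = small_study
    r, _, dispersion, _ = qc_reliability(table)
    iu = np.triu_indices(len(table.qc_samples), 1)
    assert np.nanmin(r.to_numpy()[iu]) > 0.99
    assert dispersion < 1


def test_qc_pair_with_too_few_shared_features_is_flagged():
    rows = {"f1": [1e4, np.nan, 1e4, 1e4, 1e4],
            "f2": [1e4, np.nan, 1e4, 1e4, 1e4]}
    table = _table(rows)
    r, _, _, flagged = qc_reliability(table)
    assert ("QC_1", "QC_2") in flagged or ("QC_2", "QC_1") in flagged
    assert np.isnan(r.loc["QC_1", "QC_2"])
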