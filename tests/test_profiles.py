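"""Calibration, class accounting and fatty-acid profile arithmetic."""

import io

import numpy as np
import pandas as pd
import pytest

from lipimark.profiles import (
    CompositionSummary,
    class_counts,
    composition_proportions,
    fatty_acid_totals,
    fit_calibration,
    parse_mean_sd_cell,
    quantify,
    read_profile_table,
)
from lipimark.simulate import SyntheticConfig, fatty_acid_reference, generate_lipidome

CONCS = [0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50]  # µg/mL grid


def test_calibration_exact_line():
    curve = fit_calibration(CONCS, [2 * c for c in CONCS])
    assert curve.slope == pytest.approx(2.0)
    assert curve.intercept == pytest.approx(0.0, abs=1e-9)
    assert curve.r_squared == pytest.approx(1.0)


def test_calibration_small_noise_limit():
    rng = np.random.default_rng(0)
    areas = 2 * np.array(CONCS) + rng.normal(0, 1e-8, len(CONCS))
    assert fit_calibration(CONCS, areas).slope == pytest.approx(2.0, abs=1e-6)


def test_calibration_slope_ci_coverage():
    """OLS on the 12-point standard grid: the 95% CI covers the true slope
    at roughly nominal rate over 100 simulations."""
    from scipy import stats

    rng = np.random.default_rng(42)
    x = np.array(CONCS)
    covered = 0
    for _ in range(100):
        y = 3.5 * x + rng.normal(0, 0.5, x.size)
        res = stats.linregress(x, y)
        half = stats.t.ppf(0.975, x.size - 2) * res.stderr
        covered += abs(res.slope - 3.5) <= half
        curve = fit_calibration(x, y)
        assert curve.slope == pytest.approx(res.slope)
    assert 88 <= covered <= 100


def test_calibration_errors():
    with pytest.raises(ValueError):
        fit_calibration([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_calibration([1, 2], [1, 2])
    with pytest.raises(ValueError):
        fit_calibration([0, 1, 2], [0, 1, 2])


def test_quantify_inverse_prediction():
    curve = fit_calibration([1, 2, 3], [2, 4, 6])
    assert quantify(10, curve)[0] == pytest.approx(5.0)
    assert quantify(curve.intercept, curve)[0] == pytest.approx(0.0)
    conc, below = quantify(-1.0, curve)
    assert below
    for c in (0.01, 3.7, 42.0):
        assert quantify(curve.predict(c), curve)[0] == pytest.approx(c)


def test_class_counts_from_names():
    summary = class_counts(["PC (16:0_16:1)"])
    assert summary.class_counts == {"GP": 1}
    assert summary.total == 1
    summary = class_counts([])
    assert summary.total == 0
    summary = class_counts(["PC (16:0_16:1)", "XX (1:0)", "Carnitine C3:0"])
    assert summary.unparseable == ["XX (1:0)"]
    assert summary.class_counts == {"GP": 1, "FA": 1}


def test_published_class_tallies_share():
    """The six published class counts total 1080 identified lipids with
    glycerophospholipids + glycerolipids at 81.57% of them."""
    summary = CompositionSummary(
        class_counts={"FA": 84, "GL": 225, "GP": 656, "PR": 2,
                      "SP": 106, "ST": 7},
        subclass_counts={})
    assert summary.total == 1080
    assert round(100 * summary.class_share(("GP", "GL")), 2) == 81.57


def test_composition_proportions_basic(tiny_table):
    ann = {f: "PC" for f in tiny_table.feature_ids}
    props = composition_proportions(tiny_table, ann, "A")
    assert props == {"PC": pytest.approx(1.0)}

    ann = {"L1": "TG", "L2": "TG", "L3": "PC", "L4": "PC"}
    values = tiny_table.values.copy()
    values.loc[:, :] = 1.0
    from lipimark.table import FeatureTable

    eq = FeatureTable(values, tiny_table.groups)
    props = composition_proportions(eq, ann, "A")
    assert props["TG"] == pytest.approx(0.5)
    assert props["PC"] == pytest.approx(0.5)

    with pytest.raises(ValueError, match="unannotated"):
        composition_proportions(tiny_table, {"L1": "PC"}, "A")


def test_composition_proportions_sum_to_one(small_study):
    _, table, _ = small_study
    rng = np.random.default_rng(1)
    subs = ["TG", "PC", "CAR", "SM"]
    ann = {f: subs[i] for f, i in
           zip(table.feature_ids, rng.integers(0, 4, len(table.feature_ids)))}
    for g in table.biological_groups:
        props = composition_proportions(table, ann, g)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)


def test_fatty_acid_totals_reproduce_published_profile():
    """Component sums per group against the published totals: five totals
    exact at 3 dp, two known to disagree by one unit in the last digit
    because the printed components are themselves rounded."""
    ref = fatty_acid_reference()
    means = ref.pivot(index="acid", columns="group", values="mean")
    prof = fatty_acid_totals(means)
    t = prof.totals
    assert round(t.loc["SFA", "NX"], 3) == 1.523
    assert round(t.loc["MUFA", "NX"], 3) == 1.265
    assert round(t.loc["MUFA", "GS"], 3) == 1.407
    assert round(t.loc["PUFA", "GS"], 3) == 0.358
    assert round(t.loc["SFA", "IM"], 3) == 1.869
    assert round(t.loc["MUFA", "IM"], 3) == 1.521
    assert round(t.loc["PUFA", "IM"], 3) == 0.462
    # documented last-digit printing discrepancies in the source profile
    assert abs(t.loc["PUFA", "NX"] - 0.460) <= 0.001 + 1e-9
    assert abs(t.loc["SFA", "GS"] - 1.864) <= 0.001 + 1e-9

    ratios = {g: round(v, 3) for g, v in prof.ufa_fa_ratio.items()}
    assert ratios == {"NX": 0.531, "GS": 0.486, "IM": 0.515}


def test_fatty_acid_totals_partition_and_errors():
    ref = fatty_acid_reference()
    means = ref.pivot(index="acid", columns="group", values="mean")
    prof = fatty_acid_totals(means)
    sats = pd.Series(prof.acids)
    assert (sats == "SFA").sum() == 8
    assert (sats == "MUFA").sum() == 4
    assert (sats == "PUFA").sum() == 5

    zero = pd.DataFrame({"G": [0.0, 0.0]}, index=["C16:0", "C18:1n9c"])
    prof = fatty_acid_totals(zero)
    assert prof.undefined == ["G"]
    assert "G" not in prof.ufa_fa_ratio

    with pytest.raises(Exception):
        fatty_acid_totals(pd.DataFrame({"G": [1.0]}, index=["banana"]))


def test_totals_permutation_invariant_and_additive():
    ref = fatty_acid_reference()
    means = ref.pivot(index="acid", columns="group", values="mean")
    shuffled = means.sample(frac=1, random_state=0)
    pd.testing.assert_frame_equal(
        fatty_acid_totals(means).totals.sort_index(),
        fatty_acid_totals(shuffled).totals.sort_index())
    half1, half2 = means.iloc[:8], means.iloc[8:]
    total = (fatty_acid_totals(half1).totals + fatty_acid_totals(half2).totals)
    pd.testing.assert_frame_equal(total, fatty_acid_totals(means).totals)


def test_mean_sd_cell_dialect():
    assert parse_mean_sd_cell("0.711 ± 0.009 ^c^") == (0.711, 0.009, "c")
    assert parse_mean_sd_cell("1.523 ± 0.042") == (1.523, 0.042, "")
    csv = "acid,NX,GS\nC16:0,0.711 ± 0.009 ^c^,0.959 ± 0.010 ^a^\n" \
          "C18:1n9c,1.181 ± 0.011 ^c^,1.279 ± 0.003 ^b^\n"
    means, sds = read_profile_table(io.StringIO(csv))
    assert means.loc["C16:0", "GS"] == 0.959
    assert sds.loc["C18:1n9c", "NX"] == 0.011
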