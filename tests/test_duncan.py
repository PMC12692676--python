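"""ANOVA + Duncan multiple range test and compact letter display."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipimark.duncan import (
    _lsr_quantile,
    duncan_letters,
    one_way_anova,
    summarize_groups,
)


def _random_instance(rng):
    k = int(rng.integers(3, 7))
    n = int(rng.integers(2, 6))
    means = {f"g{j}": float(rng.normal(0, rng.uniform(0.5, 3)))
             for j in range(k)}
    ns = {f"g{j}": n for j in range(k)}
    mse = float(rng.uniform(0.1, 2.0))
    return means, ns, mse, k * (n - 1)


def test_anova_matches_scipy():
    rng = np.random.default_rng(0)
    y = rng.standard_normal(18)
    g = np.repeat(["a", "b", "c"], 6)
    res = one_way_anova(y, g)
    F, p = stats.f_oneway(y[:6], y[6:12], y[12:])
    assert res.F == pytest.approx(F)
    assert res.p == pytest.approx(p)
    assert res.df_error == 15


def test_anova_two_groups_is_t_squared():
    rng = np.random.default_rng(1)
    a, b = rng.standard_normal(6) + 1, rng.standard_normal(6)
    res = one_way_anova(np.concatenate([a, b]), np.repeat(["a", "b"], 6))
    t, _ = stats.ttest_ind(a, b)
    assert res.F == pytest.approx(t * t)


def test_anova_degenerate_flagged_and_small_groups_rejected():
    res = one_way_anova([1, 1, 1, 1], ["a", "a", "b", "b"])
    assert res.degenerate and np.isnan(res.F)
    with pytest.raises(ValueError):
        one_way_anova([1, 2, 3], ["a", "a", "b"])


def test_equal_means_share_a_letter():
    res = duncan_letters({"a": 1.0, "b": 1.0001, "c": 0.9999},
                         {"a": 6, "b": 6, "c": 6}, mse=1.0, df_error=15)
    assert res.letters == {"a": "a", "b": "a", "c": "a"}
    assert not any(res.pairwise_significant.values())


def test_large_separation_gives_distinct_letters():
    res = duncan_letters({"a": 0.0, "b": 10.0, "c": 20.0},
                         {"a": 6, "b": 6, "c": 6}, mse=1.0, df_error=15)
    assert sorted(res.letters.values()) == ["a", "b", "c"]
    assert res.letters["c"] == "a"  # largest mean carries 'a'
    assert all(res.pairwise_significant.values())


def test_nonpositive_mse_rejected():
    with pytest.raises(ValueError):
        duncan_letters({"a": 1.0, "b": 2.0}, {"a": 3, "b": 3},
                       mse=0.0, df_error=4)


def test_letters_match_pairwise_decisions():
    """Shared letter iff not significantly different, over random
    instances with up to 6 groups."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        means, ns, mse, df = _random_instance(rng)
        res = duncan_letters(means, ns, mse, df)
        for (a, b), sig in res.pairwise_significant.items():
            assert sig == (not res.share_letter(a, b)), (means, res.letters)


def test_significance_monotone_in_gaps():
    """Scaling every gap between sorted means up never turns a significant
    pair non-significant (mse fixed)."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        means, ns, mse, df = _random_instance(rng)
        order = sorted(means, key=means.get)
        base = means[order[0]]
        wide = {}
        acc = base
        prev = base
        for g in order:
            acc += (means[g] - prev) * 2.5
            prev = means[g]
            wide[g] = acc
        r1 = duncan_letters(means, ns, mse, df)
        r2 = duncan_letters(wide, ns, mse, df)
        for pair, sig in r1.pairwise_significant.items():
            if sig:
                assert r2.pairwise_significant[pair], (means, wide)


def test_two_groups_reduce_to_lsd():
    """With k=2 the range test is the t-based LSD decision at level α."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        m1, m2 = rng.normal(0, 1, 2)
        n, mse, df = 6, float(rng.uniform(0.05, 1.0)), 10
        res = duncan_letters({"a": m1, "b": m2}, {"a": n, "b": n}, mse, df)
        lsd = stats.t.ppf(0.975, df) * np.sqrt(2 * mse / n)
        assert res.pairwise_significant[("a", "b")] == (abs(m1 - m2) > lsd)


def test_lsr_quantile_protection_level():
    # span 2 at alpha .05 equals the plain studentized-range 95% point
    q = _lsr_quantile(2, 10, 0.05)
    assert q == pytest.approx(stats.studentized_range.ppf(0.95, 2, 10))
    # wider spans use the relaxed protection (1-alpha)^(p-1)
    q3 = _lsr_quantile(3, 10, 0.05)
    assert q3 == pytest.approx(stats.studentized_range.ppf(0.95 ** 2, 3, 10))


def test_summarize_groups_table_dialect():
    rng = np.random.default_rng(5)
    idx = [f"s{i}" for i in range(18)]
    groups = pd.Series(np.repeat(["NX", "GS", "IM"], 6), index=idx)
    data = pd.DataFrame({
        "flat": np.ones(18),
        "spread": np.concatenate([rng.normal(0, 0.1, 6),
                                  rng.normal(10, 0.1, 6),
                                  rng.normal(20, 0.1, 6)]),
    }, index=idx)
    out = summarize_groups(data, groups)
    assert "±" in out.loc["spread", "NX"]
    assert "^" in out.loc["spread", "NX"]        # letters present
    assert "^" not in out.loc["flat", "NX"]      # all share one letter
    assert out.loc["spread", "p"] < 1e-6


def test_published_letter_patterns_recovered():
    """Samples drawn at the published palmitic-acid group means ± sd give
    the printed c/a/b letters; a no-difference row shares letters (majority
    of 100 simulations each)."""
    rng = np.random.default_rng(0)
    cab = shared = 0
    for _ in range(100):
        vals = {"NX": rng.normal(0.711, 0.009, 6),
                "GS": rng.normal(0.959, 0.010, 6),
                "IM": rng.normal(0.912, 0.009, 6)}
        y = np.concatenate(list(vals.values()))
        g = np.repeat(list(vals), 6)
        a = one_way_anova(y, g)
        res = duncan_letters({k: v.mean() for k, v in vals.items()},
                             {k: 6 for k in vals}, a.mse, a.df_error)
        cab += (res.letters["GS"] == "a" and res.letters["IM"] == "b"
                and res.letters["NX"] == "c")

        vals = {"NX": rng.normal(0.005, 0.002, 6),
                "GS": rng.normal(0.006, 0.002, 6),
                "IM": rng.normal(0.005, 0.002, 6)}
        y = np.concatenate(list(vals.values()))
        a = one_way_anova(y, g)
        res = duncan_letters({k: v.mean() for k, v in vals.items()},
                             {k: 6 for k in vals}, a.mse, a.df_error)
        shared += all(res.share_letter("NX", other) for other in ("GS", "IM"))
    assert cab > 50
    assert shared > 50
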