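"""One-way ANOVA with Duncan's multiple range test and compact letters.

Duncan's multiple range test compares all group means after an ANOVA using
studentized-range critical values that grow with the span of ordered means
being compared: a span of p means is tested at the protection level
``alpha_p = 1 − (1 − alpha)^(p−1)``, giving the least significant range
``LSR_p = q(1−alpha_p; p, df_error) · sqrt(MSE / n_h)`` with ``n_h`` the
harmonic mean group size. Two means differ only if their gap exceeds the
LSR for their span and no wider non-significant span encloses them.
Results are summarized as a compact letter display: groups share a letter
iff they are not significantly different.

Quantiles come from the studentized-range distribution numerically, so any
error degrees of freedom are supported without tabulated values.
No correction is applied across variables when many features are tested
one at a time — a deliberate mirror of common practice, noted as a
statistical limitation in the package docs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "DuncanResult",
    "one_way_anova",
    "duncan_letters",
    "summarize_groups",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    mse: float
    df_error: int
    df_between: int
    degenerate: bool = False


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Standard one-way decomposition, exposing MSE and error df.

    With zero within-group variance the F statistic is undefined; the result
    is returned flagged ``degenerate`` instead of raising.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must align")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("ANOVA needs at least two groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than two observations: {small}")

    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lab in labels:
        yi = y[g == lab]
        ss_between += yi.size * (yi.mean() - grand) ** 2
        ss_within += float(np.sum((yi - yi.mean()) ** 2))
    df_between = labels.size - 1
    df_error = y.size - labels.size
    mse = ss_within / df_error
    if mse == 0:
        return AnovaResult(np.nan, np.nan, 0.0, df_error, df_between,
                           degenerate=True)
    F = (ss_between / df_between) / mse
    p = float(stats.f.sf(F, df_between, df_error))
    return AnovaResult(float(F), p, float(mse), df_error, df_between)


@lru_cache(maxsize=4096)
def _lsr_quantile(p_span: int, df_error: int, alpha: float) -> float:
    """Studentized-range quantile at Duncan's protection level for a span."""
    protect = (1.0 - alpha) ** (p_span - 1)
    return float(stats.studentized_range.ppf(protect, p_span, df_error))


@dataclass
class DuncanResult:
    """Group means with compact significance letters.

    ``letters`` maps each group to its letter string (letters are assigned
    over means sorted descending, 'a' containing the largest mean);
    ``pairwise_significant`` records every unordered pair's decision and is
    consistent with the letters by construction.
    """

    means: dict[str, float]
    ns: dict[str, int]
    mse: float
    df_error: int
    alpha: float
    letters: dict[str, str]
    pairwise_significant: dict[tuple[str, str], bool]

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def duncan_letters(means: Mapping[str, float], ns: Mapping[str, int],
                   mse: float, df_error: int, alpha: float = 0.05
                   ) -> DuncanResult:
    """Run the multiple range test and build the letter display.

    Unequal group sizes are handled through the harmonic mean n (Duncan's
    convention). The step-down protection is explicit: a span found
    non-significant shields every enclosed pair from being declared
    significant.
    """
    if mse <= 0:
        raise ValueError("Duncan's test needs a positive error mean square")
    names = list(means)
    if any(not np.isfinite(means[g]) for g in names):
        raise ValueError("group means must be finite")
    k = len(names)
    order = sorted(names, key=lambda g: -means[g])
    m = np.array([means[g] for g in order])
    n_h = k / sum(1.0 / ns[g] for g in names)
    se = np.sqrt(mse / n_h)

    # accepted[i, j] == span i..j (inclusive, sorted order) non-significant
    accepted: list[tuple[int, int]] = []

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in accepted)

    for span in range(k, 1, -1):
        lsr = _lsr_quantile(span, df_error, alpha) * se
        for i in range(0, k - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            if m[i] - m[j] <= lsr:
                accepted.append((i, j))

    # maximal accepted intervals + singletons for uncovered groups -> letters
    maximal = [iv for iv in accepted
               if not any(iv != other and other[0] <= iv[0] and iv[1] <= other[1]
                          for other in accepted)]
    for i in range(k):
        if not any(a <= i <= b for a, b in maximal):
            maximal.append((i, i))
    maximal.sort()

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {g: "" for g in names}
    for idx, (a, b) in enumerate(maximal):
        letter = alphabet[idx % len(alphabet)]
        for pos in range(a, b + 1):
            letters[order[pos]] += letter

    pairwise: dict[tuple[str, str], bool] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pair = tuple(sorted((order[i], order[j])))
            pairwise[pair] = not covered(i, j)
    return DuncanResult(means=dict(means), ns=dict(ns), mse=mse,
                        df_error=df_error, alpha=alpha, letters=letters,
                        pairwise_significant=pairwise)


def summarize_groups(data: pd.DataFrame, groups: Mapping[str, str] | pd.Series,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable group mean ± sd with Duncan letters.

    ``data`` holds samples as rows and variables as columns; ``groups`` maps
    sample id → group. Returns one row per variable with per-group
    ``mean ± sd ^letters^`` strings (letters omitted when every group shares
    one letter, the convention used in published tables) plus the ANOVA F
    and p. Constant variables yield a single shared letter.
    """
    groups = pd.Series(groups)
    g = groups.loc[data.index]
    labels = list(dict.fromkeys(g))
    rows = {}
    for var in data.columns:
        y = data[var].astype(float)
        res = one_way_anova(y.to_numpy(), g.to_numpy())
        means = {lab: float(y[g == lab].mean()) for lab in labels}
        sds = {lab: float(y[g == lab].std(ddof=1)) for lab in labels}
        ns = {lab: int((g == lab).sum()) for lab in labels}
        if res.degenerate:
            letters = {lab: "a" for lab in labels}
        else:
            letters = duncan_letters(means, ns, res.mse, res.df_error,
                                     alpha).letters
        uniform = len(set(letters.values())) == 1
        row = {}
        for lab in labels:
            cell = f"{means[lab]:.3f} ± {sds[lab]:.3f}"
            if not uniform:
                cell += f" ^{letters[lab]}^"
            row[lab] = cell
        row["F"] = res.F
        row["p"] = res.p
        rows[var] = row
    return pd.DataFrame.from_dict(rows, orient="index")
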