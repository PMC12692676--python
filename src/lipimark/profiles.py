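"""Calibration curves, lipid class accounting and fatty-acid arithmetic.

Covers the descriptive layer of a lipidomics/fatty-acid study: external
standard curves (peak area vs concentration, inverse prediction), tallies of
identified species per lipid class and subclass, per-group composition
shares of summed intensity, and SFA/MUFA/PUFA totals with the UFA/FA
unsaturation ratio of a fatty-acid profile.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import LipidSpecies, classify_fatty_acid
from .table import FeatureTable

__all__ = [
    "CalibrationCurve",
    "CompositionSummary",
    "FattyAcidProfile",
    "fit_calibration",
    "quantify",
    "class_counts",
    "composition_proportions",
    "fatty_acid_totals",
    "parse_mean_sd_cell",
    "read_profile_table",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS external-standard line: area = slope · concentration + intercept."""

    concentrations: tuple[float, ...]
    peak_areas: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(concentrations: Iterable[float], areas: Iterable[float],
                    weighting: str | None = None) -> CalibrationCurve:
    """Fit the standard curve by least squares (optionally 1/x weighted).

    Concentration is the x axis, peak area the y axis, matching how external
    standard curves are constructed.
    """
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(areas), dtype=float)
    if x.size != y.size:
        raise ValueError("concentrations and areas must have equal length")
    if x.size < 3:
        raise ValueError("calibration needs at least three points")
    if (x <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    if np.unique(x).size < 2:
        raise ValueError("concentrations are constant; no line can be fit")

    if weighting is None:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    elif weighting == "1/x":
        w = 1.0 / x
        W = np.diag(w)
        A = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
        slope, intercept = float(beta[0]), float(beta[1])
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationCurve(tuple(x), tuple(y), slope, intercept, min(r2, 1.0))


def quantify(area: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Inverse-predict concentration from a peak area.

    Returns ``(concentration, below_range)``; a negative estimate is clamped
    semantics-free but flagged ``below_range=True``.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    conc = (area - curve.intercept) / curve.slope
    return conc, conc < 0


@dataclass
class CompositionSummary:
    """Class/subclass tallies and per-group intensity shares."""

    class_counts: dict[str, int]
    subclass_counts: dict[str, int]
    unparseable: list[str] = field(default_factory=list)
    proportions: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    def class_share(self, classes: Iterable[str]) -> float:
        """Fraction of all identified species in the given classes."""
        total = self.total
        if total == 0:
            raise ValueError("no species counted")
        return sum(self.class_counts.get(c, 0) for c in classes) / total


def class_counts(species: Iterable[LipidSpecies | str],
                 ontology: Mapping[str, str] | None = None) -> CompositionSummary:
    """Tally identified species per class and subclass.

    Accepts parsed :class:`LipidSpecies` or raw names; names that fail to
    parse are listed in ``unparseable``, never silently dropped.
    """
    from .catalog import LipidParseError, parse_lipid_name

    cls: dict[str, int] = {}
    sub: dict[str, int] = {}
    bad: list[str] = []
    for sp in species:
        if isinstance(sp, str):
            try:
                sp = parse_lipid_name(sp, ontology)
            except LipidParseError:
                bad.append(sp)
                continue
        cls[sp.lipid_class] = cls.get(sp.lipid_class, 0) + 1
        sub[sp.subclass] = sub.get(sp.subclass, 0) + 1
    return CompositionSummary(class_counts=cls, subclass_counts=sub, unparseable=bad)


def composition_proportions(table: FeatureTable,
                            annotation: Mapping[str, str],
                            group: str) -> dict[str, float]:
    """Share of each subclass in a group's summed raw intensity.

    ``annotation`` maps feature id → subclass; every feature must be
    annotated. Missing cells contribute zero. Fractions sum to 1.
    """
    cols = table.group_columns(group)
    if not cols:
        raise ValueError(f"no samples in group {group!r}")
    missing = [f for f in table.feature_ids if f not in annotation]
    if missing:
        raise ValueError(f"unannotated feature(s): {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    sums = table.values[cols].sum(axis=1, skipna=True)
    by_sub: dict[str, float] = {}
    for fid, s in sums.items():
        by_sub[annotation[fid]] = by_sub.get(annotation[fid], 0.0) + float(s)
    total = sum(by_sub.values())
    if total <= 0:
        raise ValueError(f"group {group!r} has zero total intensity")
    return {k: v / total for k, v in by_sub.items()}


@dataclass
class FattyAcidProfile:
    """Per-group totals of a fatty-acid profile (g/100 g).

    ``ufa_fa_ratio`` is (MUFA + PUFA) / (SFA + MUFA + PUFA); ``undefined``
    flags groups whose total content is zero.
    """

    acids: dict[str, str]                     # acid label -> saturation class
    totals: pd.DataFrame                      # rows SFA/MUFA/PUFA × group cols
    ufa_fa_ratio: dict[str, float]
    undefined: list[str] = field(default_factory=list)

    def rounded(self, ndigits: int = 3) -> "FattyAcidProfile":
        return FattyAcidProfile(
            acids=self.acids,
            totals=self.totals.round(ndigits),
            ufa_fa_ratio={g: round(v, ndigits)
                          for g, v in self.ufa_fa_ratio.items()},
            undefined=list(self.undefined),
        )


def fatty_acid_totals(profile: pd.DataFrame) -> FattyAcidProfile:
    """Sum a fatty-acid table into SFA/MUFA/PUFA totals and UFA/FA ratios.

    ``profile`` has acid shorthand labels as index and one column per group
    (mean contents, g/100 g). Unknown labels raise; groups with zero total
    are flagged rather than given a ratio.
    """
    sat = {acid: classify_fatty_acid(str(acid)).saturation
           for acid in profile.index}
    totals = pd.DataFrame(0.0, index=["SFA", "MUFA", "PUFA"],
                          columns=profile.columns)
    for acid, s in sat.items():
        totals.loc[s] += profile.loc[acid].astype(float)
    ratios: dict[str, float] = {}
    undefined: list[str] = []
    for g in profile.columns:
        sfa, mufa, pufa = (float(totals.loc[k, g]) for k in ("SFA", "MUFA", "PUFA"))
        denom = sfa + mufa + pufa
        if denom <= 0:
            undefined.append(g)
        else:
            ratios[g] = (mufa + pufa) / denom
    return FattyAcidProfile(acids=sat, totals=totals, ufa_fa_ratio=ratios,
                            undefined=undefined)


_MEAN_SD_RE = re.compile(
    r"^\s*([0-9.]+)\s*(?:±|\+/-|\+-)\s*([0-9.]+)\s*(?:\^?([a-z]+)\^?)?\s*$")


def parse_mean_sd_cell(cell: str) -> tuple[float, float, str]:
    """Parse a ``'0.711 ± 0.009 ^c^'`` style cell to (mean, sd, letters)."""
    m = _MEAN_SD_RE.match(str(cell))
    if not m:
        raise ValueError(f"cannot parse mean±sd cell {cell!r}")
    return float(m.group(1)), float(m.group(2)), m.group(3) or ""


def read_profile_table(path, sep: str = ",") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a published-style profile table into (means, sds) frames.

    Accepts either split numeric columns (``<group>_mean`` / ``<group>_sd``)
    or combined ``mean ± sd ^letters^`` text cells, with acid labels in the
    first column.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    mean_cols = [c for c in raw.columns if c.endswith("_mean")]
    if mean_cols:
        groups = [c[:-5] for c in mean_cols]
        means = pd.DataFrame({g: raw[f"{g}_mean"].astype(float) for g in groups})
        sds = pd.DataFrame({
            g: raw[f"{g}_sd"].astype(float) if f"{g}_sd" in raw.columns
            else np.nan for g in groups})
        return means, sds
    means = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    sds = means.copy()
    for g in raw.columns:
        parsed = raw[g].map(parse_mean_sd_cell)
        means[g] = [p[0] for p in parsed]
        sds[g] = [p[1] for p in parsed]
    return means, sds
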