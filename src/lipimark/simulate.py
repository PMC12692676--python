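"""Synthetic lipidomics study generator.

Emulates the statistical shape of a widely targeted lipidomics comparison of
three origins (default 3 groups × 6 animals): ~1000 log-normally distributed
lipid peak areas, a small set of planted origin-discriminating markers (each
elevated in one group, as origin-marker lipids typically are), five pooled-QC
injections carrying only multiplicative technical noise, missing-at-random
detection dropout in the QC cells, and meat-quality traits linearly wired to
chosen marker log-intensities. The generator also returns the ground truth
(marker ids, planted bad features, trait wirings) so recovery can be scored.

Lipid intensities are modelled log-normal: peak areas are positive and
right-skewed, and CV-based QC filtering presumes multiplicative noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import classify_fatty_acid
from .table import QC_GROUP, FeatureTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "TRAIT_BASELINES",
    "DEFAULT_TRAIT_LOADINGS",
    "generate_lipidome",
    "generate_quality_table",
    "generate_fatty_acid_table",
    "fatty_acid_reference",
]

#: Realistic baselines (location, scale) for each meat-quality trait.
#: pH is unitless; L*/a*/b* are colorimeter units; shear force N; losses,
#: moisture, fat and protein are percentages.
TRAIT_BASELINES: dict[str, tuple[float, float]] = {
    "pH": (5.85, 0.12),
    "L": (38.0, 2.5),
    "a": (18.0, 1.5),
    "b": (8.0, 1.2),
    "shear_force": (45.0, 8.0),
    "centrifugal_loss": (18.0, 3.0),
    "cooking_loss": (35.0, 4.0),
    "moisture": (74.0, 2.0),
    "fat": (3.5, 1.0),
    "protein": (21.0, 1.5),
}

_PERCENT_TRAITS = {"centrifugal_loss", "cooking_loss", "moisture", "fat", "protein"}

#: Default trait wirings: trait -> (marker index, population correlation with
#: the marker's log-intensity). Remaining traits are pure baseline noise.
DEFAULT_TRAIT_LOADINGS: dict[str, tuple[int, float]] = {
    "pH": (0, -0.8),
    "L": (1, 0.8),
    "centrifugal_loss": (2, 0.8),
    "fat": (3, 0.8),
    "moisture": (4, -0.8),
}


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic lipidome.

    Defaults mirror the emulated study design: 3 origins × 6 animals,
    ~1000 lipid features, 10 markers at 4× fold elevation, 5 pooled-QC
    injections at 10% technical CV with 5% QC dropout.
    """

    n_groups: int = 3
    n_per_group: int = 6
    n_features: int = 1000
    n_markers: int = 10
    effect_size: float = 4.0       # fold elevation of a marker in its up-group
    base_log_mean: float = 13.0    # log peak area location (~4.4e5 cps)
    base_log_spread: float = 1.5   # feature-to-feature spread of log abundance
    biological_sigma: float = 0.5  # within-group log sd (~53% biological CV)
    technical_cv: float = 0.1      # QC replicate CV
    dropout_rate: float = 0.05     # fraction of QC cells set undetected
    n_qc: int = 5
    n_bad_detection: int = 0       # planted features failing the 50% rule
    n_bad_cv: int = 0              # planted features failing the CV 0.3 rule
    group_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.n_markers > self.n_features:
            raise ValueError("n_markers cannot exceed n_features")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.technical_cv <= 0:
            raise ValueError("technical_cv must be positive")
        if self.n_bad_detection + self.n_bad_cv > self.n_features - self.n_markers:
            raise ValueError("too many planted bad features")

    def groups(self) -> list[str]:
        if self.group_names is not None:
            if len(self.group_names) != self.n_groups:
                raise ValueError("group_names length must equal n_groups")
            return list(self.group_names)
        defaults = ["NX", "GS", "IM"]
        if self.n_groups <= 3:
            return defaults[: self.n_groups]
        return defaults + [f"G{i}" for i in range(4, self.n_groups + 1)]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study, for recovery scoring."""

    marker_ids: list[str]
    up_group: dict[str, str]
    group_log_means: pd.DataFrame  # markers × groups, log-intensity locations
    bad_detection_ids: list[str] = field(default_factory=list)
    bad_cv_ids: list[str] = field(default_factory=list)
    trait_loadings: dict[str, tuple[str, float]] = field(default_factory=dict)


def _tech_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unbiased multiplicative log-normal noise with the requested CV."""
    s2 = math.log(1.0 + cv * cv)
    return np.exp(rng.normal(-s2 / 2.0, math.sqrt(s2), size=size))


def generate_lipidome(config: SyntheticConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[FeatureTable, SyntheticTruth]:
    """Draw a synthetic feature table with planted markers and QC columns.

    Biological sample ``log x = mu_f + marker shift + N(0, biological_sigma)``;
    each QC column is the per-feature arithmetic mean of all biological
    samples times multiplicative noise at ``technical_cv``; ``dropout_rate``
    of QC cells are blanked at random. Planted bad features are made to fail
    the QC rules deterministically (detection exactly below 50%, or an
    alternating 3× inflation pattern pushing CV above 0.3).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    groups = config.groups()
    n_bio = config.n_groups * config.n_per_group
    width = len(str(config.n_features))
    feature_ids = [f"L{i + 1:0{width}d}" for i in range(config.n_features)]
    sample_ids = [f"{g}_{j + 1}" for g in groups for j in range(config.n_per_group)]
    sample_groups = [g for g in groups for _ in range(config.n_per_group)]
    qc_ids = [f"QC_{j + 1}" for j in range(config.n_qc)]

    mu = rng.normal(config.base_log_mean, config.base_log_spread,
                    size=config.n_features)

    special = rng.choice(config.n_features,
                         size=config.n_markers + config.n_bad_detection + config.n_bad_cv,
                         replace=False)
    marker_idx = special[: config.n_markers]
    bad_det_idx = special[config.n_markers: config.n_markers + config.n_bad_detection]
    bad_cv_idx = special[config.n_markers + config.n_bad_detection:]

    shift = np.zeros((config.n_features, config.n_groups))
    up_group: dict[str, str] = {}
    for j, fi in enumerate(marker_idx):
        g = j % config.n_groups
        shift[fi, g] = math.log(config.effect_size)
        up_group[feature_ids[fi]] = groups[g]

    log_bio = (mu[:, None]
               + np.repeat(shift, config.n_per_group, axis=1)
               + rng.normal(0.0, config.biological_sigma,
                            size=(config.n_features, n_bio)))
    bio = np.exp(log_bio)

    qc_base = bio.mean(axis=1)
    qc = qc_base[:, None] * _tech_noise(rng, config.technical_cv,
                                        (config.n_features, config.n_qc))

    if config.dropout_rate > 0:
        qc[rng.random(qc.shape) < config.dropout_rate] = np.nan

    # planted detection failures: keep strictly fewer than half the QC cells
    keep = max(0, math.ceil(config.n_qc / 2) - 1)
    for fi in bad_det_idx:
        drop = rng.permutation(config.n_qc)[: config.n_qc - keep]
        qc[fi, drop] = np.nan
    # planted CV failures: alternate 1x/3x inflation (CV ≈ 0.6 at cv_tech=0.1)
    for fi in bad_cv_idx:
        qc[fi, 1::2] *= 3.0

    values = pd.DataFrame(np.hstack([bio, qc]), index=feature_ids,
                          columns=sample_ids + qc_ids)
    group_map = pd.Series(sample_groups + [QC_GROUP] * config.n_qc,
                          index=sample_ids + qc_ids)

    marker_ids = [feature_ids[i] for i in marker_idx]
    group_log_means = pd.DataFrame(
        mu[marker_idx][:, None] + shift[marker_idx],
        index=marker_ids, columns=groups)
    truth = SyntheticTruth(
        marker_ids=marker_ids,
        up_group=up_group,
        group_log_means=group_log_means,
        bad_detection_ids=[feature_ids[i] for i in bad_det_idx],
        bad_cv_ids=[feature_ids[i] for i in bad_cv_idx],
    )
    return FeatureTable(values, group_map), truth


def generate_quality_table(config: SyntheticConfig,
                           truth: SyntheticTruth,
                           table: FeatureTable,
                           loadings: dict[str, tuple[int | str, float]] | None = None,
                           scales: dict[str, float] | None = None,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Meat-quality traits for the biological samples, wired to markers.

    ``loadings`` maps trait name → (marker index or id, target population
    correlation r with that marker's log-intensity). Each wired trait is
    ``baseline mean + scale * (r·z + sqrt(1−r²)·ε)`` where ``z`` is the
    marker's standardized log-intensity; unwired traits are baseline noise.
    ``scales`` overrides a trait's baseline scale (0 gives a constant or
    purely marker-driven column). The realized wirings (with marker ids)
    are recorded in ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if loadings is None:
        # default wirings restricted to the markers that exist
        loadings = {t: (i, r) for t, (i, r) in DEFAULT_TRAIT_LOADINGS.items()
                    if i < len(truth.marker_ids)}

    samples = table.biological_samples
    n = len(samples)
    out = pd.DataFrame(index=pd.Index(samples, name="sample"),
                       columns=list(TRAIT_BASELINES), dtype=float)
    for trait, (mean, scale) in TRAIT_BASELINES.items():
        scale = (scales or {}).get(trait, scale)
        if trait in loadings:
            ref, r = loadings[trait]
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"loading r for {trait!r} outside [-1, 1]")
            marker = truth.marker_ids[ref] if isinstance(ref, int) else ref
            if marker not in table.values.index:
                raise ValueError(f"unknown marker {marker!r} for trait {trait!r}")
            z = np.log(table.values.loc[marker, samples].to_numpy(dtype=float))
            sd = z.std(ddof=1)
            z = (z - z.mean()) / sd if sd > 0 else np.zeros(n)
            eps = rng.standard_normal(n)
            col = mean + scale * (r * z + math.sqrt(1.0 - r * r) * eps)
            truth.trait_loadings[trait] = (marker, r)
        else:
            col = mean + scale * rng.standard_normal(n)
        if trait in _PERCENT_TRAITS:
            col = np.clip(col, 0.0, 100.0)
        out[trait] = col
    unknown = set(loadings) - set(TRAIT_BASELINES)
    if unknown:
        raise ValueError(f"unknown trait name(s): {sorted(unknown)}")
    return out


def fatty_acid_reference() -> pd.DataFrame:
    """Published per-group fatty-acid means ± sd (g/100 g) for the 17 acids.

    Long format: columns acid, group, mean, sd, letters. Used as the
    generator's default parameters and as a worked-example input.
    """
    from importlib import resources

    path = resources.files("lipimark.data").joinpath("tan_lamb_fatty_acids.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, keep_default_na=False)
    df["mean"] = df["mean"].astype(float)
    df["sd"] = df["sd"].astype(float)
    return df


def generate_fatty_acid_table(config: SyntheticConfig,
                              reference: pd.DataFrame | None = None,
                              sd_scale: float = 1.0,
                              rng: np.random.Generator | None = None
                              ) -> pd.DataFrame:
    """Per-sample fatty-acid contents (g/100 g), Gaussian around group means.

    Group means/sds default to the shipped reference profile; ``sd_scale=0``
    makes every sample equal its group mean. Output is tidy: one row per
    sample with a ``group`` column and one column per acid.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if reference is None:
        reference = fatty_acid_reference()
    for acid in reference["acid"].unique():
        classify_fatty_acid(acid)  # validate labels up front

    wide_mean = reference.pivot(index="acid", columns="group", values="mean")
    wide_sd = reference.pivot(index="acid", columns="group", values="sd")
    groups = [g for g in reference["group"].unique()]
    rows = []
    index = []
    for g in groups:
        for j in range(config.n_per_group):
            draw = rng.normal(wide_mean[g].to_numpy(),
                              sd_scale * wide_sd[g].to_numpy())
            rows.append(np.clip(draw, 0.0, None))
            index.append(f"{g}_{j + 1}")
    out = pd.DataFrame(rows, index=pd.Index(index, name="sample"),
                       columns=list(wide_mean.index))
    out.insert(0, "group", [g for g in groups for _ in range(config.n_per_group)])
    return out
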