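"""Condition-level Z-score and single-cell standard-score profiling.

The aggregation hierarchy runs cells -> well summary means (technical
replicates) -> experiment means (one per replicate plate) -> condition
means.  Two normalizations are built on it:

* **Z-score profile** (condition level, relative to the proliferating
  control): per feature,
  ``Z = (condition mean_sen - condition mean_ctrl) / SD(control experiment
  means)`` with the n-1 SD over the control replicate means.  |Z| > 1.96
  is called a significant change.
* **Standard score** (single cell): within each experimental replicate,
  each feature is centred and scaled by the mean and n-1 SD of the pooled
  proliferating + senescent cells of that replicate; replicate scores are
  then concatenated and summarized by feature-wise medians.

Masked features (e.g. the 8 cell-geometry features unavailable on the
older rectangular-image microscope generation) are fixed at 0 in profiles
and excluded from significance counts and downstream factor analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io_tables import FeatureTable, StudyDesign

logger = logging.getLogger(__name__)

Z_SIGNIFICANCE = 1.96


@dataclass
class ProfileMatrix:
    """Rows = conditions (or strata), columns = features."""

    data: pd.DataFrame
    kind: str  # "zscore" | "standard"
    mask: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"zscore", "standard"}:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        self.mask = tuple(self.mask)


@dataclass
class AggregationLevels:
    """Feature-wise means at the three aggregation levels, with cell counts."""

    well_means: pd.DataFrame        # index (condition, replicate, well)
    experiment_means: pd.DataFrame  # index (condition, replicate)
    condition_means: pd.DataFrame   # index condition
    counts: dict = dc_field(default_factory=dict)


def aggregate(table: FeatureTable, design: StudyDesign | None = None) -> AggregationLevels:
    """Three-level mean hierarchy; missing values are excluded pairwise."""
    df = table.df
    feats = list(table.schema)
    if design is not None:
        for cond in (design.control_condition_id, design.senescent_condition_id):
            if cond not in set(df["condition_id"]):
                raise ValueError(f"condition {cond!r} absent from table")
    well = df.groupby(["condition_id", "replicate_id", "well_id"], sort=True)[feats].mean()
    expt = well.groupby(["condition_id", "replicate_id"], sort=True).mean()
    cond = expt.groupby("condition_id", sort=True).mean()
    counts = {
        "cells_per_well": df.groupby(["condition_id", "replicate_id", "well_id"]).size(),
        "wells_per_experiment": well.groupby(["condition_id", "replicate_id"]).size(),
        "experiments_per_condition": expt.groupby("condition_id").size(),
    }
    return AggregationLevels(well, expt, cond, counts)


def zscore_profile(levels: AggregationLevels, design: StudyDesign) -> ProfileMatrix:
    """Senescent-vs-control Z-score row; the control row is implicit (zero)."""
    ctrl, sen = design.control_condition_id, design.senescent_condition_id
    ctrl_expts = levels.experiment_means.loc[ctrl]
    if len(ctrl_expts) < 2:
        raise ValueError("need >=2 control experiment means for a defined SD")
    sd = ctrl_expts.std(ddof=1)
    diff = levels.condition_means.loc[sen] - levels.condition_means.loc[ctrl]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / sd
    zero_sd = sd == 0
    if zero_sd.any():
        bad = list(sd.index[zero_sd])
        warnings.warn(f"zero control SD, Z missing for: {bad}", stacklevel=2)
        z[zero_sd] = np.nan
    return ProfileMatrix(pd.DataFrame([z], index=[sen]), kind="zscore")


def standard_scores(table: FeatureTable) -> pd.DataFrame:
    """Per-cell standard scores, centred/scaled within each replicate.

    Pooling covers every condition present in the replicate; the returned
    frame keeps the metadata columns and replaces feature values by scores.
    """
    df = table.df.copy()
    feats = list(table.schema)
    for rep, idx in df.groupby("replicate_id").groups.items():
        sub = df.loc[idx, feats]
        mean, sd = sub.mean(), sub.std(ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"replicate {rep}: zero pooled SD for {list(sd.index[zero])}", stacklevel=2
            )
        sd = sd.where(~zero)
        df.loc[idx, feats] = ((sub - mean) / sd).to_numpy()
    return df


def median_profile(
    scores: pd.DataFrame,
    features: list[str],
    by: str | list[str] = "condition_id",
) -> ProfileMatrix:
    """Feature-wise median of scores per condition (or other grouping)."""
    med = scores.groupby(by, sort=True)[features].median()
    return ProfileMatrix(med, kind="standard")


def significant_features(
    profile: ProfileMatrix, threshold: float = Z_SIGNIFICANCE
) -> dict[str, tuple[list[str], int]]:
    """Features with |Z| strictly above *threshold*, per profile row.

    Masked features never count; NaN (undefined) Z-scores never count.
    """
    out = {}
    for row, z in profile.data.iterrows():
        z = z.drop(labels=list(profile.mask), errors="ignore")
        hits = list(z.index[z.abs() > threshold])
        out[row] = (hits, len(hits))
    return out


def mask_features(profile: ProfileMatrix, names: list[str]) -> ProfileMatrix:
    """Zero the named features in all rows and record them in the mask list."""
    unknown = [n for n in names if n not in profile.data.columns]
    if unknown:
        raise KeyError(f"cannot mask unknown feature(s): {unknown}")
    data = profile.data.copy()
    data[list(names)] = 0.0
    return ProfileMatrix(data, kind=profile.kind, mask=tuple(dict.fromkeys((*profile.mask, *names))))


def cluster_profiles(profile: ProfileMatrix) -> tuple[list, np.ndarray | None]:
    """Ward.D2 agglomerative clustering of profile rows on Euclidean distances.

    Ward's criterion is applied to unsquared Euclidean distances (the
    ward.D2 convention).  Returns (leaf order as row labels, linkage
    matrix); fewer than two rows yield the identity order.
    """
    rows = profile.data.index.tolist()
    if len(rows) < 2:
        return rows, None
    x = profile.data.fillna(0.0).to_numpy()
    link = linkage(pdist(x, metric="euclidean"), method="ward")
    order = [rows[i] for i in leaves_list(link)]
    return order, link


def plot_profile(profile: ProfileMatrix, path, cluster: bool = True) -> None:
    """Export a red/blue diverging heatmap (red positive, blue negative)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = profile.data
    if cluster and len(data) > 1:
        order, _ = cluster_profiles(profile)
        data = data.loc[order]
    lim = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(6, 0.18 * data.shape[1]), max(2.5, 0.5 * data.shape[0] + 1.5))
    )
    im = ax.imshow(data.to_numpy(), cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_yticks(range(len(data.index)), data.index)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label=profile.kind)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
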