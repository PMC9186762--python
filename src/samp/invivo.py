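"""In-vivo profiling of brightfield IHC per-cell tables.

Consumes tab-separated per-cell measurement exports (27 morphology
features plus the p21 DAB mean optical density per nucleus), grades p21
staining intensity into 0/1+/2+/3+ classes at configurable OD thresholds
(0.2/0.4/0.6 by default; the 0.05 counterstain detection threshold is
upstream metadata), and builds treatment-level and p21-stratified Z-score
and standard-score profiles over the 27 features.

Conventions: the class boundary is inclusive (OD >= 0.2 is 1+, hence
p21-positive); the Z-score reference population for the stratified
profiles is the within-treatment p21-negative stratum, with the SD taken
across sample-level means (n-1).  Both choices are configurable.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .profiling import ProfileMatrix
from .registry import INVIVO_FEATURES

logger = logging.getLogger(__name__)

P21_THRESHOLDS = (0.2, 0.4, 0.6)
COUNTERSTAIN_DETECTION_OD = 0.05  # upstream nucleus-detection threshold (metadata)
OD_COLUMN = "Nucleus: p21 OD mean"
CLASS_LABELS = ("0", "1+", "2+", "3+")


def read_invivo_table(path: str | Path, od_column: str = OD_COLUMN) -> pd.DataFrame:
    """Read a tab-separated per-cell export and validate the 27-feature schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (*INVIVO_FEATURES, od_column, "sample_id", "treatment") if c not in df.columns]
    if missing:
        raise ValueError(f"in-vivo table missing column(s): {missing}")
    return df


def classify_p21(
    cells: pd.DataFrame,
    thresholds: tuple[float, float, float] = P21_THRESHOLDS,
    od_column: str = OD_COLUMN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grade p21 intensity and summarize percent positivity.

    Class = highest threshold not exceeding the OD (inclusive boundaries);
    a cell is p21-positive iff it reaches 1+.  Cells with missing OD are
    excluded and counted.  Returns (classed table, per-sample summary).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    df = cells.copy()
    missing = df[od_column].isna()
    if missing.any():
        logger.warning("excluding %d cell(s) with missing p21 OD", int(missing.sum()))
        df = df[~missing].copy()
    od = df[od_column].to_numpy(float)
    if (od < 0).any():
        raise ValueError("optical densities must be nonnegative")
    cls = np.zeros(len(df), dtype=int)
    for i, t in enumerate(thresholds, start=1):
        cls[od >= t] = i
    df["p21_class"] = [CLASS_LABELS[c] for c in cls]
    df["p21_positive"] = cls >= 1
    per_sample = (
        df.groupby(["treatment", "sample_id"])["p21_positive"]
        .agg(n_cells="size", percent_positive=lambda s: 100.0 * s.mean())
        .reset_index()
    )
    per_sample["n_excluded_missing_od"] = int(missing.sum())
    return df, per_sample


def _pooled_standard_scores(df: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    out = df.copy()
    sub = out[list(features)]
    sd = sub.std(ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"zero pooled SD for {list(sd.index[zero])}", stacklevel=3)
    out[list(features)] = (sub - sub.mean()) / sd.where(~zero)
    return out


def invivo_condition_profiles(cells: pd.DataFrame) -> ProfileMatrix:
    """Mean standard-score profile per treatment, pooled over both treatments."""
    feats = list(INVIVO_FEATURES)
    scored = _pooled_standard_scores(cells, feats)
    prof = scored.groupby("treatment", sort=True)[feats].mean()
    return ProfileMatrix(prof, kind="standard")


def invivo_stratified_profiles(
    cells: pd.DataFrame,
    thresholds: tuple[float, float, float] = P21_THRESHOLDS,
    od_column: str = OD_COLUMN,
) -> tuple[ProfileMatrix, ProfileMatrix]:
    """p21-stratified profiles: Z of positive vs negative cells, per treatment.

    The Z-score row for each treatment compares the p21-positive stratum
    against the p21-negative reference: per feature,
    ``Z = (mean of positive sample means - mean of negative sample means)
    / SD(negative sample means)``.  The standard-score matrix holds one
    row per treatment x p21 status, scores pooled within treatment.
    """
    feats = list(INVIVO_FEATURES)
    classed, _ = classify_p21(cells, thresholds, od_column)

    z_rows, z_index = [], []
    std_frames = []
    for treatment, group in classed.groupby("treatment", sort=True):
        sample_means = group.groupby(["p21_positive", "sample_id"])[feats].mean()
        try:
            neg = sample_means.loc[False]
            pos = sample_means.loc[True]
        except KeyError:
            warnings.warn(f"{treatment}: a p21 stratum is empty, Z skipped", stacklevel=2)
            neg = pos = None
        if neg is not None and len(neg) >= 2 and len(pos) >= 1:
            z = (pos.mean() - neg.mean()) / neg.std(ddof=1)
            z_rows.append(z)
            z_index.append(f"{treatment}: p21+ vs p21-")
        else:
            warnings.warn(
                f"{treatment}: <2 samples in a stratum, Z missing", stacklevel=2
            )
        scored = _pooled_standard_scores(group, feats)
        med = scored.groupby("p21_positive")[feats].mean()
        med.index = [
            f"{treatment}: p21{'+' if flag else '-'}" for flag in med.index
        ]
        std_frames.append(med)

    zprof = ProfileMatrix(
        pd.DataFrame(z_rows, index=z_index, columns=feats), kind="zscore"
    )
    sprof = ProfileMatrix(pd.concat(std_frames), kind="standard")
    return zprof, sprof
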