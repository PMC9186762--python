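"""Input/output of segmented fields, per-cell feature tables and study designs.

Interchange formats are deliberately plain: TIFF for intensity and label
images, comma-separated UTF-8 CSV with "."-decimal for feature tables
(header names byte-exact to the registry), and a JSON sidecar for the
study design.  Missing feature values are written as empty strings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .registry import INVITRO_FEATURES, METADATA_COLUMNS

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table does not conform to the canonical feature registry."""


class DimensionError(ValueError):
    """Images of one field do not share a common shape."""


@dataclass
class SegmentedField:
    """One segmented field of view: two intensity channels plus matched label masks.

    The nuclear-stain image visualises nuclei and the whole-cell-stain image
    the full cell body.  Label masks use 0 for background and a shared
    positive integer label per nucleus/cell pair; every nucleus must lie
    inside the same-labelled cell.
    """

    nuc_image: np.ndarray
    cell_image: np.ndarray
    nuc_labels: np.ndarray
    cell_labels: np.ndarray
    pixel_size: float = 1.0
    field_id: str = "F1"
    well_id: str = "W1"
    replicate_id: str = "R1"
    condition_id: str = "C1"
    model_id: str = "M1"

    def __post_init__(self) -> None:
        self.nuc_image = np.asarray(self.nuc_image)
        self.cell_image = np.asarray(self.cell_image)
        self.nuc_labels = np.asarray(self.nuc_labels)
        self.cell_labels = np.asarray(self.cell_labels)
        shapes = {
            a.shape
            for a in (self.nuc_image, self.cell_image, self.nuc_labels, self.cell_labels)
        }
        if len(shapes) != 1:
            raise DimensionError(f"field images have mismatched shapes: {sorted(shapes)}")
        if np.any(self.nuc_image < 0) or np.any(self.cell_image < 0):
            raise ValueError("intensity images must be nonnegative")
        self._drop_unmatched()

    def _drop_unmatched(self) -> None:
        """Drop nuclei whose pixel set is not a subset of the same-labelled cell."""
        dropped = []
        for lab in self.labels():
            nuc = self.nuc_labels == lab
            if not np.all(self.cell_labels[nuc] == lab):
                dropped.append(lab)
        for lab in dropped:
            self.nuc_labels = np.where(self.nuc_labels == lab, 0, self.nuc_labels)
            self.cell_labels = np.where(self.cell_labels == lab, 0, self.cell_labels)
        if dropped:
            msg = f"dropped {len(dropped)} object(s) violating nucleus-inside-cell: {dropped}"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=3)

    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the nucleus mask."""
        labs = np.unique(self.nuc_labels)
        return labs[labs > 0]


@dataclass
class StudyDesign:
    """Pairing of one proliferating control and one senescent condition."""

    model_id: str
    control_condition_id: str
    senescent_condition_id: str
    replicate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.control_condition_id == self.senescent_condition_id:
            raise ValueError("control and senescent conditions must differ")
        self.replicate_ids = tuple(self.replicate_ids)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, default=list, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyDesign":
        d = json.loads(Path(path).read_text())
        return cls(
            model_id=d["model_id"],
            control_condition_id=d["control_condition_id"],
            senescent_condition_id=d["senescent_condition_id"],
            replicate_ids=tuple(d.get("replicate_ids", ())),
        )


class FeatureTable:
    """Cells x features table with study metadata.

    Wraps a :class:`pandas.DataFrame` whose columns are the metadata
    identifiers followed by the canonical feature registry, in registry
    order.  Missing values are permitted only where the extraction rules
    allow them (spatial features in near-empty fields, masked features).
    """

    def __init__(self, df: pd.DataFrame, schema: Sequence[str] = INVITRO_FEATURES):
        self.schema = tuple(schema)
        df = df.copy()
        missing_meta = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing_meta:
            raise SchemaError(f"missing mandatory metadata column(s): {missing_meta}")
        missing_feat = [c for c in self.schema if c not in df.columns]
        if missing_feat:
            raise SchemaError(f"missing feature column(s): {missing_feat}")
        unknown = [
            c for c in df.columns if c not in self.schema and c not in METADATA_COLUMNS
        ]
        if unknown:
            logger.warning("ignoring unknown column(s): %s", unknown)
        for c in METADATA_COLUMNS:
            df[c] = df[c].astype(str)
        for c in self.schema:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                bad = df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
                row = bad[0] if len(bad) else "?"
                raise SchemaError(
                    f"non-numeric value in feature column {c!r} at row {row}"
                ) from exc
        key = df[list(METADATA_COLUMNS[1:])]
        if key.duplicated().any():
            raise SchemaError("duplicate (condition, replicate, well, field, object) keys")
        self.df = df[list(METADATA_COLUMNS) + list(self.schema)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def features(self) -> pd.DataFrame:
        return self.df[list(self.schema)]

    @property
    def metadata(self) -> pd.DataFrame:
        return self.df[list(METADATA_COLUMNS)]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.df.copy(), self.schema)


def read_feature_table(
    path: str | Path, schema: Sequence[str] = INVITRO_FEATURES
) -> FeatureTable:
    """Read a CSV/TSV per-cell feature table and validate it against *schema*."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={c: str for c in METADATA_COLUMNS})
    return FeatureTable(df, schema)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write *table* as UTF-8 CSV; missing values become empty strings."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False, na_rep="")


def read_field(
    nuc_image_path: str | Path,
    cell_image_path: str | Path,
    nuc_labels_path: str | Path,
    cell_labels_path: str | Path,
    **metadata,
) -> SegmentedField:
    """Assemble a :class:`SegmentedField` from four TIFF files.

    Nuclei that are not contained in their same-labelled cell are dropped
    with a logged warning; a shape mismatch raises :class:`DimensionError`.
    """
    arrays = [
        tifffile.imread(p)
        for p in (nuc_image_path, cell_image_path, nuc_labels_path, cell_labels_path)
    ]
    return SegmentedField(
        nuc_image=np.asarray(arrays[0], dtype=np.float64),
        cell_image=np.asarray(arrays[1], dtype=np.float64),
        nuc_labels=np.asarray(arrays[2], dtype=np.int64),
        cell_labels=np.asarray(arrays[3], dtype=np.int64),
        **metadata,
    )


def write_field(field: SegmentedField, directory: str | Path, stem: str = "field") -> dict:
    """Write the four images of *field* as TIFFs; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "nuc_image": directory / f"{stem}_nuc.tif",
        "cell_image": directory / f"{stem}_cell.tif",
        "nuc_labels": directory / f"{stem}_nuclabels.tif",
        "cell_labels": directory / f"{stem}_celllabels.tif",
    }
    tifffile.imwrite(paths["nuc_image"], field.nuc_image.astype(np.float32))
    tifffile.imwrite(paths["cell_image"], field.cell_image.astype(np.float32))
    tifffile.imwrite(paths["nuc_labels"], field.nuc_labels.astype(np.int32))
    tifffile.imwrite(paths["cell_labels"], field.cell_labels.astype(np.int32))
    return paths
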