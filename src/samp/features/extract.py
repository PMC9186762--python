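"""Assemble the 62-feature per-cell table from a segmented field.

Nuclear features are measured on the nuclear-stain channel within the
nucleus mask; cellular features on the whole-cell-stain channel within
the cell mask (the "Cyto" variants use cell-minus-nucleus pixels).
Objects whose cell mask touches the field border are excluded from
measurement (truncated morphology would bias size features).  Spatial
features are computed per field on the nuclear centroids of the included
objects and are missing when a field holds fewer than two nuclei.  Light
flux is total intensity normalized to the field-median total intensity of
the same compartment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..io_tables import FeatureTable, SegmentedField
from ..registry import INVITRO_FEATURES, METADATA_COLUMNS
from .geometry import object_geometry
from .glrlm import glrlm_stats
from .graphs import GRAPH_METHODS, spatial_stats
from .intensity import intensity_spreading, intensity_stats

logger = logging.getLogger(__name__)


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def _object_row(field: SegmentedField, lab: int) -> dict[str, float] | None:
    nuc_mask = field.nuc_labels == lab
    cell_mask = field.cell_labels == lab
    if not nuc_mask.any() or not cell_mask.any():
        return None

    nuc_geo = object_geometry(nuc_mask, field.nuc_image)
    cell_geo = object_geometry(cell_mask, field.cell_image)

    nuc_int = intensity_stats(field.nuc_image[nuc_mask])
    cell_int = intensity_stats(field.cell_image[cell_mask])

    cyto_mask = cell_mask & ~nuc_mask
    if cyto_mask.any():
        cyto_int = intensity_stats(field.cell_image[cyto_mask])
        cyto_mean = cyto_int.mean
        nuc_cyto = (
            float(field.cell_image[nuc_mask].mean()) / cyto_mean
            if cyto_mean != 0
            else np.nan
        )
        cyto = dict(
            mean=cyto_int.mean, total=cyto_int.total, sd=cyto_int.sd, cv=cyto_int.cv
        )
    else:
        logger.warning("object %d: nucleus fills cell, cytoplasm features missing", lab)
        cyto = dict(mean=np.nan, total=np.nan, sd=np.nan, cv=np.nan)
        nuc_cyto = np.nan

    pts = np.argwhere(cell_mask).astype(float)
    dists = np.hypot(*(pts - np.asarray(cell_geo.centroid)).T)
    spreading = intensity_spreading(field.cell_image[cell_mask], dists)

    nuc_tex = glrlm_stats(field.nuc_image, nuc_mask)
    cell_tex = glrlm_stats(field.cell_image, cell_mask)

    return {
        "Nuclei Area": nuc_geo.area,
        "Nuclei Form Factor": nuc_geo.form_factor,
        "Nuclei Elongation": nuc_geo.elongation,
        "Nuclei Compactness": nuc_geo.compactness,
        "Nuclei Chord Ratio": nuc_geo.chord_ratio,
        "Nuclei Gyration Radius": nuc_geo.gyration_radius,
        "Nuclei Displacement": nuc_geo.displacement,
        "Nuclei Diameter": nuc_geo.equivalent_diameter,
        "Nuclei Perimeter": nuc_geo.perimeter,
        "Nuclei Intensity": nuc_int.mean,
        "Nuclei Total Intensity": nuc_int.total,
        "Nuclei Intensity CV": nuc_int.cv,
        "Nuclei Light Flux": np.nan,  # field-normalized after the object loop
        "Nuclei Intensity SD": nuc_int.sd,
        "Nuclei Major Axis": nuc_geo.major_axis,
        "Nuclei Minor Axis": nuc_geo.minor_axis,
        "Nuclei Skewness": nuc_int.skewness,
        "Nuclei Kurtosis": nuc_int.kurtosis,
        "Nuclei Energy": nuc_int.energy,
        "Nuclei Entropy": nuc_int.entropy,
        "Nuclei Grey Level Non Uniformity": nuc_tex.gln,
        "Nuclei High GLRE": nuc_tex.hglre,
        "Nuclei Low GLRE": nuc_tex.lglre,
        "Nuclei Run Length Non uniformity": nuc_tex.rln,
        "Cells Area": cell_geo.area,
        "Cells Form Factor": cell_geo.form_factor,
        "Cells Elongation": cell_geo.elongation,
        "Cells Compactness": cell_geo.compactness,
        "Cells Chord Ratio": cell_geo.chord_ratio,
        "Cells Gyration Radius": cell_geo.gyration_radius,
        "Cells Nuc/Cell Area": nuc_geo.area / cell_geo.area,
        "Cells Diameter": cell_geo.equivalent_diameter,
        "Cells Perimeter": cell_geo.perimeter,
        "Cells Intensity (Cell)": cell_int.mean,
        "Cells Intensity (Cyto)": cyto["mean"],
        "Cells Total Intensity (Cell)": cell_int.total,
        "Cells Total Intensity (Cyto)": cyto["total"],
        "Cells Intensity CV (Cell)": cell_int.cv,
        "Cells Intensity CV (Cyto)": cyto["cv"],
        "Cells Intensity Spreading": spreading,
        "Cells Light Flux": np.nan,
        "Cells Nuc/Cyto Intensity": nuc_cyto,
        "Cells Intensity SD (Cell)": cell_int.sd,
        "Cells Intensity SD (Cyto)": cyto["sd"],
        "Cells Major Axis": cell_geo.major_axis,
        "Cells Minor Axis": cell_geo.minor_axis,
        "Cells Skewness": cell_int.skewness,
        "Cells Kurtosis": cell_int.kurtosis,
        "Cells Energy": cell_int.energy,
        "Cells Entropy": cell_int.entropy,
        "Cells Grey Level Non Uniformity": cell_tex.gln,
        "Cells High GLRE": cell_tex.hglre,
        "Cells Low GLRE": cell_tex.lglre,
        "Cells Run Length Non Uniformity": cell_tex.rln,
        "_nuc_centroid_r": nuc_geo.centroid[0],
        "_nuc_centroid_c": nuc_geo.centroid[1],
    }


def extract_all(field: SegmentedField) -> FeatureTable:
    """One row of 62 features per matched, non-border nucleus/cell pair."""
    rows: dict[int, dict[str, float]] = {}
    excluded: list[int] = []
    for lab in field.labels():
        if _touches_border(field.cell_labels == int(lab)):
            excluded.append(int(lab))
            continue
        row = _object_row(field, int(lab))
        if row is not None:
            rows[int(lab)] = row
    if excluded:
        logger.info("field %s: excluded %d border object(s)", field.field_id, len(excluded))
    if not rows:
        return FeatureTable(
            pd.DataFrame(columns=list(METADATA_COLUMNS) + list(INVITRO_FEATURES))
        )

    labels = sorted(rows)
    # field-level normalizations: light flux relative to the field-median total
    nuc_totals = np.array([rows[l]["Nuclei Total Intensity"] for l in labels])
    cell_totals = np.array([rows[l]["Cells Total Intensity (Cell)"] for l in labels])
    nuc_med, cell_med = np.median(nuc_totals), np.median(cell_totals)
    for l in labels:
        rows[l]["Nuclei Light Flux"] = (
            rows[l]["Nuclei Total Intensity"] / nuc_med if nuc_med > 0 else np.nan
        )
        rows[l]["Cells Light Flux"] = (
            rows[l]["Cells Total Intensity (Cell)"] / cell_med if cell_med > 0 else np.nan
        )

    spatial_cols = [f"Nuclei {k}" for m in GRAPH_METHODS for k in (f"Spacing ({m})", f"Neighbor Count ({m})")]
    if len(labels) >= 2:
        centroids = np.array(
            [(rows[l]["_nuc_centroid_r"], rows[l]["_nuc_centroid_c"]) for l in labels]
        )
        stats = spatial_stats(centroids)
        for i, l in enumerate(labels):
            for m in GRAPH_METHODS:
                rows[l][f"Nuclei Spacing ({m})"] = stats[f"Spacing ({m})"][i]
                rows[l][f"Nuclei Neighbor Count ({m})"] = stats[f"Neighbor Count ({m})"][i]
    else:
        logger.warning("field %s: <2 nuclei, spatial features missing", field.field_id)
        for l in labels:
            for col in spatial_cols:
                rows[l][col] = np.nan

    records = []
    for l in labels:
        rec = {
            "model_id": field.model_id,
            "condition_id": field.condition_id,
            "replicate_id": field.replicate_id,
            "well_id": field.well_id,
            "field_id": field.field_id,
            "object_id": str(l),
        }
        rec.update({k: v for k, v in rows[l].items() if not k.startswith("_")})
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    return FeatureTable(df[list(METADATA_COLUMNS) + list(INVITRO_FEATURES)])
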