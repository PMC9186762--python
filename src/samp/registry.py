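"""Canonical feature registries.

The in-vitro registry fixes the 62 per-cell features measured from the
two-channel (DAPI + whole-cell stain) high-content images: nuclear and
cellular size/shape, intensity moments, histogram statistics, grey-level
run-length (GLRLM) texture and nuclear neighbourhood-graph spatial
statistics.  The in-vivo registry fixes the 27 per-cell features exported
from brightfield IHC analysis of xenograft sections.

Feature names are byte-exact interchange identifiers: every table reader,
profile and factor model in this package validates against these lists.
"""

from __future__ import annotations

import json

#: The 62 in-vitro features, order fixed.  Index = position + 1.
INVITRO_FEATURES: tuple[str, ...] = (
    "Nuclei Area",                      # 1
    "Nuclei Form Factor",               # 2
    "Nuclei Elongation",                # 3
    "Nuclei Compactness",               # 4
    "Nuclei Chord Ratio",               # 5
    "Nuclei Gyration Radius",           # 6
    "Nuclei Displacement",              # 7
    "Nuclei Diameter",                  # 8
    "Nuclei Perimeter",                 # 9
    "Nuclei Intensity",                 # 10
    "Nuclei Total Intensity",           # 11
    "Nuclei Intensity CV",              # 12
    "Nuclei Light Flux",                # 13
    "Nuclei Intensity SD",              # 14
    "Nuclei Major Axis",                # 15
    "Nuclei Minor Axis",                # 16
    "Nuclei Spacing (SOI)",             # 17
    "Nuclei Neighbor Count (SOI)",      # 18
    "Nuclei Spacing (MIN)",             # 19
    "Nuclei Neighbor Count (MIN)",      # 20
    "Nuclei Spacing (Gabriel)",         # 21
    "Nuclei Neighbor Count (Gabriel)",  # 22
    "Nuclei Spacing (Lune)",            # 23
    "Nuclei Neighbor Count (Lune)",     # 24
    "Nuclei Skewness",                  # 25
    "Nuclei Kurtosis",                  # 26
    "Nuclei Energy",                    # 27
    "Nuclei Entropy",                   # 28
    "Nuclei Grey Level Non Uniformity", # 29
    "Nuclei High GLRE",                 # 30
    "Nuclei Low GLRE",                  # 31
    "Nuclei Run Length Non uniformity", # 32
    "Cells Area",                       # 33
    "Cells Form Factor",                # 34
    "Cells Elongation",                 # 35
    "Cells Compactness",                # 36
    "Cells Chord Ratio",                # 37
    "Cells Gyration Radius",            # 38
    "Cells Nuc/Cell Area",              # 39
    "Cells Diameter",                   # 40
    "Cells Perimeter",                  # 41
    "Cells Intensity (Cell)",           # 42
    "Cells Intensity (Cyto)",           # 43
    "Cells Total Intensity (Cell)",     # 44
    "Cells Total Intensity (Cyto)",     # 45
    "Cells Intensity CV (Cell)",        # 46
    "Cells Intensity CV (Cyto)",        # 47
    "Cells Intensity Spreading",        # 48
    "Cells Light Flux",                 # 49
    "Cells Nuc/Cyto Intensity",         # 50
    "Cells Intensity SD (Cell)",        # 51
    "Cells Intensity SD (Cyto)",        # 52
    "Cells Major Axis",                 # 53
    "Cells Minor Axis",                 # 54
    "Cells Skewness",                   # 55
    "Cells Kurtosis",                   # 56
    "Cells Energy",                     # 57
    "Cells Entropy",                    # 58
    "Cells Grey Level Non Uniformity",  # 59
    "Cells High GLRE",                  # 60
    "Cells Low GLRE",                   # 61
    "Cells Run Length Non Uniformity",  # 62
)

#: The 27 in-vivo (brightfield IHC) per-cell features, order fixed.
INVIVO_FEATURES: tuple[str, ...] = (
    "Nucleus: Area",
    "Nucleus: Perimeter",
    "Nucleus: Circularity",
    "Nucleus: Max Caliper",
    "Nucleus: Min Caliper",
    "Nucleus: Eccentricity",
    "Nucleus: Counterstain OD Mean",
    "Nucleus: Counterstain OD Sum",
    "Nucleus: Counterstain OD SD",
    "Nucleus: Counterstain OD Max",
    "Nucleus: Counterstain OD Min",
    "Nucleus: Counterstain OD Range",
    "Cell: Area",
    "Cell: Perimeter",
    "Cell: Circularity",
    "Cell: Max Caliper",
    "Cell: Min Caliper",
    "Cell: Eccentricity",
    "Cell: Counterstain OD Mean",
    "Cell: Counterstain OD SD",
    "Cell: Counterstain OD Max",
    "Cell: Counterstain OD Min",
    "Cytoplasm: Counterstain OD Mean",
    "Cytoplasm: Counterstain OD SD",
    "Cytoplasm: Counterstain OD Max",
    "Cytoplasm: Counterstain OD Min",
    "Nucleus/Cell area ratio",
)

#: Metadata columns carried by every in-vitro feature table.
METADATA_COLUMNS: tuple[str, ...] = (
    "model_id",
    "condition_id",
    "replicate_id",
    "well_id",
    "field_id",
    "object_id",
)

#: The nine latent-factor designations used to label EFA factors.
DESIGNATIONS: tuple[str, ...] = (
    "Nuclear Size",
    "Cell Size",
    "Cell Intensity",
    "Nuclear Intensity",
    "Nuclear Spacing",
    "Nuclear Shape",
    "Cell Shape",
    "Cell Intensity (variance)",
    "Nuclear Intensity (variance)",
)

# Feature -> designation category.  One category per feature; variance /
# texture statistics of each stain go to the corresponding variance bucket.
_CATEGORY_BY_INDEX: dict[str, tuple[int, ...]] = {
    "Nuclear Size": (1, 6, 8, 9, 15, 16),
    "Nuclear Shape": (2, 3, 4, 5, 7),
    "Nuclear Intensity": (10, 11, 13),
    "Nuclear Intensity (variance)": (12, 14, 25, 26, 27, 28, 29, 30, 31, 32),
    "Nuclear Spacing": (17, 18, 19, 20, 21, 22, 23, 24),
    "Cell Size": (33, 38, 40, 41, 53, 54),
    "Cell Shape": (34, 35, 36, 37, 39),
    "Cell Intensity": (42, 43, 44, 45, 49, 50),
    "Cell Intensity (variance)": (46, 47, 48, 51, 52, 55, 56, 57, 58, 59, 60, 61, 62),
}

FEATURE_CATEGORIES: dict[str, str] = {
    INVITRO_FEATURES[i - 1]: cat
    for cat, idx in _CATEGORY_BY_INDEX.items()
    for i in idx
}

#: Default 8-feature mask for datasets acquired on the older, rectangular-image
#: microscope generation: the cell-geometry features that cannot be measured
#: there.  Exposed as configuration, not hard-coded behaviour.
DEFAULT_MASK: tuple[str, ...] = (
    "Cells Area",
    "Cells Form Factor",
    "Cells Elongation",
    "Cells Compactness",
    "Cells Chord Ratio",
    "Cells Gyration Radius",
    "Cells Diameter",
    "Cells Perimeter",
)

def _compartment(name: str) -> str:
    return "nucleus" if name.startswith("Nuclei") else "cell"


def feature_registry() -> list[dict]:
    """Machine-readable registry: index, name, compartment and family."""
    return [
        {
            "index": i + 1,
            "name": name,
            "compartment": _compartment(name),
            "family": FEATURE_CATEGORIES[name],
        }
        for i, name in enumerate(INVITRO_FEATURES)
    ]


def registry_json(indent: int = 2) -> str:
    return json.dumps(feature_registry(), indent=indent)


assert len(INVITRO_FEATURES) == 62
assert len(INVIVO_FEATURES) == 27
assert set(FEATURE_CATEGORIES) == set(INVITRO_FEATURES)
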