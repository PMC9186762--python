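"""Synthetic study data: phantom fields and factor-structured feature tables.

Two generators make every downstream stage testable without microscopy
data:

* :func:`generate_phantom_field` renders two-population fields of
  elliptical nuclei inside larger elliptical cells with Gaussian pixel
  noise and dart-throwing placement.  The default conditions emulate the
  study populations: proliferating cells are small, bright and densely
  packed; senescent cells have roughly doubled nuclear/cellular axes
  (about 4x area), dimmer nuclear stain (x0.6) and sparser packing.

* :func:`generate_feature_table` draws single-cell tables from a planted
  common-factor model X = F L' + eps, with eight latent factors mapped
  onto the canonical feature families (primary loadings 0.8, cross
  loadings 0.1, uniqueness 0.3) and a condition-dependent factor-mean
  shift, so the full profiling/EFA pipeline can be validated against a
  known ground truth.

All randomness flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import FeatureTable, SegmentedField
from .registry import FEATURE_CATEGORIES, INVITRO_FEATURES, INVIVO_FEATURES

logger = logging.getLogger(__name__)


class SpecError(ValueError):
    """A generator specification is internally inconsistent."""


# --------------------------------------------------------------------------
# phantom segmented fields
# --------------------------------------------------------------------------

@dataclass
class ConditionPhantom:
    """Per-condition rendering parameters (pixel units, arbitrary intensity)."""

    n_cells: int = 12
    nuc_axis_mean: tuple[float, float] = (9.0, 7.0)  # semi-axes (px)
    nuc_axis_sd: float = 0.8
    cell_scale: float = 2.2          # cell semi-axes = nucleus semi-axes * scale
    nuc_intensity: float = 180.0
    nuc_intensity_sd: float = 12.0   # between-object variation
    cell_intensity: float = 120.0
    cell_intensity_sd: float = 10.0
    noise_sd: float = 6.0            # per-pixel texture graininess
    min_distance: float | None = None  # default: just above max cell diameter


@dataclass
class PhantomSpec:
    conditions: dict[str, ConditionPhantom] = field(default_factory=dict)
    shape: tuple[int, int] = (512, 512)
    fields_per_well: int = 2
    wells_per_replicate: int = 2
    replicates: int = 3
    model_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            sen = ConditionPhantom(
                n_cells=5,
                nuc_axis_mean=(18.0, 14.0),
                nuc_intensity=108.0,  # x0.6 of proliferating: reduced DAPI
                cell_intensity=110.0,
            )
            self.conditions = {"proliferating": ConditionPhantom(), "senescent": sen}
        for name, c in self.conditions.items():
            if min(c.nuc_axis_mean) <= 0 or c.cell_scale <= 1:
                raise SpecError(f"condition {name!r}: axes must be positive, scale > 1")

    def condition_min_distance(self, cond: str) -> float:
        c = self.conditions[cond]
        if c.min_distance is not None:
            return c.min_distance
        # beyond max cell diameter -> no overlap possible
        return 2.0 * (max(c.nuc_axis_mean) + 4 * c.nuc_axis_sd) * c.cell_scale + 2.0


def _ellipse_mask(shape, center, axes, theta) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_phantom_field(
    spec: PhantomSpec,
    condition: str,
    rng: np.random.Generator,
    field_id: str = "F1",
    well_id: str = "W1",
    replicate_id: str = "R1",
) -> tuple[SegmentedField, pd.DataFrame]:
    """Render one field; returns the field plus a ground-truth object table."""
    c = spec.conditions[condition]
    h, w = spec.shape
    min_d = spec.condition_min_distance(condition)
    margin = min_d / 2.0 + 1.0

    centers: list[tuple[float, float]] = []
    truth = []
    attempts_per_cell = 200
    for k in range(c.n_cells):
        placed = False
        for _ in range(attempts_per_cell):
            cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_d for p in centers):
                centers.append(cand)
                placed = True
                break
        if not placed:
            logger.warning(
                "field %s/%s: placed only %d/%d objects", condition, field_id, k, c.n_cells
            )
            break

    nuc_img = np.zeros(spec.shape)
    cell_img = np.zeros(spec.shape)
    nuc_lab = np.zeros(spec.shape, dtype=np.int64)
    cell_lab = np.zeros(spec.shape, dtype=np.int64)
    for i, center in enumerate(centers, start=1):
        a = max(1.5, rng.normal(c.nuc_axis_mean[0], c.nuc_axis_sd))
        b = max(1.0, min(a, rng.normal(c.nuc_axis_mean[1], c.nuc_axis_sd)))
        theta = rng.uniform(0, np.pi)
        nuc_i = max(1.0, rng.normal(c.nuc_intensity, c.nuc_intensity_sd))
        cell_i = max(1.0, rng.normal(c.cell_intensity, c.cell_intensity_sd))
        nmask = _ellipse_mask(spec.shape, center, (a, b), theta)
        cmask = _ellipse_mask(spec.shape, center, (a * c.cell_scale, b * c.cell_scale), theta)
        nuc_lab[nmask] = i
        cell_lab[cmask] = i
        nuc_img[nmask] = nuc_i
        cell_img[cmask] = cell_i
        truth.append(
            dict(
                object_id=i, center_r=center[0], center_c=center[1],
                semi_major=a, semi_minor=b, orientation=theta,
                cell_semi_major=a * c.cell_scale, cell_semi_minor=b * c.cell_scale,
                nuc_intensity=nuc_i, cell_intensity=cell_i,
            )
        )
    if c.noise_sd > 0:
        nuc_img = np.clip(nuc_img + rng.normal(0, c.noise_sd, spec.shape), 0, None)
        cell_img = np.clip(cell_img + rng.normal(0, c.noise_sd, spec.shape), 0, None)

    fieldobj = SegmentedField(
        nuc_image=nuc_img, cell_image=cell_img,
        nuc_labels=nuc_lab, cell_labels=cell_lab,
        field_id=field_id, well_id=well_id, replicate_id=replicate_id,
        condition_id=condition, model_id=spec.model_id,
    )
    return fieldobj, pd.DataFrame(truth)


def generate_phantom_study(spec: PhantomSpec):
    """Yield (field, truth) over every replicate/well/field/condition."""
    rng = np.random.default_rng(spec.seed)
    for r in range(1, spec.replicates + 1):
        for wl in range(1, spec.wells_per_replicate + 1):
            for f in range(1, spec.fields_per_well + 1):
                for cond in spec.conditions:
                    yield generate_phantom_field(
                        spec, cond, rng,
                        field_id=f"F{f}", well_id=f"{cond[:3]}_W{wl}", replicate_id=f"R{r}",
                    )


# --------------------------------------------------------------------------
# factor-structured feature tables
# --------------------------------------------------------------------------

#: Default block design: the eight latent factors planted in synthetic
#: tables, mirroring the designations recovered from real data.  Features
#: in the ninth family (Cell Intensity (variance)) carry no primary
#: loading, i.e. they behave as near-unique noise features.
DEFAULT_BLOCKS: tuple[str, ...] = (
    "Nuclear Size",
    "Cell Size",
    "Cell Intensity",
    "Nuclear Intensity",
    "Nuclear Spacing",
    "Nuclear Shape",
    "Cell Shape",
    "Nuclear Intensity (variance)",
)

#: Condition effect: shift of each factor mean in the senescent condition,
#: in factor-score SD units.  Senescent cells are larger (nucleus and
#: cell), sparser, dimmer in nuclear stain and more irregular in texture.
DEFAULT_EFFECTS: dict[str, float] = {
    "Nuclear Size": 2.0,
    "Cell Size": 2.0,
    "Cell Intensity": -1.0,
    "Nuclear Intensity": -1.5,
    "Nuclear Spacing": 1.5,
    "Nuclear Shape": -0.8,
    "Cell Shape": -1.2,
    "Nuclear Intensity (variance)": 1.0,
}


def default_loading_matrix(
    blocks: tuple[str, ...] = DEFAULT_BLOCKS,
    primary: float = 0.8,
    cross: float = 0.1,
) -> pd.DataFrame:
    """62 x k loading matrix: block structure over the feature families."""
    lam = pd.DataFrame(cross, index=list(INVITRO_FEATURES), columns=list(blocks))
    for name in INVITRO_FEATURES:
        cat = FEATURE_CATEGORIES[name]
        if cat in blocks:
            lam.loc[name, cat] = primary
    return lam


@dataclass
class FactorTableSpec:
    loadings: pd.DataFrame | None = None        # 62 x k; default block design
    factor_corr: np.ndarray | None = None       # k x k Phi; default identity
    effects: dict[str, float] | None = None     # senescent factor-mean shifts
    uniqueness: float = 0.3
    n_cells: int = 1700                         # per condition per replicate
    replicates: int = 3
    conditions: tuple[str, str] = ("proliferating", "senescent")
    model_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loadings is None:
            self.loadings = default_loading_matrix()
        if self.effects is None:
            self.effects = dict(DEFAULT_EFFECTS)
        k = self.loadings.shape[1]
        if self.factor_corr is None:
            self.factor_corr = np.eye(k)
        self.factor_corr = np.asarray(self.factor_corr, float)
        if self.factor_corr.shape != (k, k):
            raise SpecError("factor correlation matrix has wrong shape")
        if self.uniqueness <= 0:
            raise SpecError("uniqueness must be positive")
        sigma = self.implied_covariance()
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise SpecError("implied covariance is not positive definite")

    def implied_covariance(self) -> np.ndarray:
        lam = self.loadings.to_numpy()
        return lam @ self.factor_corr @ lam.T + self.uniqueness * np.eye(lam.shape[0])


# per-feature raw-data affine transform so generated tables resemble raw
# measurements (different scales per feature) rather than scored data
def _raw_affine(n_features: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(62)
    scale = 10.0 ** rng.uniform(-1, 3, n_features)
    offset = rng.uniform(0, 500, n_features)
    return scale, offset


def generate_feature_table(spec: FactorTableSpec) -> FeatureTable:
    """Draw a planted-factor single-cell table with study metadata."""
    lam = spec.loadings.to_numpy()
    p, k = lam.shape
    blocks = list(spec.loadings.columns)
    effect_vec = np.array([spec.effects.get(b, 0.0) for b in blocks])
    chol = np.linalg.cholesky(spec.factor_corr)
    scale, offset = _raw_affine(p)
    rng = np.random.default_rng(spec.seed)

    frames = []
    for r in range(1, spec.replicates + 1):
        for ci, cond in enumerate(spec.conditions):
            shift = effect_vec if ci == 1 else np.zeros(k)
            f = rng.standard_normal((spec.n_cells, k)) @ chol.T + shift
            eps = rng.standard_normal((spec.n_cells, p)) * np.sqrt(spec.uniqueness)
            x = (f @ lam.T + eps) * scale + offset
            df = pd.DataFrame(x, columns=list(spec.loadings.index))
            df.insert(0, "model_id", spec.model_id)
            df.insert(1, "condition_id", cond)
            df.insert(2, "replicate_id", f"R{r}")
            df.insert(3, "well_id", f"{cond[:3]}_W1")
            df.insert(4, "field_id", "F1")
            df.insert(5, "object_id", [f"{cond[:3]}_{r}_{i}" for i in range(spec.n_cells)])
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return FeatureTable(out, schema=tuple(spec.loadings.index))


# --------------------------------------------------------------------------
# in-vivo per-cell tables
# --------------------------------------------------------------------------

@dataclass
class InVivoSpec:
    """Planted brightfield-IHC study: p21-positive cells have enlarged nuclei.

    Each treatment group holds ``n_samples`` tumours; palbociclib raises the
    fraction of p21-positive cells, and positivity shifts the morphology
    features by ``effect`` (in SD units) with the sign pattern of
    ``feature_signs`` (default: +1 on sizes/calipers, 0 elsewhere).
    """

    n_samples: int = 3
    n_cells: int = 400                       # per sample
    positive_fraction: dict[str, float] | None = None
    od_scale_negative: float = 0.08          # mean OD of p21-negative nuclei
    od_scale_positive: float = 0.45
    effect: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positive_fraction is None:
            self.positive_fraction = {"control": 0.10, "palbociclib": 0.45}


_SIZE_FEATURES = (
    "Nucleus: Area", "Nucleus: Perimeter", "Nucleus: Max Caliper",
    "Nucleus: Min Caliper", "Cell: Area", "Cell: Perimeter",
    "Cell: Max Caliper", "Cell: Min Caliper",
)


def generate_invivo_table(spec: InVivoSpec) -> pd.DataFrame:
    """Per-cell in-vivo table: 27 features + p21 DAB mean OD + metadata."""
    rng = np.random.default_rng(spec.seed)
    p = len(INVIVO_FEATURES)
    signs = np.array([1.0 if f in _SIZE_FEATURES else 0.0 for f in INVIVO_FEATURES])
    scale, offset = _raw_affine(p)
    frames = []
    for treatment, frac in spec.positive_fraction.items():
        for s in range(1, spec.n_samples + 1):
            n = spec.n_cells
            positive = rng.random(n) < frac
            base = rng.standard_normal((n, p))
            base += np.outer(positive.astype(float) * spec.effect, signs)
            x = base * scale + offset
            od = np.where(
                positive,
                rng.gamma(6.0, spec.od_scale_positive / 6.0, n),
                rng.gamma(4.0, spec.od_scale_negative / 4.0, n),
            )
            df = pd.DataFrame(x, columns=list(INVIVO_FEATURES))
            df.insert(0, "sample_id", f"{treatment[:4]}_S{s}")
            df.insert(1, "treatment", treatment)
            df["Nucleus: p21 OD mean"] = od
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
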