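import numpy as np
import pandas as pd
import pytest

from samp.io_tables import FeatureTable
from samp.profiling import standard_scores
from samp.registry import INVITRO_FEATURES, METADATA_COLUMNS
from samp.synthetic import FactorTableSpec, generate_feature_table


def build_table(
    cells_per_group: dict[tuple[str, str], int] | None = None,
    overrides: dict[str, dict[tuple[str, str], list[float]]] | None = None,
    wells: int = 1,
    seed: int = 0,
) -> FeatureTable:
    """Small valid FeatureTable: background noise in all 62 features.

    *cells_per_group* maps (condition, replicate) -> n cells; *overrides*
    maps feature name -> {(condition, replicate): explicit cell values}.
    """
    rng = np.random.default_rng(seed)
    cells_per_group = cells_per_group or {
        (c, r) for c in ("ctrl", "sen") for r in ("R1", "R2", "R3")
    }
    if not isinstance(cells_per_group, dict):
        cells_per_group = {g: 4 for g in cells_per_group}
    rows = []
    for (cond, rep), n in cells_per_group.items():
        for i in range(n):
            row = {
                "model_id": "toy",
                "condition_id": cond,
                "replicate_id": rep,
                "well_id": f"W{1 + i % wells}",
                "field_id": "F1",
                "object_id": f"{cond}_{rep}_{i}",
            }
            row.update(
                {f: v for f, v in zip(INVITRO_FEATURES, rng.normal(10, 2, 62))}
            )
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(INVITRO_FEATURES))
    for feat, groups in (overrides or {}).items():
        for (cond, rep), values in groups.items():
            idx = df.index[(df.condition_id == cond) & (df.replicate_id == rep)]
            df.loc[idx, feat] = np.asarray(values, float)
    return FeatureTable(df)


@pytest.fixture
def table_factory():
    return build_table


@pytest.fixture(scope="session")
def default_factor_table() -> FeatureTable:
    """The default planted 8-factor study table (seeded)."""
    return generate_feature_table(FactorTableSpec(seed=1))


@pytest.fixture(scope="session")
def default_scores(default_factor_table) -> pd.DataFrame:
    return standard_scores(default_factor_table)
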