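import numpy as np
import pandas as pd
import pytest

from samp.io_tables import StudyDesign
from samp.profiling import (
    ProfileMatrix,
    aggregate,
    cluster_profiles,
    mask_features,
    median_profile,
    significant_features,
    standard_scores,
    zscore_profile,
)
from samp.registry import DEFAULT_MASK, INVITRO_FEATURES

from conftest import build_table
from oracles import ward_d2_first_merge, ward_d2_heights

DESIGN = StudyDesign("toy", "ctrl", "sen", ("R1", "R2", "R3"))


def test_aggregation_hierarchy_arithmetic():
    """Wells {1,3} and {5}: well means 2 and 5, experiment mean 3.5."""
    table = build_table(
        {("ctrl", "R1"): 3, ("sen", "R1"): 3, ("ctrl", "R2"): 3, ("sen", "R2"): 3},
        overrides={"Nuclei Area": {("ctrl", "R1"): [1, 3, 5]}},
        wells=2,  # cells alternate W1, W2, W1 -> W1 holds {1,5}, W2 holds {3}
    )
    levels = aggregate(table, DESIGN)
    w = levels.well_means.loc[("ctrl", "R1")]["Nuclei Area"]
    assert sorted(w) == [3.0, 3.0]
    # rebuild with explicit wells {1,3},{5}
    df = table.df.copy()
    idx = df.index[(df.condition_id == "ctrl") & (df.replicate_id == "R1")]
    df.loc[idx, "Nuclei Area"] = [1.0, 3.0, 5.0]
    df.loc[idx, "well_id"] = ["W1", "W1", "W2"]
    from samp.io_tables import FeatureTable

    levels = aggregate(FeatureTable(df), DESIGN)
    wells = levels.well_means.loc[("ctrl", "R1")]["Nuclei Area"]
    assert sorted(wells) == [2.0, 5.0]
    assert levels.experiment_means.loc[("ctrl", "R1"), "Nuclei Area"] == 3.5


def test_single_replicate_condition_mean_equals_experiment_mean():
    table = build_table({("ctrl", "R1"): 4, ("sen", "R1"): 4})
    levels = aggregate(table)
    pd.testing.assert_series_equal(
        levels.condition_means.loc["ctrl"],
        levels.experiment_means.loc[("ctrl", "R1")],
        check_names=False,
    )


def test_aggregation_matches_bruteforce_groupby():
    table = build_table({(c, r): 5 for c in ("ctrl", "sen") for r in ("R1", "R2")}, wells=2)
    levels = aggregate(table)
    df = table.df
    for cond in ("ctrl", "sen"):
        expt = []
        for rep in ("R1", "R2"):
            wells = []
            sub = df[(df.condition_id == cond) & (df.replicate_id == rep)]
            for well in sub.well_id.unique():
                wells.append(sub[sub.well_id == well]["Cells Area"].mean())
            expt.append(np.mean(wells))
        assert levels.condition_means.loc[cond, "Cells Area"] == pytest.approx(
            np.mean(expt)
        )


def test_missing_condition_raises_design_error():
    table = build_table({("ctrl", "R1"): 3})
    with pytest.raises(ValueError, match="sen"):
        aggregate(table, DESIGN)


def _z_table(ctrl_means=(9.0, 10.0, 11.0), sen_mean=12.0, feature="Nuclei Area"):
    groups = {(c, r): 2 for c in ("ctrl", "sen") for r in ("R1", "R2", "R3")}
    overrides = {
        feature: {
            **{("ctrl", f"R{i+1}"): [m, m] for i, m in enumerate(ctrl_means)},
            **{("sen", f"R{i+1}"): [sen_mean, sen_mean] for i in range(3)},
        }
    }
    return build_table(groups, overrides)


def test_zscore_textbook_example_flags_significance():
    """Control experiment means {9,10,11} (SD 1), senescent mean 12 -> Z=2."""
    table = _z_table()
    prof = zscore_profile(aggregate(table, DESIGN), DESIGN)
    assert list(prof.data.index) == ["sen"]
    assert prof.data.loc["sen", "Nuclei Area"] == pytest.approx(2.0)
    hits, n = significant_features(prof)["sen"]
    assert "Nuclei Area" in hits


def test_zscore_zero_when_conditions_equal_and_sign_convention():
    prof = zscore_profile(aggregate(_z_table(sen_mean=10.0), DESIGN), DESIGN)
    assert prof.data.loc["sen", "Nuclei Area"] == pytest.approx(0.0)
    below = zscore_profile(aggregate(_z_table(sen_mean=7.0), DESIGN), DESIGN)
    assert below.data.loc["sen", "Nuclei Area"] == pytest.approx(-3.0)


def test_zscore_invariant_to_affine_rescaling():
    table = build_table({(c, r): 4 for c in ("ctrl", "sen") for r in ("R1", "R2", "R3")})
    prof1 = zscore_profile(aggregate(table, DESIGN), DESIGN)
    df = table.df.copy()
    df[list(INVITRO_FEATURES)] = df[list(INVITRO_FEATURES)] * 37.5 + 11.0
    from samp.io_tables import FeatureTable

    prof2 = zscore_profile(aggregate(FeatureTable(df), DESIGN), DESIGN)
    np.testing.assert_allclose(
        prof1.data.to_numpy(), prof2.data.to_numpy(), rtol=1e-9, atol=1e-9
    )


def test_zscore_zero_control_variance_yields_missing():
    table = _z_table(ctrl_means=(10.0, 10.0, 10.0))
    with pytest.warns(UserWarning, match="zero control SD"):
        prof = zscore_profile(aggregate(table, DESIGN), DESIGN)
    assert np.isnan(prof.data.loc["sen", "Nuclei Area"])
    hits, _ = significant_features(prof)["sen"]
    assert "Nuclei Area" not in hits


def test_standard_scores_pooled_mean_zero_sd_one_per_replicate():
    table = build_table({(c, r): 20 for c in ("ctrl", "sen") for r in ("R1", "R2")}, seed=9)
    scores = standard_scores(table)
    for _, grp in scores.groupby("replicate_id"):
        m = grp[list(INVITRO_FEATURES)].mean()
        sd = grp[list(INVITRO_FEATURES)].std(ddof=1)
        assert np.abs(m.to_numpy()).max() < 1e-9
        assert np.abs(sd.to_numpy() - 1).max() < 1e-9


def test_standard_scores_match_bruteforce_per_replicate():
    table = build_table({(c, r): 6 for c in ("ctrl", "sen") for r in ("R1", "R2")}, seed=2)
    scores = standard_scores(table)
    df = table.df
    feat = "Cells Entropy"
    for rep in ("R1", "R2"):
        sub = df[df.replicate_id == rep][feat]
        expected = (sub - sub.mean()) / sub.std(ddof=1)
        got = scores[scores.replicate_id == rep][feat]
        np.testing.assert_allclose(got.to_numpy(), expected.to_numpy())


def test_median_profile_exact_middle_and_oracle():
    table = build_table({("ctrl", "R1"): 5, ("sen", "R1"): 5}, seed=1)
    scores = standard_scores(table)
    prof = median_profile(scores, list(INVITRO_FEATURES))
    for cond in ("ctrl", "sen"):
        sub = scores[scores.condition_id == cond]["Nuclei Area"].to_numpy()
        assert prof.data.loc[cond, "Nuclei Area"] == sorted(sub)[2]  # odd count


def test_significance_boundary_is_strict_and_monotone():
    data = pd.DataFrame(
        {"a": [1.96], "b": [-2.5], "c": [1.97], "d": [0.0]}, index=["sen"]
    )
    prof = ProfileMatrix(data, kind="zscore")
    hits, n = significant_features(prof, threshold=1.96)["sen"]
    assert set(hits) == {"b", "c"}  # 1.96 exactly is NOT significant
    counts = [
        significant_features(prof, threshold=t)["sen"][1] for t in (0.5, 1.96, 2.6)
    ]
    assert counts == sorted(counts, reverse=True)


def test_masking_eight_features_reduces_denominator_to_54():
    z = pd.DataFrame(
        [np.linspace(-3, 3, 62)], index=["sen"], columns=list(INVITRO_FEATURES)
    )
    prof = mask_features(ProfileMatrix(z, kind="zscore"), list(DEFAULT_MASK))
    assert (prof.data[list(DEFAULT_MASK)] == 0).all().all()
    assert len(prof.mask) == 8
    hits, n = significant_features(prof)["sen"]
    assert not set(hits) & set(DEFAULT_MASK)
    assert len(prof.data.columns) - len(prof.mask) == 54


def test_masking_nothing_is_identity():
    z = pd.DataFrame([np.ones(62)], index=["sen"], columns=list(INVITRO_FEATURES))
    prof = mask_features(ProfileMatrix(z, kind="zscore"), [])
    pd.testing.assert_frame_equal(prof.data, z)
    with pytest.raises(KeyError):
        mask_features(prof, ["No Such Feature"])


def test_clustering_first_merge_and_duplicate_rows():
    rows = pd.DataFrame(
        [[0, 0], [0, 0.1], [5, 5]], index=["a", "b", "c"], columns=["f1", "f2"]
    )
    order, link = cluster_profiles(ProfileMatrix(rows, kind="standard"))
    assert sorted(link[0, :2]) == [0, 1]  # near rows merge first
    assert set(order[:2]) == {"a", "b"} or set(order[1:]) == {"a", "b"}
    assert ward_d2_first_merge(rows.to_numpy()) == (0, 1)

    dup = pd.DataFrame([[1, 2], [1, 2], [9, 9]], index=list("xyz"), columns=["f1", "f2"])
    _, link = cluster_profiles(ProfileMatrix(dup, kind="standard"))
    assert link[0, 2] == pytest.approx(0.0)


@pytest.mark.parametrize("seed", range(20))
def test_ward_d2_heights_match_lance_williams_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(rng.integers(4, 10), 5))
    prof = ProfileMatrix(
        pd.DataFrame(x, index=[f"r{i}" for i in range(len(x))]), kind="standard"
    )
    _, link = cluster_profiles(prof)
    np.testing.assert_allclose(link[:, 2], ward_d2_heights(x), rtol=1e-8)


def test_planted_condition_separation_in_top_split(default_factor_table):
    """Profiles of the two conditions across replicates: the dendrogram's top
    split separates senescent from proliferating rows."""
    table = default_factor_table
    scores = standard_scores(table)
    prof = median_profile(
        scores, list(table.schema), by=["condition_id", "replicate_id"]
    )
    order, link = cluster_profiles(prof)
    conds = [idx[0] for idx in order]
    # contiguous blocks of each condition <=> top split separates them
    changes = sum(a != b for a, b in zip(conds, conds[1:]))
    assert changes == 1


def test_profile_matrix_kind_validated():
    with pytest.raises(ValueError):
        ProfileMatrix(pd.DataFrame(), kind="other")
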