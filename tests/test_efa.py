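import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from samp.efa import (
    EFAModel,
    adjust_k,
    designate_factors,
    factor_profile,
    factor_scores,
    fit_efa,
    ml_factor_fit,
    oblimin_rotate,
    representative_profile,
    scree,
)
from samp.profiling import standard_scores
from samp.registry import FEATURE_CATEGORIES, INVITRO_FEATURES
from samp.synthetic import FactorTableSpec, default_loading_matrix, generate_feature_table

FEATS = list(INVITRO_FEATURES)


def _frame(x: np.ndarray, features=None) -> pd.DataFrame:
    features = features or FEATS[: x.shape[1]]
    df = pd.DataFrame(x, columns=features)
    df.insert(0, "condition_id", "c")
    df.insert(1, "replicate_id", "R1")
    return df


def _planted(n, lam, phi=None, seed=0, shift=None):
    rng = np.random.default_rng(seed)
    p, k = lam.shape
    phi = np.eye(k) if phi is None else phi
    f = rng.standard_normal((n, k)) @ np.linalg.cholesky(phi).T
    if shift is not None:
        f += shift
    psi = np.clip(1 - np.diag(lam @ phi @ lam.T), 0.05, None)
    x = f @ lam.T + rng.standard_normal((n, p)) * np.sqrt(psi)
    return x, f


def test_exact_identity_correlation_gives_kaiser_zero():
    """Columns orthogonalized exactly: every eigenvalue is 1, strict > 1
    retains nothing."""
    from scipy.linalg import hadamard

    x = hadamard(16)[:, 1:11].astype(float)  # exactly orthogonal +-1 columns
    res = scree(_frame(x), FEATS[:10])
    np.testing.assert_allclose(res.eigenvalues, 1.0, atol=1e-12)
    assert res.kaiser_count == 0


def test_one_strong_pair_raises_kaiser_to_exactly_one():
    """Independent features plus one strongly correlated pair: the pair's
    eigenvalue 1+rho crosses 1, everything else stays at or below 1."""
    from scipy.linalg import hadamard

    x = hadamard(16)[:, 1:11].astype(float)
    x[:, 1] = 0.8 * x[:, 0] + 0.6 * x[:, 1]  # corr(f0, f1) = 0.8 exactly
    res = scree(_frame(x), FEATS[:10])
    assert res.kaiser_count == 1
    assert res.eigenvalues[0] == pytest.approx(1.8)


def test_two_block_data_gives_kaiser_two():
    lam = np.zeros((10, 2))
    lam[:5, 0] = 0.85
    lam[5:, 1] = 0.85
    x, _ = _planted(2000, lam, seed=1)
    assert scree(_frame(x), FEATS[:10]).kaiser_count == 2


def test_scree_requires_more_cells_than_features():
    with pytest.raises(ValueError):
        scree(_frame(np.zeros((5, 10))), FEATS[:10])


@pytest.mark.parametrize("k", [1, 2])
def test_ml_fit_matches_r_factanal_uniquenesses(k):
    """Independent oracle: R's stats::factanal on the same sample correlation
    recovers the same ML uniquenesses."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    lam = np.zeros((6, 2))
    lam[:3, 0] = [0.8, 0.7, 0.6]
    lam[3:, 1] = [0.75, 0.65, 0.8]
    x, _ = _planted(500, lam, seed=0)
    r = np.corrcoef(x, rowvar=False)
    _, psi = ml_factor_fit(r, k)
    np.savetxt("/tmp/_samp_efa_x.csv", x, delimiter=",")
    script = (
        'x <- as.matrix(read.csv("/tmp/_samp_efa_x.csv", header=FALSE));'
        f"f <- factanal(x, factors={k}, rotation='none');"
        'cat(f$uniquenesses, sep=",")'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    r_psi = np.array([float(v) for v in out.stdout.strip().split(",")])
    np.testing.assert_allclose(psi, r_psi, atol=1e-3)


def test_planted_two_factor_pattern_recovered():
    lam = np.zeros((10, 2))
    lam[:5, 0] = 0.8
    lam[5:, 1] = 0.8
    x, _ = _planted(5000, lam, seed=2)
    model = fit_efa(_frame(x), FEATS[:10], 2)
    got = np.abs(model.loadings.to_numpy())
    # match columns by where the big loadings sit
    order = [0, 1] if got[:5, 0].mean() > got[:5, 1].mean() else [1, 0]
    assert np.abs(got[:, order] - np.abs(lam)).max() < 0.1


def test_rotation_preserves_communalities():
    lam = np.zeros((8, 2))
    lam[:4, 0] = 0.75
    lam[4:, 1] = 0.7
    lam[0, 1] = 0.3
    x, _ = _planted(3000, lam, seed=3)
    r = np.corrcoef(x, rowvar=False)
    lam0, _ = ml_factor_fit(r, 2)
    rot, phi = oblimin_rotate(lam0)
    h_before = np.diag(lam0 @ lam0.T)
    h_after = np.diag(rot @ phi @ rot.T)
    np.testing.assert_allclose(h_before, h_after, atol=1e-6)


def test_single_factor_model_has_unit_phi():
    lam = np.full((6, 1), 0.8)
    x, _ = _planted(1000, lam, seed=4)
    model = fit_efa(_frame(x), FEATS[:6], 1)
    np.testing.assert_allclose(model.phi, [[1.0]])


def _toy_model(loadings: dict[str, list[float]]) -> EFAModel:
    feats = list(loadings)
    lam = pd.DataFrame(
        np.array(list(loadings.values())), index=feats,
        columns=[f"F{i+1}" for i in range(len(next(iter(loadings.values()))))],
    )
    k = lam.shape[1]
    return EFAModel(
        k=k, loadings=lam, phi=np.eye(k),
        psi=pd.Series(0.5, index=feats),
        corr=pd.DataFrame(np.eye(len(feats)), index=feats, columns=feats),
    )


def test_designation_by_majority_and_unclassified():
    model = _toy_model(
        {
            "Nuclei Area": [0.9, 0.0],
            "Nuclei Diameter": [0.8, 0.0],
            "Nuclei Perimeter": [0.7, 0.0],
            "Cells Entropy": [0.0, 0.2],  # below threshold everywhere on F2
        }
    )
    designate_factors(model)
    assert model.designations == ["Nuclear Size", "Unclassified"]


def test_designation_majority_beats_minority_and_tie_uses_loading_sum():
    model = _toy_model(
        {
            "Nuclei Area": [0.9],
            "Nuclei Diameter": [0.6],
            "Cells Area": [0.7],
        }
    )
    designate_factors(model)
    assert model.designations == ["Nuclear Size"]  # 2-vs-1 majority
    tie = _toy_model({"Nuclei Area": [0.6], "Cells Area": [0.9]})
    designate_factors(tie)
    assert tie.designations == ["Cell Size"]  # tie broken by |loading| sum


def _block_frame(n=3000, blocks=("Nuclear Size", "Cell Size"), seed=5):
    lam_df = default_loading_matrix(blocks=blocks, primary=0.8, cross=0.0)
    feats = [f for f in INVITRO_FEATURES if FEATURE_CATEGORIES[f] in blocks]
    lam_df = lam_df.loc[feats]
    x, _ = _planted(n, lam_df.to_numpy(), seed=seed)
    return _frame(x, feats), feats


def test_adjust_k_fixed_point_on_clean_two_block_data():
    frame, feats = _block_frame()
    model = adjust_k(frame, feats, initial_k=2)
    assert model.k == 2
    assert model.history[-1][1] == "converged"
    assert set(model.designations) == {"Nuclear Size", "Cell Size"}


def test_adjust_k_increments_on_underfactored_start():
    """One factor forced onto two planted families is under-factored."""
    frame, feats = _block_frame()
    model = adjust_k(frame, feats, initial_k=1)
    assert model.k == 2


def test_adjust_k_decrements_on_overfactored_start():
    frame, feats = _block_frame()
    model = adjust_k(frame, feats, initial_k=4)
    assert model.k == 2
    assert any(reason == "over-factored" for _, reason in model.history)


def test_adjust_k_manual_override():
    frame, feats = _block_frame(n=1500)
    model = adjust_k(frame, feats, override_k=3)
    assert model.k == 3


def test_factor_scores_linear_and_recover_planted_factor():
    lam = np.full((8, 1), 0.9)
    x, f = _planted(3000, lam, seed=6)
    frame = _frame(x, FEATS[:8])
    model = fit_efa(frame, FEATS[:8], 1)
    fs = factor_scores(model, frame)
    col = model.loadings.columns[0]
    corr = np.corrcoef(fs[col], f[:, 0])[0, 1]
    assert abs(corr) > 0.95
    # a zero standard-score row maps to a zero factor score
    zero = frame.iloc[:1].copy()
    zero[FEATS[:8]] = 0.0
    assert factor_scores(model, zero)[col].iloc[0] == pytest.approx(0.0)


def test_regression_score_covariance_near_phi(default_scores):
    model = designate_factors(fit_efa(default_scores, FEATS, 8))
    fs = factor_scores(model, default_scores)
    cols = model.designations
    cov = np.cov(fs[cols].to_numpy(), rowvar=False)
    # regression scores shrink toward zero: diagonal in (0.5, 1.05]
    assert ((np.diag(cov) > 0.5) & (np.diag(cov) < 1.05)).all()


def test_full_pipeline_recovers_eight_designations(default_scores):
    """Kaiser + iterative adjustment on the default planted table returns
    k=8 with the eight planted designations and condition-separating signs."""
    res = scree(default_scores, FEATS)
    model = adjust_k(default_scores, FEATS, initial_k=res.kaiser_count)
    assert model.k == 8
    from samp.synthetic import DEFAULT_BLOCKS, DEFAULT_EFFECTS

    assert set(model.designations) == set(DEFAULT_BLOCKS)
    prof = factor_profile(model, default_scores)
    for label in model.designations:
        diff = prof.data.loc["senescent", label] - prof.data.loc["proliferating", label]
        assert np.sign(diff) == np.sign(DEFAULT_EFFECTS[label])


def test_representative_profile_picks_anchor_features(default_scores):
    model = designate_factors(fit_efa(default_scores, FEATS, 8))
    prof = representative_profile(model, default_scores)
    assert prof.data.shape == (2, 8)
    picks = dict(zip(prof.data.columns, prof.data.columns))
    for label, members, col in zip(
        model.designations, model.memberships, model.loadings.columns
    ):
        if label == "Unclassified":
            continue
        best = max(members, key=lambda f: abs(model.loadings.loc[f, col]))
        assert FEATURE_CATEGORIES[best] == label
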