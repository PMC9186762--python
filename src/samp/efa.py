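"""Iterative exploratory factor analysis of standard-score profiles.

The procedure mirrors classical EFA practice for high-content data:

1. **Scree / Kaiser**: eigenvalues of the Pearson correlation matrix of
   per-cell standard scores; factors with eigenvalue strictly greater
   than 1 are retained as the initial count.
2. **Extraction**: maximum-likelihood common-factor fit.  The profile
   likelihood is optimized over the uniquenesses psi; for fixed psi the
   loadings follow from the eigen-decomposition of
   ``diag(psi)^-1/2 R diag(psi)^-1/2`` (Joreskog).  Heywood cases are
   clamped at psi >= 0.005.
3. **Rotation**: Oblimin with gamma = 0 (quartimin), an oblique rotation
   allowing correlated factors, via the gradient-projection algorithm.
   Column signs are fixed so each factor's largest-|loading| entry is
   positive; columns are ordered by explained sum of squares.
4. **Designation**: each factor is labelled by the majority feature
   family among its members (pattern |loading| >= 0.5); ties break on
   summed |loading|, empty memberships are "Unclassified".
5. **Adjustment**: the factor count is revised iteratively — a factor
   with fewer than two members signals over-factoring (decrement k), a
   factor mixing two or more features from each of two or more families
   signals under-factoring (increment k) — until a fixed point, with
   oscillations resolved toward the smaller count.
6. **Scores**: Thompson's regression method, ``W = R^-1 (Lambda Phi)``,
   applied to the standard scores; condition medians of the factor
   scores form the factor profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize

from .profiling import ProfileMatrix
from .registry import FEATURE_CATEGORIES

logger = logging.getLogger(__name__)

LOADING_THRESHOLD = 0.5
PSI_FLOOR = 0.005


@dataclass
class ScreeResult:
    eigenvalues: np.ndarray  # descending
    kaiser_count: int        # strict eigenvalue > 1


@dataclass
class EFAModel:
    k: int
    loadings: pd.DataFrame          # pattern matrix, p x k
    phi: np.ndarray                 # factor correlation, k x k
    psi: pd.Series                  # uniquenesses
    corr: pd.DataFrame              # fitted feature correlation matrix (input R)
    threshold: float = LOADING_THRESHOLD
    designations: list[str] | None = None
    history: list = dc_field(default_factory=list)

    @property
    def memberships(self) -> list[list[str]]:
        """Per factor, the features whose pattern |loading| meets the threshold."""
        return [
            list(self.loadings.index[self.loadings[c].abs() >= self.threshold])
            for c in self.loadings.columns
        ]

    @property
    def communalities(self) -> pd.Series:
        lam = self.loadings.to_numpy()
        return pd.Series(np.diag(lam @ self.phi @ lam.T), index=self.loadings.index)


def _feature_matrix(scores: pd.DataFrame, features: list[str]) -> np.ndarray:
    x = scores[features].to_numpy(float)
    if np.isnan(x).any():
        warnings.warn("NaN standard scores treated as 0 (the pooled mean)", stacklevel=3)
        x = np.nan_to_num(x)
    return x


def scree(scores: pd.DataFrame, features: list[str]) -> ScreeResult:
    """Eigen-decomposition of the feature correlation matrix, Kaiser count."""
    x = _feature_matrix(scores, features)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more cells than features")
    r = np.corrcoef(x, rowvar=False)
    vals = np.linalg.eigvalsh(r)[::-1]
    if vals.min() < 1e-10:
        warnings.warn("near-singular correlation matrix (eigenvalue ~ 0)", stacklevel=2)
    return ScreeResult(eigenvalues=vals, kaiser_count=int((vals > 1.0).sum()))


# ---------------------------------------------------------------- ML fit

def _ml_loadings(psi: np.ndarray, r: np.ndarray, k: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    sstar = r * np.outer(sc, sc)
    vals, vecs = np.linalg.eigh(sstar)
    vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    lam = vecs * np.sqrt(np.maximum(vals - 1.0, 0.0))
    return lam / sc[:, None]


def _ml_objective(logit_free: None, psi: np.ndarray, r: np.ndarray, k: int):
    sc = 1.0 / np.sqrt(psi)
    sstar = r * np.outer(sc, sc)
    vals = np.linalg.eigvalsh(sstar)[::-1]
    tail = vals[k:]
    f = float(np.sum(tail - np.log(tail) - 1.0))
    lam = _ml_loadings(psi, r, k)
    grad = np.diag(lam @ lam.T + np.diag(psi) - r) / psi**2
    return f, grad


def ml_factor_fit(r: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Unrotated ML loadings and uniquenesses for correlation matrix *r*."""
    p = r.shape[0]
    smc = 1.0 - 1.0 / np.diag(np.linalg.pinv(r))
    start = np.clip(1.0 - smc, 0.05, 1.0)
    res = optimize.minimize(
        lambda ps: _ml_objective(None, ps, r, k),
        start,
        jac=True,
        method="L-BFGS-B",
        bounds=[(PSI_FLOOR, 1.0)] * p,
        options={"maxiter": 1000},
    )
    psi = res.x
    if np.any(psi <= PSI_FLOOR + 1e-9):
        warnings.warn("Heywood case: uniqueness clamped at 0.005", stacklevel=3)
    return _ml_loadings(psi, r, k), psi


# ------------------------------------------------------- quartimin rotation

def _quartimin(lam: np.ndarray) -> tuple[float, np.ndarray]:
    l2 = lam**2
    k = lam.shape[1]
    n = np.ones((k, k)) - np.eye(k)
    f = float((l2 * (l2 @ n)).sum() / 4.0)
    gq = lam * (l2 @ n)
    return f, gq


def oblimin_rotate(
    a: np.ndarray, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique quartimin rotation by gradient projection.

    Returns the rotated pattern matrix and the factor correlation matrix.
    Deterministic: always started from the identity rotation.
    """
    k = a.shape[1]
    if k == 1:
        return a.copy(), np.eye(1)
    t = np.eye(k)
    tinv = np.linalg.inv(t)
    lam = a @ tinv.T
    f, gq = _quartimin(lam)
    g = -(lam.T @ gq @ tinv).T
    al = 1.0
    for _ in range(max_iter):
        gp = g - t * np.sum(t * g, axis=0)
        s = np.sqrt((gp**2).sum())
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            x = t - al * gp
            x = x / np.sqrt((x**2).sum(axis=0))
            xinv = np.linalg.inv(x)
            lam_t = a @ xinv.T
            ft, gq = _quartimin(lam_t)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        t, f, lam = x, ft, lam_t
        g = -(lam.T @ gq @ np.linalg.inv(t)).T
    phi = t.T @ t
    return lam, phi


def _canonical_order(lam: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix column signs (largest |loading| positive) and order by SS loadings."""
    lam = lam.copy()
    phi = phi.copy()
    for j in range(lam.shape[1]):
        if lam[np.abs(lam[:, j]).argmax(), j] < 0:
            lam[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    order = np.argsort(-(lam**2).sum(axis=0), kind="stable")
    return lam[:, order], phi[np.ix_(order, order)]


def fit_efa(scores: pd.DataFrame, features: list[str], k: int) -> EFAModel:
    """ML + quartimin EFA of the standard scores with *k* factors."""
    if k < 1:
        raise ValueError("k must be >= 1")
    x = _feature_matrix(scores, features)
    r = np.corrcoef(x, rowvar=False)
    lam0, psi = ml_factor_fit(r, k)
    lam, phi = oblimin_rotate(lam0)
    lam, phi = _canonical_order(lam, phi)
    cols = [f"F{i + 1}" for i in range(k)]
    return EFAModel(
        k=k,
        loadings=pd.DataFrame(lam, index=list(features), columns=cols),
        phi=phi,
        psi=pd.Series(psi, index=list(features)),
        corr=pd.DataFrame(r, index=list(features), columns=list(features)),
    )


# ------------------------------------------------------------- designation

def designate_factors(
    model: EFAModel, category_map: dict[str, str] | None = None
) -> EFAModel:
    """Label each factor by the majority feature family of its membership."""
    cmap = category_map or FEATURE_CATEGORIES
    labels = []
    for members, col in zip(model.memberships, model.loadings.columns):
        if not members:
            labels.append("Unclassified")
            continue
        weight: dict[str, float] = {}
        count: dict[str, int] = {}
        for feat in members:
            cat = cmap[feat]
            count[cat] = count.get(cat, 0) + 1
            weight[cat] = weight.get(cat, 0.0) + abs(float(model.loadings.loc[feat, col]))
        best = max(count, key=lambda c: (count[c], weight[c]))
        labels.append(best)
    dup = {l for l in labels if l != "Unclassified" and labels.count(l) > 1}
    if dup:
        logger.warning("duplicate factor designation(s): %s", sorted(dup))
    model.designations = labels
    return model


def _overfactored(model: EFAModel) -> bool:
    return any(len(m) < 2 for m in model.memberships)


def _underfactored(model: EFAModel, cmap: dict[str, str]) -> bool:
    for members in model.memberships:
        counts: dict[str, int] = {}
        for feat in members:
            counts[cmap[feat]] = counts.get(cmap[feat], 0) + 1
        if sum(c >= 2 for c in counts.values()) >= 2:
            return True
    return False


def adjust_k(
    scores: pd.DataFrame,
    features: list[str],
    initial_k: int | None = None,
    category_map: dict[str, str] | None = None,
    k_bounds: tuple[int, int] = (2, 12),
    max_iter: int = 10,
    override_k: int | None = None,
) -> EFAModel:
    """Iterative over/under-factoring adjustment starting from the Kaiser count.

    A factor with <2 members means a coherent family was split
    (over-factoring, decrement k); a factor holding >=2 features from each
    of >=2 families means families were merged (under-factoring, increment
    k).  Oscillations resolve to the smaller k.  ``override_k`` skips the
    iteration entirely.
    """
    cmap = category_map or FEATURE_CATEGORIES
    if override_k is not None:
        model = designate_factors(fit_efa(scores, features, override_k), cmap)
        model.history.append((override_k, "manual override"))
        return model
    k = initial_k if initial_k is not None else scree(scores, features).kaiser_count
    lo, hi = k_bounds
    k = int(np.clip(k, lo, hi))
    visited: dict[int, EFAModel] = {}
    history: list[tuple[int, str]] = []
    for _ in range(max_iter):
        model = visited.get(k) or designate_factors(fit_efa(scores, features, k), cmap)
        visited[k] = model
        over = _overfactored(model)
        under = _underfactored(model, cmap)
        if over:  # checked first: splitting a family is the clearer signal
            step, reason = -1, "over-factored"
        elif under:
            step, reason = +1, "under-factored"
        else:
            history.append((k, "converged"))
            model.history = history
            return model
        nxt = int(np.clip(k + step, lo, hi))
        history.append((k, reason))
        if nxt == k or nxt in visited:
            small = min(k, nxt)
            warnings.warn(
                f"factor-count oscillation between {sorted({k, nxt})}; keeping k={small}",
                stacklevel=2,
            )
            model = visited.get(small) or designate_factors(
                fit_efa(scores, features, small), cmap
            )
            history.append((small, "oscillation -> smaller k"))
            model.history = history
            return model
        k = nxt
    model.history = history + [(k, "iteration limit")]
    return model


# ------------------------------------------------------------ factor scores

def factor_scores(model: EFAModel, scores: pd.DataFrame) -> pd.DataFrame:
    """Thompson regression factor scores: ``Z @ R^-1 (Lambda Phi)``."""
    features = list(model.loadings.index)
    z = _feature_matrix(scores, features)
    r = model.corr.to_numpy()
    if np.linalg.cond(r) > 1e10:
        warnings.warn("ill-conditioned correlation matrix; ridge 1e-8 added", stacklevel=2)
        r = r + 1e-8 * np.eye(r.shape[0])
    w = np.linalg.solve(r, model.loadings.to_numpy() @ model.phi)
    fs = z @ w
    cols = model.designations or list(model.loadings.columns)
    out = scores.drop(columns=features).reset_index(drop=True)
    for i, c in enumerate(cols):
        out[c] = fs[:, i]
    return out


def factor_profile(model: EFAModel, scores: pd.DataFrame) -> ProfileMatrix:
    """Median factor score per condition: the factor-level profile heatmap."""
    fs = factor_scores(model, scores)
    cols = model.designations or list(model.loadings.columns)
    med = fs.groupby("condition_id", sort=True)[cols].median()
    return ProfileMatrix(med, kind="standard")


def representative_profile(model: EFAModel, scores: pd.DataFrame) -> ProfileMatrix:
    """Reduced profile from each factor's strongest-loading member feature."""
    picks: dict[str, str] = {}
    labels = model.designations or list(model.loadings.columns)
    for label, members, col in zip(labels, model.memberships, model.loadings.columns):
        if not members or label == "Unclassified":
            continue
        best = max(members, key=lambda f: abs(float(model.loadings.loc[f, col])))
        picks[label] = best
    med = scores.groupby("condition_id", sort=True)[list(picks.values())].median()
    med.columns = list(picks.keys())
    return ProfileMatrix(med, kind="standard")
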