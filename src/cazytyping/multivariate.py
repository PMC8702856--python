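"""Sparse PLS discriminant analysis and PERMANOVA.

The sPLS-DA here follows the classic formulation: per component, the
dominant singular pair of the cross-covariance matrix between the deflated
predictor block and a column-centred indicator (dummy) coding of the class
labels, with the X weight vector soft-thresholded so that exactly ``keepX``
entries stay non-zero, followed by regression deflation of both blocks.
keepX is tuned by repeated stratified k-fold cross-validation; the lowest
mean classification error wins, ties going to the sparser model.

PERMANOVA partitions the total sum of squared inter-point distances into
between- and within-group parts and assesses the pseudo-F statistic by
label permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PredictionDistance = Literal["max_dist", "centroids", "mahalanobis"]


# --------------------------------------------------------------------------
# sPLS-DA
# --------------------------------------------------------------------------

def _dummy_matrix(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """0/1 indicator coding, one column per class, column-centred."""
    ind = (y[:, None] == classes[None, :]).astype(float)
    return ind - ind.mean(axis=0)


def _soft_threshold_keep(a: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``a`` with the smallest lambda leaving exactly
    ``keep`` non-zeros; ties at the threshold break by feature index."""
    if keep >= a.size:
        return a.copy()
    magnitudes = np.abs(a)
    order = np.lexsort((np.arange(a.size), -magnitudes))  # stable by index
    lam = magnitudes[order[keep]] if keep < a.size else 0.0
    out = np.sign(a) * np.maximum(magnitudes - lam, 0.0)
    # ties exactly at lam: soft threshold zeroes them all, which can leave
    # fewer than keep entries; restore the lowest-index tied entries.
    nonzero = np.flatnonzero(out)
    if nonzero.size < keep:
        eps = np.finfo(float).tiny
        for idx in order[: keep]:
            if out[idx] == 0.0 and magnitudes[idx] >= lam:
                out[idx] = np.sign(a[idx]) * eps
    return out


def _fix_sign(w: np.ndarray) -> float:
    """Sign so the largest-magnitude entry of ``w`` is positive."""
    j = int(np.argmax(np.abs(w)))
    return 1.0 if w[j] >= 0 else -1.0


@dataclass
class SplsdaModel:
    """Fitted sparse PLS-DA model.

    ``x_weights`` (p x H, the sparse u vectors, unit norm), ``x_loadings``
    (p x H regression loadings), ``y_loadings`` (K x H), ``scores``
    (n x H), plus class levels and the feature/centred-Y bookkeeping needed
    for prediction.
    """

    classes: np.ndarray
    features: list
    keepx: list
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    y_mean: np.ndarray
    train_labels: np.ndarray = field(default_factory=lambda: np.empty(0))
    distance: PredictionDistance = "max_dist"
    sample_ids: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def rotation(self) -> np.ndarray:
        """W* = W (P' W)^-1, mapping raw X to scores in one step."""
        w, p = self.x_weights, self.x_loadings
        return w @ np.linalg.pinv(p.T @ w)

    def transform(self, x_new: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = self._as_matrix(x_new)
        return x @ self.rotation()

    def _as_matrix(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            missing = [f for f in self.features if f not in x.columns]
            if missing:
                raise KeyError(f"new data is missing trained features: {missing}")
            x = x[self.features].to_numpy(float)
        x = np.asarray(x, float)
        if x.shape[1] != len(self.features):
            raise ValueError("feature count mismatch with trained model")
        return x

    def loadings_frame(self) -> pd.DataFrame:
        """Feature x component weights with selection flags and the class of
        maximal mean score contribution (the contribution-plot content)."""
        out = pd.DataFrame(
            self.x_weights,
            index=self.features,
            columns=[f"comp{h+1}" for h in range(self.n_components)],
        )
        for h in range(self.n_components):
            out[f"selected_comp{h+1}"] = self.x_weights[:, h] != 0.0
        return out


def fit_splsda(
    x: pd.DataFrame | np.ndarray,
    y: Sequence,
    keepx: Sequence[int] | int,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SplsdaModel:
    """Fit a sparse PLS-DA model on an already standardized matrix.

    Parameters
    ----------
    x
        Samples x features, standardized, degenerate columns removed.
    y
        Class label per sample; at least two classes with >= 2 members.
    keepx
        Number of features retained per component (an int applies to all).
    """
    if isinstance(x, pd.DataFrame):
        features = list(x.columns)
        sample_ids = list(x.index)
        xm = x.to_numpy(float)
    else:
        xm = np.asarray(x, float)
        features = list(range(xm.shape[1]))
        sample_ids = list(range(xm.shape[0]))
    y_arr = np.asarray(list(y))
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members")
    n, p = xm.shape
    if isinstance(keepx, (int, np.integer)):
        keepx = [int(keepx)] * n_components
    keepx = [int(k) for k in keepx]
    if len(keepx) != n_components:
        raise ValueError("keepx must have one entry per component")
    if any(k < 1 or k > p for k in keepx):
        raise ValueError(f"keepX entries must lie in [1, {p}]")

    ym = _dummy_matrix(y_arr, classes)
    y_mean = (y_arr[:, None] == classes[None, :]).astype(float).mean(axis=0)

    x_def = xm.copy()
    y_def = ym.copy()
    w_all = np.zeros((p, n_components))
    p_all = np.zeros((p, n_components))
    c_all = np.zeros((len(classes), n_components))
    t_all = np.zeros((n, n_components))

    for h in range(n_components):
        m = x_def.T @ y_def  # p x K cross-covariance
        # initialise v from the dominant right singular vector
        _, _, vt = np.linalg.svd(m, full_matrices=False)
        v = vt[0]
        u = np.zeros(p)
        for _ in range(max_iter):
            a = m @ v
            u_new = _soft_threshold_keep(a, keepx[h])
            norm = np.linalg.norm(u_new)
            if norm == 0:
                logger.warning("component %d collapsed to zero weights", h + 1)
                u_new = a / max(np.linalg.norm(a), np.finfo(float).tiny)
            else:
                u_new = u_new / norm
            b = m.T @ u_new
            v_new = b / max(np.linalg.norm(b), np.finfo(float).tiny)
            if np.linalg.norm(u_new - u) < tol:
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        u = u * _fix_sign(u)
        t = x_def @ u
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"degenerate component {h + 1}: zero score variance")
        p_load = x_def.T @ t / tt
        c_load = y_def.T @ t / tt
        x_def = x_def - np.outer(t, p_load)
        y_def = y_def - np.outer(t, c_load)
        w_all[:, h] = u
        p_all[:, h] = p_load
        c_all[:, h] = c_load
        t_all[:, h] = t

    return SplsdaModel(
        classes=classes,
        features=features,
        keepx=keepx,
        x_weights=w_all,
        x_loadings=p_all,
        y_loadings=c_all,
        scores=t_all,
        y_mean=y_mean,
        train_labels=y_arr,
        sample_ids=sample_ids,
    )


def predict_splsda(
    model: SplsdaModel,
    x_new: pd.DataFrame | np.ndarray,
    distance: PredictionDistance = "max_dist",
) -> np.ndarray:
    """Class predictions for new (identically standardized) samples."""
    t_new = model.transform(x_new)
    if distance == "max_dist":
        y_hat = t_new @ model.y_loadings.T + model.y_mean
        return model.classes[np.argmax(y_hat, axis=1)]
    if distance in ("centroids", "mahalanobis"):
        train_y = model.train_labels
        centroids = np.vstack(
            [model.scores[train_y == c].mean(axis=0) for c in model.classes]
        )
        diffs = t_new[:, None, :] - centroids[None, :, :]
        if distance == "centroids":
            d2 = (diffs**2).sum(axis=2)
        else:
            pooled = _pooled_covariance(model.scores, train_y, model.classes)
            inv = np.linalg.pinv(pooled)
            d2 = np.einsum("nkh,hj,nkj->nk", diffs, inv, diffs)
        return model.classes[np.argmin(d2, axis=1)]
    raise ValueError(f"unknown prediction distance: {distance!r}")


def _pooled_covariance(scores: np.ndarray, y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    h = scores.shape[1]
    pooled = np.zeros((h, h))
    dof = 0
    for c in classes:
        sub = scores[y == c]
        if len(sub) > 1:
            pooled += np.cov(sub, rowvar=False, ddof=1) * (len(sub) - 1)
            dof += len(sub) - 1
    return pooled / max(dof, 1)


# --------------------------------------------------------------------------
# keepX tuning by repeated stratified cross-validation
# --------------------------------------------------------------------------

@dataclass
class CvTuningResult:
    """Grid of keepX candidates x components with CV error profiles."""

    grid: list
    mean_error: pd.DataFrame  # candidate x component
    sd_error: pd.DataFrame
    chosen_keepx: list
    folds: int
    repeats: int
    seed: int

    def to_tsv(self, path) -> None:
        out = self.mean_error.copy()
        out.columns = [f"mean_error_{c}" for c in out.columns]
        sd = self.sd_error.copy()
        sd.columns = [f"sd_error_{c}" for c in sd.columns]
        pd.concat([out, sd], axis=1).to_csv(path, sep="\t", index_label="keepX")


def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment by round-robin over shuffled within-class indices."""
    assignment = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


def tune_keepx(
    x: pd.DataFrame | np.ndarray,
    y: Sequence,
    candidates: Sequence[int],
    n_components: int = 2,
    folds: int = 5,
    repeats: int = 50,
    distance: PredictionDistance = "max_dist",
    seed: int = 0,
) -> CvTuningResult:
    """Tune keepX per component by repeated stratified k-fold CV.

    Components are tuned sequentially: the keepX chosen for earlier
    components is fixed while the candidate grid is scanned for the
    current one.  The chosen keepX minimizes the mean classification
    error; ties break toward the smallest keepX.
    """
    xm = x.to_numpy(float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
    y_arr = np.asarray(list(y))
    _, counts = np.unique(y_arr, return_counts=True)
    if (counts < folds).any():
        raise ValueError(
            f"smallest class ({counts.min()}) is smaller than folds={folds}; "
            "use fewer folds"
        )
    candidates = sorted(int(c) for c in candidates)
    if any(c < 1 or c > xm.shape[1] for c in candidates):
        raise ValueError("keepX candidates must lie within the feature count")

    rng = np.random.default_rng(seed)
    fold_plans = [stratified_folds(y_arr, folds, rng) for _ in range(repeats)]

    chosen: list[int] = []
    mean_err = np.zeros((len(candidates), n_components))
    sd_err = np.zeros((len(candidates), n_components))
    for h in range(n_components):
        for ci, cand in enumerate(candidates):
            keepx = chosen + [cand]
            errors = []
            for assignment in fold_plans:
                for f in range(folds):
                    test = assignment == f
                    model = fit_splsda(
                        xm[~test], y_arr[~test], keepx=keepx, n_components=h + 1
                    )
                    pred = predict_splsda(model, xm[test], distance=distance)
                    errors.append(float(np.mean(pred != y_arr[test])))
            mean_err[ci, h] = float(np.mean(errors))
            sd_err[ci, h] = float(np.std(errors, ddof=1)) if len(errors) > 1 else 0.0
        chosen.append(candidates[int(np.argmin(mean_err[:, h]))])

    comp_cols = [f"comp{h+1}" for h in range(n_components)]
    return CvTuningResult(
        grid=list(candidates),
        mean_error=pd.DataFrame(mean_err, index=candidates, columns=comp_cols),
        sd_error=pd.DataFrame(sd_err, index=candidates, columns=comp_cols),
        chosen_keepx=chosen,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def null_model_error(y: Sequence) -> float:
    """Error of always predicting the majority class (the no-component null)."""
    y_arr = np.asarray(list(y))
    _, counts = np.unique(y_arr, return_counts=True)
    return 1.0 - counts.max() / len(y_arr)


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix."""

    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    distance: str = "euclidean"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_f,
            "R2": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "distance": self.distance,
            "degenerate": self.degenerate,
        }


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += float(sub[np.triu_indices(len(idx), k=1)].sum()) / len(idx)
    return ss_total, ss_within


def permanova(
    distance: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA pseudo-F, R² and permutation p-value.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``; labels are
    permuted with a seeded generator.  All-coincident points make F
    undefined; the result is then flagged degenerate with p = 1.
    """
    d = distance.to_numpy(float) if isinstance(distance, pd.DataFrame) else np.asarray(distance, float)
    g = np.asarray(list(groups))
    if d.shape[0] != d.shape[1] or d.shape[0] != len(g):
        raise ValueError("distance matrix and group labels are inconsistent")
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    n, a = len(g), len(levels)
    d2 = d**2

    ss_total, ss_within = _permanova_ss(d2, g)
    ss_between = ss_total - ss_within
    if ss_total <= 0:
        # all points coincident: F undefined
        return PermanovaResult(
            pseudo_f=float("nan"), r_squared=float("nan"), p_value=1.0,
            n_permutations=n_permutations, degenerate=True,
        )
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(g)
        sst_p, ssw_p = _permanova_ss(d2, perm)
        ssb_p = sst_p - ssw_p
        f_p = (ssb_p / (a - 1)) / (ssw_p / (n - a)) if ssw_p > 0 else np.inf
        if f_p >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
    )
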