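"""Metabolomics: preprocessing, OPLS-DA with VIP and permutation diagnostics, DEM calls.

Metabolite intensities are log2-transformed and mean-centered per metabolite,
then a two-class orthogonal partial least squares discriminant analysis
(OPLS-DA) separates class-predictive variation from class-orthogonal
variation.  Model quality is summarised by R2X (fraction of X variance
captured), R2Y (fraction of class variance explained) and Q2 (cross-validated
predictive ability); per-metabolite importance by the VIP score (normalized
so the mean squared VIP is 1); and model validity by a label-permutation
test.  Differential metabolites are called with VIP >= 1 and
|log2 fold change| >= 1 (inclusive thresholds), and differential metabolites
are clustered on z-scored group means with the shared k-means routine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cluster import KMeansResult, kmeans_clusters
from .de import _check_samples

__all__ = [
    "MetaboliteMatrix",
    "preprocess",
    "OPLSDA",
    "OPLSDAResults",
    "PermutationResult",
    "vip_scores",
    "permutation_test",
    "call_dems",
    "metabolite_kmeans",
]


@dataclass
class MetaboliteMatrix:
    """Metabolite x sample intensity matrix with class annotation and metadata.

    ``classes`` maps each metabolite to a compound class (lipids, flavonoids,
    phenolic acids, ...); metabolites without annotation default to "other".
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate metabolite ids")
        if (self.intensities.to_numpy(dtype=float) < 0).any():
            raise ValueError("intensities must be non-negative")
        _check_samples(self.samples, self.intensities.columns)
        self.samples = self.samples.loc[self.intensities.columns]
        if self.classes is None:
            self.classes = pd.Series("other", index=self.intensities.index)
        else:
            self.classes = self.classes.reindex(self.intensities.index).fillna("other")

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.intensities.index

    def subset_samples(self, mask) -> "MetaboliteMatrix":
        keep = self.samples.index[mask]
        return MetaboliteMatrix(self.intensities[keep], self.samples.loc[keep], self.classes)

    def pseudocount(self) -> float:
        """Half the smallest nonzero intensity when zeros are present, else 0."""
        arr = self.intensities.to_numpy(dtype=float)
        if (arr == 0).any():
            return float(arr[arr > 0].min()) / 2.0
        return 0.0


def preprocess(met: MetaboliteMatrix) -> pd.DataFrame:
    """log2-transform and per-metabolite mean-center intensities.

    All-zero metabolites carry no information on the log scale and are
    dropped with a warning.  Returns a metabolite x sample DataFrame whose
    rows (variables) have mean zero.
    """
    arr = met.intensities
    allzero = (arr == 0).all(axis=1)
    if allzero.any():
        warnings.warn(
            f"dropping {int(allzero.sum())} all-zero metabolite(s)", stacklevel=2
        )
        arr = arr[~allzero]
    logx = np.log2(arr + met.pseudocount())
    return logx.sub(logx.mean(axis=1), axis=0)


def _center_cols(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    return X - mu, mu


def _fit_opls_core(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """One predictive + ``n_ortho`` orthogonal components (NIPALS-style).

    X is samples x variables, column-centered; y is centered +-1.  Returns a
    dict of weights/scores/loadings for the orthogonal sequence and the
    predictive component.
    """
    Xi = X.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = Xi.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("y carries no covariance with X; cannot fit")
        w /= nw
        t = Xi @ w
        p = Xi.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            raise ValueError(
                "no y-orthogonal variation left to extract; lower n_ortho"
            )
        w_o /= n_wo
        t_o = Xi @ w_o
        p_o = Xi.T @ t_o / (t_o @ t_o)
        Xi = Xi - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = Xi.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("y carries no covariance with X; cannot fit")
    w /= nw
    t = Xi @ w
    p = Xi.T @ t / (t @ t)
    c = float(y @ t / (t @ t))
    return {
        "w": w,
        "t": t,
        "p": p,
        "c": c,
        "W_o": np.array(W_o).reshape(n_ortho, -1) if n_ortho else np.empty((0, X.shape[1])),
        "P_o": np.array(P_o).reshape(n_ortho, -1) if n_ortho else np.empty((0, X.shape[1])),
        "T_o": np.array(T_o).T if n_ortho else np.empty((X.shape[0], 0)),
    }


def _predict_opls(core, Xnew: np.ndarray) -> np.ndarray:
    Xi = Xnew.copy()
    for w_o, p_o in zip(core["W_o"], core["P_o"]):
        t_o = Xi @ w_o
        Xi = Xi - np.outer(t_o, p_o)
    return (Xi @ core["w"]) * core["c"]


class OPLSDA:
    """Two-class OPLS-DA model on a samples x variables matrix.

    Parameters
    ----------
    X
        DataFrame (samples x variables) or array.  Typically the transpose
        of :func:`preprocess` output; columns are re-centered at fit time.
    y
        Class label per sample (exactly two distinct labels, each with at
        least two samples).  Labels are encoded -1/+1 in sorted order.
    n_ortho
        Number of y-orthogonal components removed before the single
        predictive component; default 1.
    """

    def __init__(self, X, y, n_ortho: int = 1) -> None:
        if isinstance(X, pd.DataFrame):
            self.var_names = X.columns
            self.sample_names = X.index
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.var_names = pd.RangeIndex(X.shape[1])
            self.sample_names = pd.RangeIndex(X.shape[0])
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {list(classes)}")
        counts = [(y == c).sum() for c in classes]
        if min(counts) < 2:
            raise ValueError("each class needs >=2 samples")
        rank_bound = min(X.shape[0] - 1, X.shape[1])
        if n_ortho >= rank_bound:
            raise ValueError(f"n_ortho={n_ortho} >= usable rank bound {rank_bound}")
        self.X = X
        self.classes_ = classes
        self.y = np.where(y == classes[1], 1.0, -1.0)
        self.y_labels = y
        self.n_ortho = int(n_ortho)

    def fit(self, cv_folds: int = 7, seed: int = 0) -> "OPLSDAResults":
        Xc, x_mean = _center_cols(self.X)
        yc = self.y - self.y.mean()
        ssx = float((Xc**2).sum())
        ssy = float((yc**2).sum())
        core = _fit_opls_core(Xc, yc, self.n_ortho)

        t, p, c = core["t"], core["p"], core["c"]
        r2y = 1.0 - float(((yc - t * c) ** 2).sum()) / ssy
        r2x_pred = float((np.outer(t, p) ** 2).sum()) / ssx
        r2x_ortho = (
            float(sum((np.outer(t_o, p_o) ** 2).sum()
                      for t_o, p_o in zip(core["T_o"].T, core["P_o"])))
            / ssx
        )

        q2 = self._cross_validated_q2(cv_folds, seed)
        vip = vip_scores_from_core(core)
        return OPLSDAResults(
            model=self,
            x_mean=x_mean,
            weights=pd.Series(core["w"], index=self.var_names, name="w"),
            loadings=pd.Series(p, index=self.var_names, name="p"),
            scores=pd.Series(t, index=self.sample_names, name="t_pred"),
            c=c,
            ortho_weights=pd.DataFrame(core["W_o"], columns=self.var_names),
            ortho_loadings=pd.DataFrame(core["P_o"], columns=self.var_names),
            ortho_scores=pd.DataFrame(core["T_o"], index=self.sample_names),
            r2x=r2x_pred + r2x_ortho,
            r2x_pred=r2x_pred,
            r2x_ortho=r2x_ortho,
            r2y=r2y,
            q2=q2,
            vip=pd.Series(vip, index=self.var_names, name="vip"),
            core=core,
        )

    def _cross_validated_q2(self, cv_folds: int, seed: int) -> float:
        """Q2 = 1 - PRESS/SSY via stratified k-fold CV (folds capped by class size)."""
        y = self.y
        min_class = int(min((self.y_labels == c).sum() for c in self.classes_))
        n_splits = max(2, min(cv_folds, min_class))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        press = 0.0
        for train, test in skf.split(self.X, self.y_labels):
            Xtr, x_mu = _center_cols(self.X[train])
            ytr = y[train] - y[train].mean()
            core = _fit_opls_core(Xtr, ytr, self.n_ortho)
            yhat = _predict_opls(core, self.X[test] - x_mu) + y[train].mean()
            press += float(((y[test] - yhat) ** 2).sum())
        ssy = float(((y - y.mean()) ** 2).sum())
        return 1.0 - press / ssy


def vip_scores_from_core(core) -> np.ndarray:
    """VIP over the predictive component(s) from fitted weights.

    VIP_j = sqrt(p * sum_a[SSY_a (w_aj/||w_a||)^2] / sum_a SSY_a); with one
    predictive component this reduces to sqrt(p) * |w_j| / ||w||, so the
    squared VIPs sum to the number of variables exactly.
    """
    w = core["w"]
    n_vars = w.size
    frac = (w / np.linalg.norm(w)) ** 2
    # single predictive component: the SSY weights cancel
    return np.sqrt(n_vars * frac)


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA: scores, loadings, R2X/R2Y/Q2, VIP."""

    model: OPLSDA = field(repr=False)
    x_mean: np.ndarray = field(repr=False)
    weights: pd.Series = field(repr=False)
    loadings: pd.Series = field(repr=False)
    scores: pd.Series = field(repr=False)
    c: float = 0.0
    ortho_weights: pd.DataFrame = field(repr=False, default=None)
    ortho_loadings: pd.DataFrame = field(repr=False, default=None)
    ortho_scores: pd.DataFrame = field(repr=False, default=None)
    r2x: float = 0.0
    r2x_pred: float = 0.0
    r2x_ortho: float = 0.0
    r2y: float = 0.0
    q2: float = 0.0
    vip: pd.Series = field(repr=False, default=None)
    core: dict = field(repr=False, default=None)

    def predict(self, Xnew) -> np.ndarray:
        """Continuous class score for new samples (sign gives the class)."""
        Xnew = np.asarray(Xnew, dtype=float)
        return _predict_opls(self.core, Xnew - self.x_mean) + self.model.y.mean()

    def summary(self) -> str:
        cls = self.model.classes_
        lines = [
            "OPLS-DA (1 predictive + "
            f"{self.model.n_ortho} orthogonal component(s))",
            f"  classes: {cls[0]!r} (-1) vs {cls[1]!r} (+1)   "
            f"n = {len(self.scores)} samples, {len(self.vip)} variables",
            f"  R2X = {self.r2x:.3f} (predictive {self.r2x_pred:.3f}, "
            f"orthogonal {self.r2x_ortho:.3f})",
            f"  R2Y = {self.r2y:.3f}   Q2 = {self.q2:.3f}",
            f"  top VIP: "
            + ", ".join(
                f"{i}={v:.2f}" for i, v in self.vip.sort_values(ascending=False)[:5].items()
            ),
        ]
        return "\n".join(lines)


def vip_scores(results: OPLSDAResults) -> pd.Series:
    """Per-variable VIP of a fitted model (mean squared VIP = 1)."""
    if results.core is None:
        raise ValueError("model is not fitted")
    return results.vip


@dataclass
class PermutationResult:
    """Label-permutation null of (R2Y, Q2) and the empirical p-value for Q2."""

    r2y_null: np.ndarray
    q2_null: np.ndarray
    r2y_observed: float
    q2_observed: float
    p_value: float


def permutation_test(
    model: OPLSDA,
    n_perm: int = 200,
    seed: int = 0,
    cv_folds: int = 7,
) -> PermutationResult:
    """Refit under shuffled class labels to assess model validity.

    p = (1 + #{null Q2 >= observed Q2}) / (n_perm + 1).

    With few samples a uniformly drawn permutation frequently reproduces the
    observed class assignment (or its mirror, which fits identically); such
    draws carry no information about the null, so they are rejected and
    redrawn.  Without this, the smallest attainable p at 3+3 samples would
    be ~0.1 regardless of effect size.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives a very coarse permutation p-value", stacklevel=2)
    observed = model.fit(cv_folds=cv_folds, seed=seed)
    rng = np.random.default_rng(seed)
    y_enc = model.y
    r2y_null = np.empty(n_perm)
    q2_null = np.empty(n_perm)
    for i in range(n_perm):
        for _ in range(1000):
            y_perm = rng.permutation(model.y_labels)
            enc = np.where(y_perm == model.classes_[1], 1.0, -1.0)
            if not (np.array_equal(enc, y_enc) or np.array_equal(enc, -y_enc)):
                break
        else:
            raise ValueError("could not draw a label assignment distinct from the observed one")
        perm_model = OPLSDA(model.X, y_perm, n_ortho=model.n_ortho)
        res = perm_model.fit(cv_folds=cv_folds, seed=seed)
        r2y_null[i] = res.r2y
        q2_null[i] = res.q2
    p = (1.0 + float((q2_null >= observed.q2).sum())) / (n_perm + 1.0)
    return PermutationResult(
        r2y_null=r2y_null,
        q2_null=q2_null,
        r2y_observed=observed.r2y,
        q2_observed=observed.q2,
        p_value=p,
    )


def call_dems(
    met: MetaboliteMatrix,
    vip: pd.Series,
    genotype: str | None = None,
    contrast: tuple[str, str] = ("HS", "CK"),
    log2fc_threshold: float = 1.0,
    vip_threshold: float = 1.0,
) -> pd.DataFrame:
    """Call differential metabolites from VIP and fold change.

    log2 fold change is computed from group geometric means of the raw
    intensities (consistent with log-scale modelling).  Calls use inclusive
    thresholds: ``up`` iff log2_fc >= threshold and VIP >= vip_threshold,
    ``down`` iff log2_fc <= -threshold and VIP >= vip_threshold, else ``ns``.
    """
    sub = met
    if genotype is not None:
        if genotype not in set(met.samples["genotype"]):
            raise ValueError(f"genotype {genotype!r} not in sample sheet")
        sub = met.subset_samples(met.samples["genotype"] == genotype)
    cond = sub.samples["condition"]
    for c in contrast:
        if not (cond == c).any():
            raise ValueError(f"condition {c!r} missing")
    logx = np.log2(sub.intensities + sub.pseudocount())
    gm_num = logx.loc[:, (cond == contrast[0]).to_numpy()].mean(axis=1)
    gm_den = logx.loc[:, (cond == contrast[1]).to_numpy()].mean(axis=1)
    log2_fc = gm_num - gm_den
    vip = vip.reindex(log2_fc.index)
    call = np.where(
        (log2_fc >= log2fc_threshold) & (vip >= vip_threshold),
        "up",
        np.where((log2_fc <= -log2fc_threshold) & (vip >= vip_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2_fc": log2_fc, "vip": vip, "call": call},
        index=log2_fc.index.rename("metabolite_id"),
    )


def metabolite_kmeans(
    met: MetaboliteMatrix,
    metabolite_ids: Iterable[str],
    k: int = 9,
    seed: int = 0,
    n_init: int = 10,
) -> KMeansResult:
    """Cluster differential metabolites on z-scored group means of log2 intensity.

    Group means are taken over the genotype x condition groups; constant
    metabolites are excluded with a warning.  Shares the k-means routine
    with the expression-clustering module.
    """
    ids = pd.Index(metabolite_ids)
    logx = np.log2(met.intensities.loc[ids] + met.pseudocount())
    keys = met.samples["genotype"] + "_" + met.samples["condition"]
    means = logx.T.groupby(keys.values).mean().T
    sd = means.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant metabolite(s) from clustering",
            stacklevel=2,
        )
        means, sd = means[~constant], sd[~constant]
    z = means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)
    res = kmeans_clusters(z, k=k, seed=seed, n_init=n_init)
    res.assignments.index.name = "metabolite_id"
    return res
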