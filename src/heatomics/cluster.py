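"""k-means expression clustering with elbow diagnostics, and hypergeometric enrichment.

Differentially expressed genes are clustered on z-scored group-mean
expression profiles (four genotype x condition groups per gene), with the
within-cluster sum of squares over a range of k providing the elbow
diagnostic.  Gene sets (clusters, response categories) are tested for term
enrichment against a GMT-style annotation with the upper-tail hypergeometric
test and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .de import ExpressionMatrix, bh_adjust

__all__ = [
    "scaled_group_profiles",
    "kmeans_clusters",
    "KMeansResult",
    "elbow_curve",
    "ElbowResult",
    "hypergeom_enrich",
]


def scaled_group_profiles(
    expr: ExpressionMatrix, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-gene z-scores of group-mean FPKM across genotype x condition groups.

    Genes with a constant profile cannot be scaled and are dropped with a
    warning.
    """
    means = expr.group_means()
    if genes is not None:
        means = means.loc[means.index.intersection(pd.Index(genes))]
    sd = means.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant-profile gene(s) before scaling",
            stacklevel=2,
        )
        means, sd = means[~constant], sd[~constant]
    return means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)


@dataclass
class KMeansResult:
    """Cluster assignment (labels M1..Mk), within-cluster SS, and centroids."""

    assignments: pd.Series
    wss: float
    centers: pd.DataFrame

    @property
    def k(self) -> int:
        return len(self.centers)


def kmeans_clusters(
    profiles: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> KMeansResult:
    """Lloyd's k-means, Euclidean, best of ``n_init`` random starts.

    Deterministic given ``seed``.  Raises if k exceeds the number of usable
    profiles.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds {len(profiles)} usable profiles")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_init,
        algorithm="lloyd",
        random_state=seed,
    ).fit(profiles.to_numpy(dtype=float))
    labels = pd.Series(
        [f"M{i + 1}" for i in km.labels_], index=profiles.index, name="cluster"
    )
    centers = pd.DataFrame(
        km.cluster_centers_,
        index=[f"M{i + 1}" for i in range(k)],
        columns=profiles.columns,
    )
    return KMeansResult(assignments=labels, wss=float(km.inertia_), centers=centers)


@dataclass
class ElbowResult:
    """Within-cluster SS over a k range plus an automated elbow suggestion."""

    ks: list[int]
    wss: list[float]
    suggested_k: int
    low_confidence: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "wss": self.wss})


def elbow_curve(
    profiles: pd.DataFrame,
    k_range: Iterable[int],
    seed: int = 0,
    n_init: int = 10,
    default_k: int = 4,
) -> ElbowResult:
    """WSS per k with the elbow located at the largest discrete curvature.

    The suggestion is the k maximizing the second difference of log WSS:
    on the log scale a steadily shrinking curve has roughly constant
    curvature, so the maximum marks the transition from steep decay to
    plateau (the visual elbow).  It is advisory (the pipeline default stays
    at ``default_k``).
    With fewer than three k values no curvature exists and the default is
    returned with a warning.  The suggestion is flagged low-confidence when
    the maximum curvature is less than twice the median curvature.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be nonempty")
    wss = [kmeans_clusters(profiles, k, seed=seed, n_init=n_init).wss for k in ks]
    if len(ks) < 3:
        warnings.warn(
            "k_range too short for an elbow; returning the default k",
            stacklevel=2,
        )
        return ElbowResult(ks=ks, wss=wss, suggested_k=default_k, low_confidence=True)
    log_wss = np.log(np.maximum(wss, 1e-300))
    curv = np.array(
        [log_wss[i - 1] - 2.0 * log_wss[i] + log_wss[i + 1] for i in range(1, len(ks) - 1)]
    )
    best = int(np.argmax(curv))
    suggested = ks[best + 1]
    med = float(np.median(curv))
    low_confidence = bool(curv[best] < 2.0 * med) if med > 0 else False
    return ElbowResult(ks=ks, wss=wss, suggested_k=suggested, low_confidence=low_confidence)


def hypergeom_enrich(
    selected: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with BH correction.

    For each term with at least one universe gene, tests whether the
    selected set contains more term genes than expected when drawing
    ``n = |selected|`` genes from the ``N``-gene universe containing ``K``
    term genes: p = P(X >= k).  Only universe-intersected annotations count.

    Returns a DataFrame with columns term_id, k, K, n, N, hypergeom_p,
    p_adj and significant (p_adj < ``alpha``), sorted by p_adj.
    """
    sel = set(selected)
    uni = set(universe)
    if not sel <= uni:
        raise ValueError(
            f"selected genes outside universe: {sorted(sel - uni)[:5]}"
        )
    N, n = len(uni), len(sel)
    rows = []
    for term, genes in annotations.items():
        term_genes = set(genes) & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "hypergeom_p": p})
    result = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "hypergeom_p"])
    if len(result):
        result["p_adj"] = bh_adjust(result["hypergeom_p"].to_numpy())
        result["significant"] = result["p_adj"] < alpha
        result = result.sort_values("p_adj", kind="mergesort").reset_index(drop=True)
    else:
        result["p_adj"] = []
        result["significant"] = []
    return result
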