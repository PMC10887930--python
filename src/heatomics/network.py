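"""Gene-metabolite correlation network over matched samples.

Expression (log2 FPKM) of differentially expressed genes is correlated
pairwise with log2 metabolite intensities across samples matched one-to-one
by (genotype, condition, replicate).  Pairs with squared correlation above
the threshold and a two-sided p below alpha (t distribution, n-2 df) become
network edges, signed by the correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import ExpressionMatrix
from .metabolome import MetaboliteMatrix

__all__ = ["CorrelationNetwork", "correlation_network", "network_summary"]


@dataclass
class CorrelationNetwork:
    """Edge list of highly correlated gene-metabolite pairs plus node tables."""

    edges: pd.DataFrame
    n_samples: int
    r2_threshold: float
    alpha: float
    method: str

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.edges["gene_id"].unique())

    @property
    def metabolites(self) -> pd.Index:
        return pd.Index(self.edges["metabolite_id"].unique())

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for gene in self.genes:
            g.add_node(gene, kind="gene")
        for met in self.metabolites:
            g.add_node(met, kind="metabolite")
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.gene_id,
                row.metabolite_id,
                r=float(row.r),
                r_squared=float(row.r_squared),
                p=float(row.p),
                sign=row.sign,
            )
        return g


def _match_samples(
    expr_samples: pd.DataFrame, met_samples: pd.DataFrame
) -> tuple[list, list]:
    def keys(df):
        if "replicate" not in df.columns:
            raise ValueError("sample sheets need a replicate column for matching")
        return {
            (r.genotype, r.condition, r.replicate): idx
            for idx, r in df.iterrows()
        }

    ek, mk = keys(expr_samples), keys(met_samples)
    shared = sorted(set(ek) & set(mk))
    return [ek[k] for k in shared], [mk[k] for k in shared]


def correlation_network(
    expr: ExpressionMatrix,
    met: MetaboliteMatrix,
    genes: Iterable[str] | None = None,
    r2_threshold: float = 0.9,
    alpha: float = 0.05,
    method: str = "pearson",
) -> CorrelationNetwork:
    """All-pairs gene x metabolite correlation with cor^2 and p screening.

    Parameters
    ----------
    expr, met
        Omics matrices whose sample sheets are matched one-to-one by
        (genotype, condition, replicate); at least 3 matched samples.
    genes
        Restrict the gene side (typically the DEG union); default all genes.
    r2_threshold, alpha
        Keep edges with r^2 > ``r2_threshold`` and p < ``alpha`` (per-pair,
        unadjusted, matching the published screen).
    method
        "pearson" (on log2 values) or "spearman".
    """
    e_ids, m_ids = _match_samples(expr.samples, met.samples)
    n = len(e_ids)
    if n < 3:
        raise ValueError(f"need >=3 matched samples, found {n}")
    gene_index = expr.fpkm.index if genes is None else pd.Index(genes)
    X = np.log2(expr.fpkm.loc[gene_index, e_ids].to_numpy(dtype=float) + 1.0)
    Y = np.log2(met.intensities.loc[:, m_ids].to_numpy(dtype=float) + met.pseudocount())
    met_index = met.metabolite_ids

    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        Y = stats.rankdata(Y, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    def standardize(mat, label):
        centered = mat - mat.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        # relative tolerance: exact-constant rows leave machine-eps residue
        # after centering, which would otherwise correlate as pure noise
        scale = np.abs(mat).max(axis=1)
        const = norms <= 1e-9 * (1.0 + scale)
        if const.any():
            warnings.warn(
                f"skipping {int(const.sum())} constant {label} profile(s)",
                stacklevel=3,
            )
        safe = np.where(const, 1.0, norms)
        return centered / safe[:, None], ~const

    Zx, keep_x = standardize(X, "gene")
    Zy, keep_y = standardize(Y, "metabolite")
    r = Zx @ Zy.T
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    valid = np.outer(keep_x, keep_y)
    keep = valid & (r**2 > r2_threshold) & (p < alpha)
    gi, mi = np.nonzero(keep)
    edges = pd.DataFrame(
        {
            "gene_id": gene_index[gi],
            "metabolite_id": met_index[mi],
            "r": r[gi, mi],
            "r_squared": r[gi, mi] ** 2,
            "p": p[gi, mi],
            "sign": np.where(r[gi, mi] >= 0, "positive", "negative"),
        }
    )
    return CorrelationNetwork(
        edges=edges,
        n_samples=n,
        r2_threshold=r2_threshold,
        alpha=alpha,
        method=method,
    )


def network_summary(net: CorrelationNetwork) -> dict[str, int]:
    """Edge and node counts, including the number of negative correlations."""
    return {
        "n_edges": int(len(net.edges)),
        "n_genes": int(net.edges["gene_id"].nunique()),
        "n_metabolites": int(net.edges["metabolite_id"].nunique()),
        "n_negative": int((net.edges["sign"] == "negative").sum()),
        "n_positive": int((net.edges["sign"] == "positive").sum()),
    }
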