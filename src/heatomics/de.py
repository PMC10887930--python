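"""Negative-binomial differential expression for a two-genotype heat-stress design.

The transcriptomic substrate is a gene x sample matrix of read counts with a
sample sheet assigning each library a genotype (``tolerant`` or
``susceptible``), a condition (``CK`` control or ``HS`` heat stress) and a
replicate number.  Counts are depth-normalized with median-of-ratios size
factors, expression is standardized to FPKM for filtering and downstream
screens, and per-gene differential expression between conditions within one
genotype is tested with a transparent negative-binomial Wald test
(method-of-moments dispersion, no shrinkage).  A gene is called ``up`` when
log2 fold change > 1 with BH-adjusted p < 0.05, ``down`` when < -1, else
``ns``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "SampleQC",
    "NegativeBinomialDE",
    "DEResults",
    "size_factors",
    "fpkm",
    "filter_expressed",
    "bh_adjust",
    "nb_wald_test",
    "sample_qc",
]

SAMPLE_COLUMNS = ("genotype", "condition", "replicate")


def _check_samples(samples: pd.DataFrame, sample_ids) -> None:
    missing = [c for c in ("genotype", "condition") if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet is missing columns {missing}")
    extra = set(sample_ids) - set(samples.index)
    if extra:
        raise ValueError(f"samples absent from sample sheet: {sorted(extra)[:5]}")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with metadata.

    Attributes
    ----------
    counts
        DataFrame indexed by gene_id, one column per sample_id;
        non-negative integers.
    samples
        DataFrame indexed by sample_id with columns ``genotype``,
        ``condition`` and (optionally) ``replicate``.
    gene_lengths
        Series of transcript lengths in bp, aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
        if bad.size:
            g, s = bad[0]
            raise ValueError(
                "counts must be non-negative integers; offending cell "
                f"gene={self.counts.index[g]!r} sample={self.counts.columns[s]!r} "
                f"value={arr[g, s]!r}"
            )
        _check_samples(self.samples, self.counts.columns)
        self.samples = self.samples.loc[self.counts.columns]
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            bad_gene = self.gene_lengths.index[
                self.gene_lengths.isna() | (self.gene_lengths <= 0)
            ][0]
            raise ValueError(f"gene length missing or non-positive for {bad_gene!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        keep = self.samples.index[mask]
        return CountMatrix(self.counts[keep], self.samples.loc[keep], self.gene_lengths)


@dataclass
class ExpressionMatrix:
    """FPKM expression matrix sharing shape and metadata with its source counts."""

    fpkm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_samples(self.samples, self.fpkm.columns)
        self.samples = self.samples.loc[self.fpkm.columns]
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    def group_means(self, pseudocount: float = 0.0) -> pd.DataFrame:
        """Mean FPKM (+pseudocount) per gene over each genotype x condition group."""
        keys = self.samples["genotype"] + "_" + self.samples["condition"]
        means = self.fpkm.T.groupby(keys.values).mean().T
        return means + pseudocount


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth normalization factors, one per sample.

    For each gene nonzero in every sample, the ratio of its count to its
    geometric mean across samples is formed; a sample's size factor is the
    median of those ratios.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios is "
            "undefined -- consider a pseudo-reference fallback on filtered data"
        )
    sub = arr[nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(sub) - log_geomean, axis=0))
    return pd.Series(sf, index=mat.columns, name="size_factor")


def fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    fpkm[g, j] = count[g, j] / ((length_g / 1e3) * (colsum_j / 1e6)), with the
    per-sample mapped total taken as the column sum of the count matrix.
    """
    totals = counts.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = counts.sample_ids[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    kb = counts.gene_lengths.to_numpy(dtype=float)[:, None] / 1e3
    vals = counts.counts.to_numpy(dtype=float) / (kb * (totals[None, :] / 1e6))
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        counts.samples,
    )


def filter_expressed(expr: ExpressionMatrix, threshold: float = 1.0) -> pd.Index:
    """Genes whose FPKM summed over all samples strictly exceeds ``threshold``."""
    sums = expr.fpkm.sum(axis=1)
    return expr.fpkm.index[sums > threshold]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


class NegativeBinomialDE:
    """Per-gene NB Wald test of heat stress vs control within one genotype.

    The model is NB with var = mu + alpha * mu^2 per gene.  Counts are
    depth-normalized by median-of-ratios size factors computed on the
    samples entering the contrast.  The log2 fold change is
    log2((mu_HS + pc) / (mu_CK + pc)) with pseudocount ``pc`` on normalized
    means; its standard error comes from the expected NB information with a
    per-gene dispersion.  The per-gene method-of-moments dispersion is very
    noisy at 2-3 replicates, so it is moderated toward the experiment-wide
    median of the positive per-gene estimates with ``prior_df`` prior
    degrees of freedom (empirical-Bayes squeezing), then floored.  The Wald
    statistic is referred to a t distribution with a per-gene Satterthwaite
    effective degrees of freedom: the Poisson component of the variance is
    treated as known given the mean while the dispersion component carries
    d_resid + prior_df degrees of freedom; the effective df is clipped to
    [d_total, 2 * d_total] to keep small-sample calibration honest.

    Parameters
    ----------
    counts
        Full-design count matrix.
    genotype
        Which genotype's samples to test.
    contrast
        Pair (numerator condition, denominator condition); default (HS, CK).
    pseudocount
        Added to normalized group means in the fold change; default 0.5.
    dispersion_floor
        Lower bound on the moderated dispersion; default 1e-8.
    prior_df
        Prior degrees of freedom of the dispersion moderation; default 4.
    """

    def __init__(
        self,
        counts: CountMatrix,
        genotype: str,
        contrast: tuple[str, str] = ("HS", "CK"),
        pseudocount: float = 0.5,
        dispersion_floor: float = 1e-8,
        prior_df: float = 4.0,
    ) -> None:
        if genotype not in set(counts.samples["genotype"]):
            raise ValueError(f"genotype {genotype!r} not present in sample sheet")
        self.genotype = genotype
        self.contrast = tuple(contrast)
        self.pseudocount = float(pseudocount)
        self.dispersion_floor = float(dispersion_floor)
        self.prior_df = float(prior_df)
        sub = counts.subset_samples(counts.samples["genotype"] == genotype)
        for cond in self.contrast:
            n = int((sub.samples["condition"] == cond).sum())
            if n == 0:
                raise ValueError(f"condition {cond!r} missing for genotype {genotype!r}")
            if n < 2:
                raise ValueError(
                    f"need >=2 replicates of condition {cond!r}, got {n}"
                )
        self.data = sub

    def fit(self) -> "DEResults":
        num_cond, den_cond = self.contrast
        sf = size_factors(self.data)
        norm = self.data.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
        cond = self.data.samples["condition"].to_numpy()
        num = norm[:, cond == num_cond]
        den = norm[:, cond == den_cond]
        n_num, n_den = num.shape[1], den.shape[1]

        mu_num, mu_den = num.mean(axis=1), den.mean(axis=1)
        base_mean = norm[:, np.isin(cond, self.contrast)].mean(axis=1)
        d_resid = n_num + n_den - 2
        s2 = (
            num.var(axis=1, ddof=1) * (n_num - 1) + den.var(axis=1, ddof=1) * (n_den - 1)
        ) / d_resid
        mu_bar = (mu_num + mu_den) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_mom = (s2 - mu_bar) / np.where(mu_bar > 0, mu_bar, np.nan) ** 2
        alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
        positive = alpha_mom > 0
        prior = float(np.median(alpha_mom[positive])) if positive.any() else 0.0
        alpha = (d_resid * alpha_mom + self.prior_df * prior) / (d_resid + self.prior_df)
        alpha = np.maximum(alpha, self.dispersion_floor)

        pc = self.pseudocount
        log2_fc = np.log2((mu_num + pc) / (mu_den + pc))
        # Expected-information variance of log(mu_hat) per group is
        # (1/mu + alpha) / n; Poisson part treated as known, dispersion part
        # estimated with d_resid + prior_df df -> Satterthwaite effective df.
        d_total = d_resid + self.prior_df
        pois = (1.0 / (mu_num + pc)) / n_num + (1.0 / (mu_den + pc)) / n_den
        disp = alpha * (1.0 / n_num + 1.0 / n_den)
        se = np.sqrt(pois + disp) / np.log(2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            df_eff = (pois + disp) ** 2 / (disp**2 / d_total)
        df_eff = np.clip(np.where(np.isfinite(df_eff), df_eff, 2 * d_total),
                         d_total, 2 * d_total)
        wald = log2_fc / se
        wald_p = 2.0 * stats.t.sf(np.abs(wald), df=df_eff)
        p_adj = bh_adjust(wald_p)

        call = np.where(
            (log2_fc > 1.0) & (p_adj < 0.05),
            "up",
            np.where((log2_fc < -1.0) & (p_adj < 0.05), "down", "ns"),
        )
        table = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2_fc": log2_fc,
                "wald_p": wald_p,
                "p_adj": p_adj,
                "call": call,
            },
            index=self.data.gene_ids.rename("gene_id"),
        )
        return DEResults(
            table=table,
            genotype=self.genotype,
            contrast=self.contrast,
            size_factors=sf,
            dispersion=pd.Series(alpha, index=self.data.gene_ids, name="dispersion"),
            model=self,
        )


@dataclass
class DEResults:
    """Differential-expression results: per-gene estimates, p-values and calls."""

    table: pd.DataFrame
    genotype: str
    contrast: tuple[str, str]
    size_factors: pd.Series
    dispersion: pd.Series
    model: NegativeBinomialDE = field(repr=False)

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def genes_called(self, direction: str) -> pd.Index:
        return self.table.index[self.table["call"] == direction]

    def summary(self, top: int = 10) -> str:
        n_up = int((self.table["call"] == "up").sum())
        n_down = int((self.table["call"] == "down").sum())
        lines = [
            "Negative-binomial Wald differential expression",
            f"  genotype: {self.genotype}   contrast: {self.contrast[0]} vs {self.contrast[1]}",
            f"  genes tested: {len(self.table)}   up: {n_up}   down: {n_down}",
            "",
            self.table.reindex(self.table["p_adj"].sort_values().index[:top])
            .to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def nb_wald_test(
    counts: CountMatrix,
    genotype: str,
    contrast: tuple[str, str] = ("HS", "CK"),
    **kwargs,
) -> DEResults:
    """Convenience wrapper: fit :class:`NegativeBinomialDE` and return results."""
    return NegativeBinomialDE(counts, genotype, contrast, **kwargs).fit()


@dataclass
class SampleQC:
    """Replicate-quality diagnostics: Spearman correlations and PCA."""

    spearman: pd.DataFrame
    pca_variance_pct: np.ndarray
    pca_scores: pd.DataFrame

    def min_within_group(self, samples: pd.DataFrame) -> float:
        """Smallest Spearman correlation among samples of the same genotype."""
        vals = []
        for _, grp in samples.groupby("genotype"):
            ids = [s for s in grp.index if s in self.spearman.index]
            block = self.spearman.loc[ids, ids].to_numpy()
            iu = np.triu_indices_from(block, k=1)
            vals.extend(block[iu])
        return float(np.nanmin(vals)) if vals else float("nan")


def sample_qc(expr: ExpressionMatrix) -> SampleQC:
    """Pairwise Spearman correlation of samples plus PCA on log2(FPKM + 1).

    PCA treats genes as variables (samples as observations), centered but not
    scaled; variance explained is reported in percent, ordered.
    Constant samples yield undefined correlations, reported as NaN with a
    warning.
    """
    if expr.fpkm.shape[1] < 2:
        raise ValueError("need >=2 samples for QC")
    constant = expr.fpkm.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant sample(s) {list(expr.fpkm.columns[constant])}: "
            "Spearman correlation undefined, reported as NaN",
            stacklevel=2,
        )
    rho = expr.fpkm.corr(method="spearman")
    logx = np.log2(expr.fpkm.to_numpy(dtype=float) + 1.0).T
    n_comp = min(logx.shape[0] - 1, logx.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(logx)
    return SampleQC(
        spearman=rho,
        pca_variance_pct=pca.explained_variance_ratio_ * 100.0,
        pca_scores=pd.DataFrame(
            scores,
            index=expr.fpkm.columns,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        ),
    )
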