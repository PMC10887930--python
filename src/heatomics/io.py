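"""File formats, pipeline configuration, and the end-to-end pipeline runner.

Canonical dialects: matrices are TSV with a header row and feature ids in
the first column; the sample sheet is CSV with columns
sample_id,genotype,condition,replicate; annotations are standard GMT
(term, description, then gene ids, tab-separated); yields are CSV with
variety,treatment,grain_yield_kg_ha.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .agronomics import heat_tolerance_table
from .cluster import elbow_curve, hypergeom_enrich, kmeans_clusters, scaled_group_profiles
from .de import CountMatrix, filter_expressed, fpkm, nb_wald_test, sample_qc
from .metabolome import (
    MetaboliteMatrix,
    OPLSDA,
    call_dems,
    metabolite_kmeans,
    permutation_test,
    preprocess,
)
from .network import correlation_network, network_summary
from .responses import classify_responses, frontload_screen, venn_summary

logger = logging.getLogger("heatomics")

__all__ = [
    "read_counts",
    "write_counts",
    "read_metabolites",
    "write_metabolites",
    "read_gmt",
    "write_gmt",
    "read_yields",
    "PipelineConfig",
    "run_pipeline",
]


def _read_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate ids in {path}: {list(dups[:5])}")
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path).set_index("sample_id")
    for col in ("genotype", "condition"):
        if col not in samples.columns:
            raise ValueError(f"sample sheet {path} is missing column {col!r}")
    return samples


def read_counts(
    counts_path: str | Path,
    samples_path: str | Path,
    lengths_path: str | Path,
) -> CountMatrix:
    counts = _read_matrix(counts_path, "gene_id")
    samples = read_samples(samples_path)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts=counts, samples=samples, gene_lengths=lengths)


def write_counts(
    cm: CountMatrix,
    counts_path: str | Path,
    samples_path: str | Path,
    lengths_path: str | Path,
) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        samples_path, index=False
    )
    cm.gene_lengths.rename("length_bp").to_frame().to_csv(lengths_path, sep="\t")


def read_metabolites(
    metabolites_path: str | Path, samples_path: str | Path
) -> MetaboliteMatrix:
    df = _read_matrix(metabolites_path, "metabolite_id")
    classes = None
    if "class" in df.columns:
        classes = df["class"]
        df = df.drop(columns=["class"])
    samples = read_samples(samples_path)
    return MetaboliteMatrix(
        intensities=df.astype(float), samples=samples, classes=classes
    )


def write_metabolites(mm: MetaboliteMatrix, path: str | Path) -> None:
    out = mm.intensities.copy()
    out.insert(0, "class", mm.classes)
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need term, description, genes): {line[:60]!r}")
        terms[parts[0]] = set(parts[2:])
    return terms


def write_gmt(
    terms: dict[str, list[str] | set[str]],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    lines = []
    for term, genes in terms.items():
        desc = descriptions.get(term, "na")
        lines.append("\t".join([term, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_yields(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"variety", "treatment", "grain_yield_kg_ha"}
    if not required.issubset(df.columns):
        raise ValueError(f"yield table {path} must have columns {sorted(required)}")
    return df


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for the end-to-end run.

    Threshold defaults are the published screen values: |log2FC| > 1 with
    adjusted p < 0.05 for DEGs, FPKM sum > 1 for expressed genes,
    fold-change ratio > 2 for the frontloading screen, VIP >= 1 with
    |log2FC| >= 1 for DEMs, cor^2 > 0.9 with p < 0.05 for network edges,
    k = 4 gene clusters and k = 9 metabolite clusters.
    """

    counts: str = "counts.tsv"
    samples: str = "samples.csv"
    gene_lengths: str = "gene_lengths.tsv"
    metabolites: str = "metabolites.tsv"
    annotations: str | None = "annotations.gmt"
    yields: str | None = "yields.csv"
    outdir: str = "results"

    tolerant: str = "tolerant"
    susceptible: str = "susceptible"
    log2fc: float = 1.0
    padj: float = 0.05
    fpkm_sum: float = 1.0
    fc_ratio: float = 2.0
    vip: float = 1.0
    dem_log2fc: float = 1.0
    r2: float = 0.9
    alpha: float = 0.05
    k_genes: int = 4
    k_metabolites: int = 9
    elbow_range: tuple[int, int] = (1, 8)
    n_perm: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("log2fc", "padj", "fpkm_sum", "fc_ratio", "vip",
                     "dem_log2fc", "r2", "alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "elbow_range" in data:
            data["elbow_range"] = tuple(data["elbow_range"])
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured inputs and write all artifacts.

    Deterministic given ``config.seed``.  Returns the run manifest (also
    written as manifest.json) listing versions, seeds, thresholds and the
    emitted stage outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> Path:
        artifacts[name] = str(path)
        return path

    logger.info("reading inputs")
    cm = read_counts(config.counts, config.samples, config.gene_lengths)
    mm = read_metabolites(config.metabolites, config.samples)

    # expression, filtering, QC
    expr = fpkm(cm)
    expressed = filter_expressed(expr, threshold=config.fpkm_sum)
    expr_f = type(expr)(expr.fpkm.loc[expressed], expr.samples)
    qc = sample_qc(expr_f)
    qc.spearman.to_csv(emit("qc_spearman", out / "qc_spearman.tsv"), sep="\t")
    (out / "qc_pca.json").write_text(
        json.dumps(
            {
                "variance_explained_pct": [float(v) for v in qc.pca_variance_pct],
                "min_within_genotype_spearman": qc.min_within_group(expr_f.samples),
            },
            indent=1,
        )
    )
    emit("qc_pca", out / "qc_pca.json")

    # differential expression per genotype
    cm_f = CountMatrix(cm.counts.loc[expressed], cm.samples, cm.gene_lengths)
    de = {}
    for label, genotype in (("tolerant", config.tolerant), ("susceptible", config.susceptible)):
        res = nb_wald_test(cm_f, genotype)
        de[label] = res
        res.table.to_csv(emit(f"de_{label}", out / f"de_{label}.tsv"), sep="\t")

    # response categories, Venn, frontloading screen
    responses = classify_responses(de["tolerant"], de["susceptible"])
    venn = venn_summary(responses)
    (out / "venn_summary.json").write_text(json.dumps(venn, indent=1))
    emit("venn_summary", out / "venn_summary.json")
    screen = frontload_screen(
        expr_f, responses, ratio_threshold=config.fc_ratio
    )
    screen.to_csv(emit("frontload_screen", out / "frontload_screen.tsv"), sep="\t")

    # clustering of the DEG union + elbow diagnostics
    deg_union = responses.index[responses["category"] != "none"]
    manifest_extra = {}
    if len(deg_union) >= max(config.k_genes, 2):
        profiles = scaled_group_profiles(expr_f, genes=deg_union)
        clusters = kmeans_clusters(profiles, k=config.k_genes, seed=config.seed)
        clusters.assignments.to_frame().to_csv(
            emit("clusters", out / "clusters.tsv"), sep="\t"
        )
        lo, hi = config.elbow_range
        elbow = elbow_curve(profiles, range(lo, hi + 1), seed=config.seed,
                            default_k=config.k_genes)
        (out / "elbow.json").write_text(
            json.dumps(
                {
                    "k": elbow.ks,
                    "wss": elbow.wss,
                    "suggested_k": elbow.suggested_k,
                    "low_confidence": elbow.low_confidence,
                },
                indent=1,
            )
        )
        emit("elbow", out / "elbow.json")
    else:
        manifest_extra["clusters_skipped"] = f"only {len(deg_union)} DEGs"

    # term enrichment of the DEG union against the expressed universe
    if config.annotations:
        terms = read_gmt(config.annotations)
        enrich = hypergeom_enrich(deg_union, expressed, terms, alpha=config.padj)
        enrich.to_csv(emit("enrichment", out / "enrichment.tsv"), sep="\t", index=False)

    # metabolomics: OPLS-DA per genotype, DEM calls, DEM clustering
    oplsda_summary = {}
    dems = {}
    for label, genotype in (("tolerant", config.tolerant), ("susceptible", config.susceptible)):
        sub = mm.subset_samples(mm.samples["genotype"] == genotype)
        X = preprocess(sub).T
        y = sub.samples["condition"]
        model = OPLSDA(X, y, n_ortho=1)
        res = model.fit(seed=config.seed)
        perm = permutation_test(model, n_perm=config.n_perm, seed=config.seed)
        oplsda_summary[label] = {
            "R2X": res.r2x,
            "R2Y": res.r2y,
            "Q2": res.q2,
            "permutation_p": perm.p_value,
            "n_permutations": config.n_perm,
        }
        dems[label] = call_dems(
            sub, res.vip, log2fc_threshold=config.dem_log2fc, vip_threshold=config.vip
        )
    (out / "oplsda_summary.json").write_text(json.dumps(oplsda_summary, indent=1))
    emit("oplsda_summary", out / "oplsda_summary.json")
    dem_table = pd.concat(dems, names=["genotype_role"]).reset_index()
    dem_table.to_csv(emit("dems", out / "dems.tsv"), sep="\t", index=False)

    dem_union = sorted(
        set(dems["tolerant"].index[dems["tolerant"]["call"] != "ns"])
        | set(dems["susceptible"].index[dems["susceptible"]["call"] != "ns"])
    )
    if len(dem_union) >= config.k_metabolites:
        met_clusters = metabolite_kmeans(
            mm, dem_union, k=config.k_metabolites, seed=config.seed
        )
        met_clusters.assignments.to_frame().to_csv(
            emit("met_clusters", out / "met_clusters.tsv"), sep="\t"
        )
    else:
        manifest_extra["met_clusters_skipped"] = f"only {len(dem_union)} DEMs"

    # gene-metabolite correlation network over matched samples
    net = correlation_network(
        expr_f, mm, genes=deg_union, r2_threshold=config.r2, alpha=config.alpha
    )
    net.edges.to_csv(emit("network", out / "network.tsv"), sep="\t", index=False)
    nx.write_graphml(net.to_graph(), out / "network.graphml")
    emit("network_graphml", out / "network.graphml")
    (out / "network_summary.json").write_text(json.dumps(network_summary(net), indent=1))
    emit("network_summary", out / "network_summary.json")

    # agronomic coefficients
    if config.yields:
        table = heat_tolerance_table(read_yields(config.yields))
        table.to_csv(emit("yield_summary", out / "yield_summary.csv"), index=False)

    manifest = {
        "package": "heatomics",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "log2fc": config.log2fc,
            "padj": config.padj,
            "fpkm_sum": config.fpkm_sum,
            "fc_ratio": config.fc_ratio,
            "vip": config.vip,
            "dem_log2fc": config.dem_log2fc,
            "r2": config.r2,
            "alpha": config.alpha,
            "k_genes": config.k_genes,
            "k_metabolites": config.k_metabolites,
        },
        "n_genes": int(cm.counts.shape[0]),
        "n_expressed": int(len(expressed)),
        "n_metabolites": int(mm.intensities.shape[0]),
        "venn": venn,
        "artifacts": artifacts,
        **manifest_extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
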