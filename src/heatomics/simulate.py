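"""Synthetic dual-omics data with planted ground truth.

Emulates the study design every downstream stage expects: two genotypes
(heat ``tolerant`` and heat ``susceptible``), two conditions (``CK`` control,
``HS`` heat stress), a few biological replicates each, negative-binomial
gene counts with planted response classes, and a log-normal metabolite table
with planted differential metabolites.

Planted gene classes
--------------------
common_up / common_down
    Heat changes expression by +-effect_size_log2fc in both genotypes.
unique_susceptible_up / unique_susceptible_down
    Heat response only in the susceptible genotype.
frontloaded
    Tolerant baseline is ``frontload_baseline_ratio`` times the susceptible
    baseline and does not respond to heat; the susceptible genotype is
    induced by 2^effect_size_log2fc.
stress_indicator
    Repressed under heat only in the susceptible genotype, equal baselines.
null
    No planted effect (everything not otherwise assigned).

The generator is fully reproducible given ``rng_seed`` and never reads
external data.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .agronomics import GRAIN_YIELDS
from .de import CountMatrix
from .metabolome import MetaboliteMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_metabolites",
    "write_fixture_bundle",
]

GENE_CLASSES = (
    "common_up",
    "common_down",
    "unique_susceptible_up",
    "unique_susceptible_down",
    "frontloaded",
    "stress_indicator",
)
MET_CLASSES = ("common_up", "common_down", "unique_susceptible_up", "unique_susceptible_down")
COMPOUND_CLASSES = (
    "lipids",
    "flavonoids",
    "phenolic acids",
    "saccharides",
    "organic acids",
    "alkaloids",
    "amino acids and derivatives",
    "other",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth design of the synthetic dual-omics experiment.

    NB counts use the var = mu + dispersion * mu^2 parameterization.
    Baselines are log-normal on the natural-log scale; the per-gene means
    are rescaled so an average library holds ~``mean_library_size`` reads,
    and per-sample depths vary log-normally around that
    (``library_size_log_sd``).  Metabolite intensities are log-normal on the
    log2 scale with planted |log2FC| = ``met_effect_log2fc`` between CK and
    HS within a genotype.
    """

    n_genes: int = 2000
    n_metabolites: int = 500
    n_reps: int = 3
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    planted: dict[str, int] = field(
        default_factory=lambda: {
            "common_up": 50,
            "common_down": 50,
            "unique_susceptible_up": 50,
            "unique_susceptible_down": 50,
            "frontloaded": 50,
            "stress_indicator": 50,
        }
    )
    effect_size_log2fc: float = 2.0
    frontload_baseline_ratio: float = 4.0
    mean_library_size: float = 1e6
    library_size_log_sd: float = 0.2
    gene_length_range: tuple[int, int] = (500, 5000)
    met_planted: dict[str, int] = field(
        default_factory=lambda: {
            "common_up": 15,
            "common_down": 15,
            "unique_susceptible_up": 15,
            "unique_susceptible_down": 15,
        }
    )
    met_effect_log2fc: float = 2.0
    met_baseline_log2_mean: float = 17.0
    met_baseline_log2_sd: float = 2.0
    met_noise_log2_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        if not self.effect_size_log2fc > 1:
            raise ValueError(
                "effect_size_log2fc must exceed 1 (the DE call threshold) "
                "for planted effects to be recoverable"
            )
        unknown = set(self.planted) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted gene classes: {sorted(unknown)}")
        if sum(self.planted.values()) > self.n_genes:
            raise ValueError("planted gene class counts exceed n_genes")
        unknown_m = set(self.met_planted) - set(MET_CLASSES)
        if unknown_m:
            raise ValueError(f"unknown planted metabolite classes: {sorted(unknown_m)}")
        if sum(self.met_planted.values()) > self.n_metabolites:
            raise ValueError("planted metabolite counts exceed n_metabolites")


@dataclass
class GroundTruth:
    """Planted truth: class per feature and true per-genotype log2 fold changes."""

    gene_class: dict[str, str] = field(default_factory=dict)
    true_log2fc: pd.DataFrame | None = None
    met_status: dict[str, dict[str, str]] = field(default_factory=dict)

    def genes_in_class(self, klass: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == klass]

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(self.gene_class.values()))

    def met_class_counts(self) -> dict[str, int]:
        return dict(Counter(d["planted"] for d in self.met_status.values()))

    def to_dict(self) -> dict:
        out = {
            "gene_class": self.gene_class,
            "gene_class_counts": self.class_counts(),
            "met_status": self.met_status,
            "met_class_counts": self.met_class_counts(),
        }
        if self.true_log2fc is not None:
            out["true_log2fc"] = {
                g: {c: float(v) for c, v in row.items()}
                for g, row in self.true_log2fc.iterrows()
                if (row != 0).any()
            }
        return out


def _sample_sheet(n_reps: int) -> pd.DataFrame:
    rows = []
    for genotype, code in (("tolerant", "T"), ("susceptible", "S")):
        for condition in ("CK", "HS"):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{code}_{condition}_{rep}",
                        "genotype": genotype,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _assign_classes(rng, n_features: int, planted: dict[str, int], prefix: str):
    ids = [f"{prefix}{i + 1:05d}" for i in range(n_features)]
    order = rng.permutation(n_features)
    classes = {}
    pos = 0
    for klass in sorted(planted):
        for _ in range(planted[klass]):
            classes[ids[order[pos]]] = klass
            pos += 1
    for i in order[pos:]:
        classes[ids[i]] = "null"
    return ids, classes


def _nb_draw(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the NB count matrix for the 2x2x``n_reps`` design."""
    rng = np.random.default_rng([config.rng_seed, 0])
    samples = _sample_sheet(config.n_reps)
    ids, classes = _assign_classes(rng, config.n_genes, config.planted, "G")

    base = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    )
    base *= config.mean_library_size / base.sum()

    eff = 2.0**config.effect_size_log2fc
    # per-gene multiplier for each genotype x condition group
    mult = {g: np.ones(config.n_genes) for g in
            ("tolerant_CK", "tolerant_HS", "susceptible_CK", "susceptible_HS")}
    true_fc = pd.DataFrame(
        0.0, index=ids, columns=["tolerant", "susceptible"]
    )
    for i, gid in enumerate(ids):
        klass = classes[gid]
        if klass == "null":
            continue
        if klass == "common_up":
            mult["tolerant_HS"][i] = mult["susceptible_HS"][i] = eff
            true_fc.loc[gid] = config.effect_size_log2fc
        elif klass == "common_down":
            mult["tolerant_HS"][i] = mult["susceptible_HS"][i] = 1.0 / eff
            true_fc.loc[gid] = -config.effect_size_log2fc
        elif klass == "unique_susceptible_up":
            mult["susceptible_HS"][i] = eff
            true_fc.loc[gid, "susceptible"] = config.effect_size_log2fc
        elif klass == "unique_susceptible_down":
            mult["susceptible_HS"][i] = 1.0 / eff
            true_fc.loc[gid, "susceptible"] = -config.effect_size_log2fc
        elif klass == "frontloaded":
            ratio = config.frontload_baseline_ratio
            mult["tolerant_CK"][i] = mult["tolerant_HS"][i] = ratio
            mult["susceptible_HS"][i] = eff
            true_fc.loc[gid, "susceptible"] = config.effect_size_log2fc
        elif klass == "stress_indicator":
            mult["susceptible_HS"][i] = 1.0 / eff
            true_fc.loc[gid, "susceptible"] = -config.effect_size_log2fc

    depth = np.exp(rng.normal(0.0, config.library_size_log_sd, len(samples)))
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, (sid, row) in enumerate(samples.iterrows()):
        group = f"{row['genotype']}_{row['condition']}"
        mu = base * mult[group] * depth[j]
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"),
                            columns=samples.index),
        samples=samples,
        gene_lengths=pd.Series(lengths, index=ids, name="length_bp"),
    )
    truth = GroundTruth(gene_class=classes, true_log2fc=true_fc)
    return cm, truth


def simulate_metabolites(config: SimulationConfig) -> tuple[MetaboliteMatrix, GroundTruth]:
    """Simulate the log-normal metabolite intensity table with planted DEMs."""
    rng = np.random.default_rng([config.rng_seed, 1])
    samples = _sample_sheet(config.n_reps)
    ids, classes = _assign_classes(rng, config.n_metabolites, config.met_planted, "M")

    base_log2 = rng.normal(
        config.met_baseline_log2_mean, config.met_baseline_log2_sd, config.n_metabolites
    )
    e = config.met_effect_log2fc
    shift = {g: np.zeros(config.n_metabolites) for g in
             ("tolerant_CK", "tolerant_HS", "susceptible_CK", "susceptible_HS")}
    status: dict[str, dict[str, str]] = {}
    for i, mid in enumerate(ids):
        klass = classes[mid]
        tol, sus = "ns", "ns"
        if klass == "common_up":
            shift["tolerant_HS"][i] = shift["susceptible_HS"][i] = e
            tol = sus = "up"
        elif klass == "common_down":
            shift["tolerant_HS"][i] = shift["susceptible_HS"][i] = -e
            tol = sus = "down"
        elif klass == "unique_susceptible_up":
            shift["susceptible_HS"][i] = e
            sus = "up"
        elif klass == "unique_susceptible_down":
            shift["susceptible_HS"][i] = -e
            sus = "down"
        status[mid] = {"planted": klass, "tolerant": tol, "susceptible": sus}

    vals = np.empty((config.n_metabolites, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        group = f"{row['genotype']}_{row['condition']}"
        log2_level = base_log2 + shift[group] + rng.normal(
            0.0, config.met_noise_log2_sd, config.n_metabolites
        )
        vals[:, j] = 2.0**log2_level

    compound = pd.Series(
        rng.choice(COMPOUND_CLASSES, size=config.n_metabolites),
        index=pd.Index(ids, name="metabolite_id"),
        name="class",
    )
    mm = MetaboliteMatrix(
        intensities=pd.DataFrame(
            vals, index=pd.Index(ids, name="metabolite_id"), columns=samples.index
        ),
        samples=samples,
        classes=compound,
    )
    return mm, GroundTruth(met_status=status)


def _annotation_terms(rng, truth: GroundTruth, all_genes: list[str], n_random: int = 10):
    """Planted-class terms plus random terms, for exercising enrichment."""
    terms = {}
    for klass in GENE_CLASSES:
        members = truth.genes_in_class(klass)
        if members:
            terms[f"PLANTED_{klass.upper()}"] = sorted(members)
    for i in range(n_random):
        size = min(int(rng.integers(20, 80)), max(1, len(all_genes) // 2))
        terms[f"RANDOM_{i + 1:02d}"] = sorted(
            rng.choice(all_genes, size=size, replace=False)
        )
    return terms


def write_fixture_bundle(
    directory: str | Path, config: SimulationConfig | None = None
) -> dict[str, Path]:
    """Simulate both omics layers and write the full text fixture bundle.

    Emits counts.tsv, samples.csv, gene_lengths.tsv, metabolites.tsv,
    annotations.gmt, yields.csv and truth.json into ``directory``; all
    formats round-trip through the io module losslessly.
    """
    if config is None:
        config = SimulationConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    cm, gene_truth = simulate_counts(config)
    mm, met_truth = simulate_metabolites(config)
    rng = np.random.default_rng([config.rng_seed, 2])
    terms = _annotation_terms(rng, gene_truth, list(cm.gene_ids))

    paths = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.csv",
        "gene_lengths": directory / "gene_lengths.tsv",
        "metabolites": directory / "metabolites.tsv",
        "annotations": directory / "annotations.gmt",
        "yields": directory / "yields.csv",
        "truth": directory / "truth.json",
    }
    hio.write_counts(cm, paths["counts"], paths["samples"], paths["gene_lengths"])
    hio.write_metabolites(mm, paths["metabolites"])
    hio.write_gmt(terms, paths["annotations"])
    GRAIN_YIELDS.to_csv(paths["yields"], index=False)

    truth = GroundTruth(
        gene_class=gene_truth.gene_class,
        true_log2fc=gene_truth.true_log2fc,
        met_status=met_truth.met_status,
    )
    payload = truth.to_dict()
    payload["config"] = dataclasses.asdict(config)
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
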