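"""Genotype-comparative response classification and the frontloading screen.

Differential-expression calls from the tolerant and susceptible genotypes are
combined gene-by-gene into common / unique / discordant response categories
(the Venn logic), and the genes that respond only in the susceptible genotype
are screened for two patterns of constitutive defence:

* frontloaded -- induced under heat only in the susceptible genotype while
  the tolerant genotype already expresses the gene at a higher baseline
  (fold-change ratio > 2 between genotypes and susceptible/tolerant control
  ratio < 1);
* stress indicator -- strongly repressed under heat only in the susceptible
  genotype (fold-change ratio > 2), suggesting the tolerant genotype
  experienced less physiological stress.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .de import DEResults, ExpressionMatrix

__all__ = [
    "classify_responses",
    "venn_summary",
    "frontload_screen",
]

CATEGORIES = (
    "common_up",
    "common_down",
    "unique_tolerant",
    "unique_susceptible",
    "discordant",
    "none",
)


def _calls(de) -> pd.Series:
    if isinstance(de, DEResults):
        return de.table["call"]
    if isinstance(de, pd.DataFrame):
        return de["call"]
    return pd.Series(de)


def classify_responses(de_tolerant, de_susceptible) -> pd.DataFrame:
    """Combine per-genotype DE calls into response categories.

    Both inputs must cover the same gene universe.  Returns a DataFrame
    indexed by gene_id with columns ``call_tolerant``, ``call_susceptible``
    and ``category``.
    """
    ct, cs = _calls(de_tolerant), _calls(de_susceptible)
    only_t = ct.index.difference(cs.index)
    only_s = cs.index.difference(ct.index)
    if len(only_t) or len(only_s):
        raise ValueError(
            "gene universes differ between genotypes; "
            f"missing from susceptible: {list(only_t[:5])}, "
            f"missing from tolerant: {list(only_s[:5])}"
        )
    cs = cs.reindex(ct.index)
    t, s = ct.to_numpy(), cs.to_numpy()
    category = np.full(len(t), "none", dtype=object)
    category[(t == "up") & (s == "up")] = "common_up"
    category[(t == "down") & (s == "down")] = "common_down"
    category[(t != "ns") & (s == "ns")] = "unique_tolerant"
    category[(t == "ns") & (s != "ns")] = "unique_susceptible"
    category[((t == "up") & (s == "down")) | ((t == "down") & (s == "up"))] = "discordant"
    return pd.DataFrame(
        {"call_tolerant": t, "call_susceptible": s, "category": category},
        index=ct.index.rename("gene_id"),
    )


def venn_summary(responses: pd.DataFrame) -> dict[str, int]:
    """Category counts over the gene universe (all categories present, zero-filled)."""
    counts = Counter(responses["category"])
    return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}


def frontload_screen(
    expr: ExpressionMatrix,
    responses: pd.DataFrame,
    ratio_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Screen unique-susceptible genes for frontloaded / stress-indicator patterns.

    For each gene responding only in the susceptible genotype, replicate
    group means of FPKM (+``pseudocount``) give per-genotype heat/control
    fold changes ``fc_tolerant`` and ``fc_susceptible``.  The fold-change
    ratio is oriented so that values > 1 always mean "stronger response in
    the susceptible genotype": fc_susceptible / fc_tolerant for up-regulated
    candidates and fc_tolerant / fc_susceptible for down-regulated ones.
    ``control_ratio`` and ``heat_ratio`` compare susceptible to tolerant
    expression under control and heat.

    Classification:

    * ``frontloaded``: up-regulated candidate with fc_ratio > threshold and
      control_ratio < 1 (tolerant baseline higher);
    * ``stress_indicator``: down-regulated candidate with
      fc_ratio > threshold;
    * otherwise ``neither``.
    """
    means = expr.group_means(pseudocount=pseudocount)
    needed = {"tolerant_CK", "tolerant_HS", "susceptible_CK", "susceptible_HS"}
    missing = needed - set(means.columns)
    if missing:
        raise ValueError(f"expression matrix lacks groups: {sorted(missing)}")

    cand = responses[responses["category"] == "unique_susceptible"]
    m = means.loc[cand.index]
    fc_t = m["tolerant_HS"] / m["tolerant_CK"]
    fc_s = m["susceptible_HS"] / m["susceptible_CK"]
    up = (cand["call_susceptible"] == "up").to_numpy()
    fc_ratio = np.where(up, fc_s / fc_t, fc_t / fc_s)
    control_ratio = m["susceptible_CK"] / m["tolerant_CK"]
    heat_ratio = m["susceptible_HS"] / m["tolerant_HS"]

    klass = np.full(len(cand), "neither", dtype=object)
    klass[up & (fc_ratio > ratio_threshold) & (control_ratio.to_numpy() < 1.0)] = "frontloaded"
    klass[~up & (fc_ratio > ratio_threshold)] = "stress_indicator"

    return pd.DataFrame(
        {
            "fc_tolerant": fc_t,
            "fc_susceptible": fc_s,
            "fc_ratio": fc_ratio,
            "control_ratio": control_ratio,
            "heat_ratio": heat_ratio,
            "klass": klass,
        },
        index=cand.index,
    )
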