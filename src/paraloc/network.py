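"""Network-feature association of redistribution.

Bins paralogs by protein-protein-interaction and genetic-interaction network
features (shared interactors vs the cohort median, shortest path 1 vs 1+,
within-pair genetic interaction at the stringent threshold, trigenic
fraction class), tests redistribution-score differences between bins with
two-sided Mann-Whitney U tests, tests enrichment of colocalized private
interactors among redistributed proteins with Fisher's exact test, and
correlates morphology features with embedding features by Spearman rank
correlation.

Edge tables are consumed as normalized CSV-style frames (gene_a, gene_b,
plus system_type/throughput for PPI or epsilon/p for genetic interactions);
provider-specific download/parsing is out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from paraloc.abundance import fdr_bh

logger = logging.getLogger(__name__)

GI_LEVELS = ("lenient", "intermediate", "stringent", "synthetic_lethal")


def filter_ppi(edges: pd.DataFrame, study_whitelist: set[str] | None = None) -> pd.DataFrame:
    """Keep physical, high-throughput edges; drop self-loops.

    ``study_whitelist`` optionally restricts to specific study identifiers
    (the high-throughput criterion on real data is a citation whitelist).
    """
    df = edges.copy()
    if "system_type" in df.columns:
        df = df[df["system_type"] == "physical"]
    if "throughput" in df.columns:
        df = df[df["throughput"] == "high"]
    if study_whitelist is not None and "study_id" in df.columns:
        df = df[df["study_id"].isin(study_whitelist)]
    return df[df["gene_a"] != df["gene_b"]].reset_index(drop=True)


def ppi_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
    return g


def gi_subset(edges: pd.DataFrame, level: str) -> pd.DataFrame:
    """Genetic-interaction confidence subsets.

    lenient: p < 0.05; intermediate: p < 0.05 and |ε| > 0.08; stringent:
    p < 0.05 and (ε > 0.16 or ε < −0.12); synthetic_lethal: p < 0.05 and
    ε < −0.35.
    """
    if level not in GI_LEVELS:
        raise ValueError(f"unknown GI level {level!r}; expected one of {GI_LEVELS}")
    p = edges["p"]
    eps = edges["epsilon"]
    keep = p < 0.05
    if level == "intermediate":
        keep &= eps.abs() > 0.08
    elif level == "stringent":
        keep &= (eps > 0.16) | (eps < -0.12)
    elif level == "synthetic_lethal":
        keep &= eps < -0.35
    return edges[keep].reset_index(drop=True)


def shared_interactors(graph: nx.Graph, pair: tuple[str, str]) -> int:
    """|N(a) ∩ N(b)| excluding the pair members themselves."""
    a, b = pair
    na = set(graph.neighbors(a)) if a in graph else set()
    nb = set(graph.neighbors(b)) if b in graph else set()
    return len((na & nb) - {a, b})


def bin_by_median(counts: dict[str, int]) -> dict[str, str]:
    """low/high split at the cohort median; ties go to low (and are logged)."""
    values = np.array(list(counts.values()), dtype=float)
    med = float(np.median(values))
    ties = [k for k, v in counts.items() if v == med]
    if ties:
        logger.info("median split: %d entries equal the median (%s), assigned low", len(ties), med)
    return {k: ("high" if v > med else "low") for k, v in counts.items()}


def shortest_path_class(graph: nx.Graph, pair: tuple[str, str]) -> tuple[str, float]:
    """('1' or '1+', raw BFS length); disconnected or absent genes → 1+ with nan."""
    a, b = pair
    if a not in graph or b not in graph:
        logger.warning("pair (%s, %s): gene absent from network", a, b)
        return "1+", float("nan")
    try:
        length = nx.shortest_path_length(graph, a, b)
    except nx.NetworkXNoPath:
        return "1+", math.inf
    return ("1" if length == 1 else "1+"), float(length)


def jaccard_colocalized(set_a: set[str], set_b: set[str]) -> tuple[float, bool]:
    """Jaccard index on the 0–100 scale; colocalized when >= 50."""
    if not set_a or not set_b:
        raise ValueError("localization sets must be nonempty")
    index = 100.0 * len(set_a & set_b) / len(set_a | set_b)
    return index, index >= 50.0


def private_interactors(graph: nx.Graph, pair: tuple[str, str]) -> tuple[set[str], set[str]]:
    """Neighbors unique to each member, excluding the sister itself."""
    a, b = pair
    na = set(graph.neighbors(a)) if a in graph else set()
    nb = set(graph.neighbors(b)) if b in graph else set()
    return na - nb - {b}, nb - na - {a}


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float | None  # None when a margin is zero; inf when only b*c = 0
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def enrichment_fisher(flag_a, flag_b) -> FisherResult:
    """Association of two boolean per-protein labels.

    Sample odds ratio (a·d)/(b·c) with two-sided Fisher exact p on the 2x2
    table; a zero margin leaves the odds ratio undefined (reported missing).
    """
    x = np.asarray(flag_a, dtype=bool)
    y = np.asarray(flag_b, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("label vectors must align")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return FisherResult(odds_ratio=None, p=1.0, table=table)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if b * c == 0:
        oratio = math.inf if a * d > 0 else 0.0
    else:
        oratio = (a * d) / (b * c)
    return FisherResult(odds_ratio=oratio, p=p, table=table)


def group_compare(scores: dict[str, float], binning: dict[str, str]) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test of scores between each pair of bins.

    One comparison per unordered bin pair; comparisons with an empty bin
    are skipped with a log message.
    """
    labels = sorted(set(binning.values()))
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            xa = np.array([scores[k] for k, v in binning.items() if v == la and k in scores])
            xb = np.array([scores[k] for k, v in binning.items() if v == lb and k in scores])
            if xa.size == 0 or xb.size == 0:
                logger.warning("group_compare: empty bin in (%s, %s), skipped", la, lb)
                continue
            if np.unique(np.concatenate([xa, xb])).size == 1:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            rows.append(
                {
                    "bin_a": la,
                    "bin_b": lb,
                    "n_a": xa.size,
                    "n_b": xb.size,
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def morphology_correlation(morph: pd.DataFrame, embeddings: pd.DataFrame) -> dict:
    """Spearman ρ between each morphology feature and each embedding feature.

    Returns the ρ and p matrices (morphology features × embedding features)
    plus the fraction of pairs significant after Benjamini-Hochberg at 5%.
    Constant columns yield missing ρ.
    """
    if len(morph) != len(embeddings):
        raise ValueError("morphology and embedding tables must align cell-for-cell")
    mcols, ecols = list(morph.columns), list(embeddings.columns)
    rho = pd.DataFrame(np.nan, index=mcols, columns=ecols)
    pmat = pd.DataFrame(np.nan, index=mcols, columns=ecols)
    for mc in mcols:
        x = morph[mc].to_numpy(dtype=float)
        if np.unique(x).size == 1:
            continue
        for ec in ecols:
            y = embeddings[ec].to_numpy(dtype=float)
            if np.unique(y).size == 1:
                continue
            r, p = stats.spearmanr(x, y)
            rho.loc[mc, ec] = r
            pmat.loc[mc, ec] = p
    flat = pmat.to_numpy().ravel()
    q = fdr_bh(flat)
    ok = ~np.isnan(q)
    frac = float(np.mean(q[ok] < 0.05)) if ok.any() else float("nan")
    return {"rho": rho, "p": pmat, "fraction_significant": frac}
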