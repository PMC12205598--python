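"""Protein abundance quantification and fold-change statistics.

The abundance score of a condition is the grand mean raw pixel intensity
over all pixels of all 64x64 cell frames in that condition (raw =
background-subtracted, never log-standardized).  Relative change upon
paralog deletion is the difference of log2(score + 1) between backgrounds;
significance comes from a two-sided Mann-Whitney U test on per-cell mean
intensities pooled across replicates, corrected by Benjamini-Hochberg.
A protein is classified as increased (decreased) when log2 fold change is
>= 0.2 (<= -0.2) with q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2FC_THRESHOLD = 0.2
Q_THRESHOLD = 0.05
MIN_CELLS = 3


@dataclass(frozen=True)
class AbundanceRecord:
    protein: str
    score_wt: float
    score_del: float
    log2fc: float
    p: float  # nan when too few cells
    q: float
    abundance_class: str  # increase | decrease | ns


def abundance_score(frames: list[np.ndarray]) -> float:
    """Pixel-weighted grand mean over all pixels of all frames."""
    if len(frames) == 0:
        raise ValueError("abundance score requires at least one frame")
    total = 0.0
    n = 0
    for f in frames:
        f = np.asarray(f, dtype=float)
        total += f.sum()
        n += f.size
    return total / n


def log2fc(score_wt: float, score_del: float) -> float:
    """log2(score_del + 1) - log2(score_wt + 1); positive = increase upon deletion."""
    if score_wt < 0 or score_del < 0:
        raise ValueError("abundance scores must be nonnegative")
    return float(np.log2(score_del + 1.0) - np.log2(score_wt + 1.0))


def abundance_test(per_cell_wt, per_cell_del) -> float:
    """Two-sided Mann-Whitney U p-value on per-cell mean intensities.

    Returns nan (flagged missing) when either group has fewer than 3 cells;
    completely tied data yield p = 1 under the tie convention.
    """
    x = np.asarray(per_cell_wt, dtype=float)
    y = np.asarray(per_cell_del, dtype=float)
    if x.size < MIN_CELLS or y.size < MIN_CELLS:
        return float("nan")
    if np.unique(np.concatenate([x, y])).size == 1:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    nan entries (tests flagged missing upstream) are passed through as nan
    and excluded from the correction's m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def classify_abundance(
    lfc: float,
    q: float,
    lfc_threshold: float = LOG2FC_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> str:
    """increase / decrease / ns under the |log2fc| >= 0.2 and q < 0.05 rule."""
    if np.isnan(q):
        return "ns"
    if q < q_threshold and lfc >= lfc_threshold:
        return "increase"
    if q < q_threshold and lfc <= -lfc_threshold:
        return "decrease"
    return "ns"


def abundance_table(
    per_cell: pd.DataFrame,
    value_col: str = "mean_raw_intensity",
) -> pd.DataFrame:
    """Per-protein abundance records from a per-cell table.

    ``per_cell`` needs columns protein, background (WT/DELETION) and
    ``value_col`` (per-cell mean raw intensity); cells are pooled across
    replicates.  Returns one row per protein with scores, log2fc, p, q and
    class.
    """
    rows = []
    for protein, grp in per_cell.groupby("protein", sort=True):
        wt = grp.loc[grp["background"] == "WT", value_col].to_numpy()
        de = grp.loc[grp["background"] == "DELETION", value_col].to_numpy()
        if wt.size == 0 or de.size == 0:
            continue
        s_wt, s_del = float(wt.mean()), float(de.mean())
        rows.append(
            {
                "protein": protein,
                "score_wt": s_wt,
                "score_del": s_del,
                "n_cells_wt": wt.size,
                "n_cells_del": de.size,
                "log2fc": log2fc(s_wt, s_del),
                "p": abundance_test(wt, de),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = fdr_bh(df["p"].to_numpy())
    df["abundance_class"] = [
        classify_abundance(l, q) for l, q in zip(df["log2fc"], df["q"])
    ]
    return df
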