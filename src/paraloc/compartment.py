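"""Two-channel per-cell compartment quantification (GFP + ER marker).

The validation pipeline for ER/cytoplasm partitioning: cells are segmented
on the GFP channel, border-adjacent cells (within the median major axis
length of the image edge) are removed, images with outlying background
intensity are discarded per replicate, and within each cell the ER-marker
channel classifies pixels by intensity quantile — at or above the 0.975
quantile is ER, below the 0.973 quantile is cytoplasm, the sliver in
between stays unassigned.  Cells with fewer than 100 ER pixels are
discarded.  Normalized abundances are median intensities divided by the
image background intensity; strain differences are tested by two-sided
Mann-Whitney U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

ER_QUANTILE = 0.975
CYTO_QUANTILE = 0.973
MIN_ER_PIXELS = 100
MIN_CELL_PIXELS = 200


@dataclass(frozen=True)
class CompartmentRecord:
    cell_id: str
    strain: str
    replicate: int
    norm_abundance_cell: float | None
    norm_abundance_er: float | None
    norm_abundance_cyto: float | None
    n_er_pixels: int
    kept: bool
    rejection_reason: str = ""


def remove_edge_cells(mask: np.ndarray, image_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Drop cells within the median major-axis length of the image edge.

    The band width is the median major-axis length over all cells in the
    mask; any stencil intersecting the band is removed, so cells touching
    the border are always removed.
    """
    mask = np.asarray(mask)
    if image_shape is None:
        image_shape = mask.shape
    props = regionprops(mask)
    if not props:
        return mask.copy()
    band = float(np.median([p.axis_major_length for p in props]))
    band = max(int(round(band)), 1)
    rows, cols = image_shape
    out = mask.copy()
    for p in props:
        rmin, cmin, rmax, cmax = p.bbox  # bbox is half-open
        if rmin < band or cmin < band or rmax > rows - band or cmax > cols - band:
            out[out == p.label] = 0
    return out


def image_background(image: np.ndarray, mask: np.ndarray) -> float:
    """Background intensity of an image: median over non-cell pixels."""
    image = np.asarray(image, dtype=float)
    bg = image[np.asarray(mask) == 0]
    if bg.size == 0:
        raise ValueError("no background pixels (mask covers the full image)")
    return float(np.median(bg))


def background_qc(
    background_by_image: dict[str, float],
    replicate_by_image: dict[str, int],
    n_sd: float = 1.0,
) -> dict[str, bool]:
    """Keep/discard flags per image based on background intensity outliers.

    Within each replicate, images whose background lies outside
    mean ± n_sd·stdev (sample stdev) of the replicate's backgrounds are
    discarded.  Replicates with fewer than 3 images skip QC with a warning.
    """
    keep = {}
    reps: dict[int, list[str]] = {}
    for im, rep in replicate_by_image.items():
        reps.setdefault(rep, []).append(im)
    for rep, ims in reps.items():
        vals = np.array([background_by_image[i] for i in ims], dtype=float)
        if len(ims) < 3:
            logger.warning("replicate %s has %d images; background QC skipped", rep, len(ims))
            keep.update({i: True for i in ims})
            continue
        mu = vals.mean()
        sd = vals.std(ddof=1)
        lo, hi = mu - n_sd * sd, mu + n_sd * sd
        for i, v in zip(ims, vals):
            keep[i] = bool(lo <= v <= hi)
    return keep


def cell_abundance(cell_pixels: np.ndarray, background: float) -> float:
    """Median cell intensity divided by the image background intensity."""
    cell_pixels = np.asarray(cell_pixels, dtype=float)
    if cell_pixels.size == 0:
        raise ValueError("empty cell")
    if background <= 0:
        raise ValueError("background intensity must be positive")
    return float(np.median(cell_pixels) / background)


def compartment_masks(
    marker_pixels: np.ndarray,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Quantile-classify a cell's marker pixels into ER and cytoplasm.

    ER = intensity >= the 0.975 quantile; cytoplasm = intensity < the 0.973
    quantile; pixels in between stay unassigned (the published rule is kept
    verbatim, gap included).  Returns boolean masks over the cell's pixel
    vector, or None when the cell is too small to quantile (< 200 px) or
    has fewer than 100 ER pixels.
    """
    vals = np.asarray(marker_pixels, dtype=float)
    if vals.size < MIN_CELL_PIXELS:
        return None
    q_er = np.quantile(vals, ER_QUANTILE)
    q_cy = np.quantile(vals, CYTO_QUANTILE)
    er = vals >= q_er
    cyto = vals < q_cy
    if int(er.sum()) < MIN_ER_PIXELS:
        return None
    return er, cyto


def compartment_abundance(
    gfp_pixels: np.ndarray,
    er_mask: np.ndarray,
    cyto_mask: np.ndarray,
    background: float,
) -> tuple[float | None, float | None]:
    """Median GFP intensity within each compartment mask, over background."""
    if background <= 0:
        raise ValueError("background intensity must be positive")
    gfp = np.asarray(gfp_pixels, dtype=float)
    er_val = float(np.median(gfp[er_mask]) / background) if er_mask.any() else None
    cy_val = float(np.median(gfp[cyto_mask]) / background) if cyto_mask.any() else None
    return er_val, cy_val


def quantify_cells(
    gfp: np.ndarray,
    marker: np.ndarray,
    mask: np.ndarray,
    strain: str,
    replicate: int,
    image_id: str = "",
) -> list[CompartmentRecord]:
    """Per-cell compartment records for one (pre-QC'd) two-channel field."""
    gfp = np.asarray(gfp, dtype=float)
    marker = np.asarray(marker, dtype=float)
    mask = remove_edge_cells(np.asarray(mask))
    bg = image_background(gfp, mask)
    records: list[CompartmentRecord] = []
    for p in regionprops(mask):
        sel = mask == p.label
        cell_id = f"{image_id}_c{p.label}"
        marker_vals = marker[sel]
        gfp_vals = gfp[sel]
        masks = compartment_masks(marker_vals)
        if masks is None:
            n_er = 0
            if marker_vals.size >= MIN_CELL_PIXELS:
                n_er = int((marker_vals >= np.quantile(marker_vals, ER_QUANTILE)).sum())
            records.append(
                CompartmentRecord(
                    cell_id=cell_id,
                    strain=strain,
                    replicate=replicate,
                    norm_abundance_cell=cell_abundance(gfp_vals, bg),
                    norm_abundance_er=None,
                    norm_abundance_cyto=None,
                    n_er_pixels=n_er,
                    kept=False,
                    rejection_reason=(
                        "too_few_pixels" if marker_vals.size < MIN_CELL_PIXELS else "too_few_er_pixels"
                    ),
                )
            )
            continue
        er_mask, cyto_mask = masks
        er_val, cy_val = compartment_abundance(gfp_vals, er_mask, cyto_mask, bg)
        records.append(
            CompartmentRecord(
                cell_id=cell_id,
                strain=strain,
                replicate=replicate,
                norm_abundance_cell=cell_abundance(gfp_vals, bg),
                norm_abundance_er=er_val,
                norm_abundance_cyto=cy_val,
                n_er_pixels=int(er_mask.sum()),
                kept=True,
            )
        )
    return records


def records_frame(records: list[CompartmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def compare_strains(
    records: pd.DataFrame, value_col: str, strain_a: str = "WT", strain_b: str = "DELETION"
) -> dict:
    """Two-sided Mann-Whitney U comparison of a per-cell quantity between
    strains (kept cells only), with means and 95% CIs of the means."""
    kept = records[records["kept"]]
    xa = kept.loc[kept["strain"] == strain_a, value_col].dropna().to_numpy(dtype=float)
    xb = kept.loc[kept["strain"] == strain_b, value_col].dropna().to_numpy(dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both strains need kept cells for comparison")
    p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)

    def ci(x: np.ndarray) -> tuple[float, float]:
        if x.size < 2:
            return float("nan"), float("nan")
        sem = x.std(ddof=1) / np.sqrt(x.size)
        h = stats.t.ppf(0.975, x.size - 1) * sem
        return float(x.mean() - h), float(x.mean() + h)

    return {
        "n_a": int(xa.size),
        "n_b": int(xb.size),
        "mean_a": float(xa.mean()),
        "mean_b": float(xb.mean()),
        "ci95_a": ci(xa),
        "ci95_b": ci(xb),
        "p": p,
    }
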