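"""End-to-end screen pipeline: simulate → segment → embed → score → call.

``run_screen`` drives the full analysis on a synthetic screen and returns a
:class:`ScreenResult` bundling every intermediate table; the CLI and the
acceptance checks are thin layers over it.  Stages run in dependency order
and the per-image work is streamed (images are rendered, segmented and
reduced to per-cell records one at a time), so memory stays flat regardless
of screen size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from paraloc import abundance as ab
from paraloc import paralog_calls as calls
from paraloc import redistribution as redist
from paraloc import segmentation as seg
from paraloc import single_cell as sc
from paraloc import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """All tables produced by one screen run."""

    design: syn.ScreenDesign
    truth: pd.DataFrame
    cells: pd.DataFrame  # one row per segmented cell
    embeddings: np.ndarray  # aligned with `cells`
    scores: pd.DataFrame  # per-protein redistribution scores and flags
    threshold: redist.ThresholdResult
    abundance: pd.DataFrame
    call_table: pd.DataFrame
    pair_counts: dict[str, int]
    summary: dict
    qc: pd.DataFrame = dc_field(default_factory=pd.DataFrame)


def _segment_screen(
    images: list[syn.SyntheticImage],
    background: np.ndarray,
    segmenter_kind: str,
    n_train_images: int,
    seed: int,
):
    """Fit (if requested) and return the probability-map model."""
    if segmenter_kind == "intensity":
        return seg.IntensitySegmenter()
    if segmenter_kind != "trained":
        raise ValueError(f"unknown segmenter kind {segmenter_kind!r}")
    train_imgs, train_targets = [], []
    for im in images[:n_train_images]:
        sub = seg.subtract_background(im.pixels, background)
        try:
            norm = seg.normalize_image(sub)
        except seg.ConstantImageError:
            continue
        train_imgs.append(norm)
        train_targets.append(seg.encode_target(im.mask))
    return seg.train_segmenter(train_imgs, train_targets, seed=seed)


def run_screen(
    design: syn.ScreenDesign | None = None,
    truth: syn.SimTruth | None = None,
    seed: int = 1,
    embedder=None,
    segmenter: str = "trained",
    n_train_images: int = 6,
    use_truth_masks: bool = False,
    max_background_images: int = 64,
) -> ScreenResult:
    """Run the complete pipeline on a synthetic screen.

    Parameters largely mirror the experimental design: ``design`` defaults
    to the desk-scale screen (6 effect pairs + 2 random-pair controls,
    3 replicates x 4 fields, 60-90 cells per field) and ``truth`` to the
    default planted effects (2x abundance on one member of each effect
    pair, 0.6 relocalization on the other).  ``use_truth_masks`` bypasses
    segmentation with the generator's masks, for fast ablations.
    """
    if design is None:
        design = syn.demo_design()
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = syn.default_truth(design, rng_or_seed=rng)
    if embedder is None:
        embedder = sc.DeterministicEmbedder()

    logger.info("rendering screen: %d proteins", len(design.proteins))
    images, truth_df = syn.generate_screen(design, truth, seed=seed)

    stride = max(1, len(images) // max_background_images)
    background = seg.estimate_background([im.pixels for im in images[::stride]])

    model = None
    if not use_truth_masks:
        model = _segment_screen(images, background, segmenter, n_train_images, seed)

    cell_rows: list[dict] = []
    emb_blocks: list[np.ndarray] = []
    qc_rows: list[dict] = []
    for im in images:
        sub = seg.subtract_background(im.pixels, background)
        try:
            norm = seg.normalize_image(sub)
        except seg.ConstantImageError as exc:
            logger.warning("image %s/%s r%d f%d excluded: %s",
                           im.protein, im.background, im.replicate, im.field, exc)
            continue
        mask = im.mask if use_truth_masks else seg.segment_image(norm, model)
        frames = sc.extract_frames(
            norm.pixels,
            mask,
            raw_image=sub,
            protein=im.protein,
            background=im.background,
            replicate=im.replicate,
            field_no=im.field,
        )
        qc_rows.append(
            {
                "protein": im.protein,
                "background": im.background,
                "replicate": im.replicate,
                "field": im.field,
                "n_cells": len(frames),
                "n_cells_truth": int(im.mask.max()),
            }
        )
        if not frames:
            continue
        emb_blocks.append(embedder.embed([f.frame for f in frames]))
        for f in frames:
            row = {
                "cell_id": f.cell_id,
                "protein": f.protein,
                "background": f.background,
                "replicate": f.replicate,
                "field": f.field,
                "center_row": f.center[0],
                "center_col": f.center[1],
                "mean_raw_intensity": float(f.raw_frame.mean()),
            }
            row.update(f.morphology)
            cell_rows.append(row)

    cells = pd.DataFrame(cell_rows)
    embeddings = np.concatenate(emb_blocks) if emb_blocks else np.empty((0, sc.EMBED_DIM))
    qc = pd.DataFrame(qc_rows)

    # redistribution scores
    score_rows = []
    scores: dict[str, float] = {}
    for protein in design.proteins:
        sel_wt = (cells["protein"] == protein) & (cells["background"] == syn.WT)
        sel_del = (cells["protein"] == protein) & (cells["background"] == syn.DELETION)
        if sel_wt.sum() == 0 or sel_del.sum() == 0:
            logger.warning("protein %s missing a background; skipped", protein)
            continue
        c_wt = redist.condition_centroid(embeddings[sel_wt.to_numpy()], protein, syn.WT)
        c_del = redist.condition_centroid(embeddings[sel_del.to_numpy()], protein, syn.DELETION)
        score = redist.redistribution_score(c_wt, c_del)
        scores[protein] = score
        score_rows.append(
            {
                "protein": protein,
                "n_cells_wt": int(sel_wt.sum()),
                "n_cells_del": int(sel_del.sum()),
                "score": score,
            }
        )

    truth_map = truth.proteins
    control_proteins = [p for pair in design.controls for p in pair]
    true_proteins = [
        p for p in scores if p not in control_proteins and truth_map[p].label_redistributed
    ]
    thr = redist.select_threshold(
        [scores[p] for p in true_proteins],
        [scores[p] for p in control_proteins if p in scores],
    )
    score_df = pd.DataFrame(score_rows)
    score_df["threshold"] = thr.threshold
    score_df["flag_redistributed"] = score_df["score"] > thr.threshold

    # abundance
    abundance_df = ab.abundance_table(cells)

    # compensation / dependency calls from generator-truth annotations
    flags = dict(zip(score_df["protein"], score_df["flag_redistributed"]))
    ab_class = dict(zip(abundance_df["protein"], abundance_df["abundance_class"]))
    call_rows = []
    relocalized: dict[str, bool] = {}
    for protein in scores:
        t = truth_map[protein]
        partner = design.partner(protein)
        annotation = calls.RelocalizationAnnotation(
            protein=protein,
            relocalized=t.effect_relocalization > 0,
            destination=t.target_compartment if t.effect_relocalization > 0 else None,
            own_wt_compartment=t.wt_compartment,
            paralog_wt_compartment=truth_map[partner].wt_compartment,
        )
        relocalized[protein] = annotation.relocalized
        call = calls.call_direction(annotation, ab_class.get(protein, "ns"))
        call_rows.append(
            {
                "protein": protein,
                "reloc_call": call.reloc_call,
                "abundance_call": call.abundance_call,
                "flag_redistributed": flags.get(protein, False),
            }
        )
    call_table = pd.DataFrame(call_rows)

    pair_map = {p: design.pair_of(p) for p in scores}
    pair_counts = calls.pair_summary(flags, pair_map)
    summary = calls.screen_summary(flags, ab_class, relocalized, list(scores))

    return ScreenResult(
        design=design,
        truth=truth_df,
        cells=cells,
        embeddings=embeddings,
        scores=score_df,
        threshold=thr,
        abundance=abundance_df,
        call_table=call_table,
        pair_counts=pair_counts,
        summary=summary,
        qc=qc,
    )
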