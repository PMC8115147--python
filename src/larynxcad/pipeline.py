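"""End-to-end orchestration: screen -> compensate/enhance -> segment -> features -> classify."""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from larynxcad import classify as classify_mod
from larynxcad import features as features_mod
from larynxcad import io, phantom, preprocess, screening, segmentation
from larynxcad.config import RunConfig

log = logging.getLogger("larynxcad")


def analyze_image(image: np.ndarray, config: RunConfig | None = None) -> dict:
    """Run compensation, enhancement, segmentation and feature extraction.

    Glottis extraction runs on the CLAHE-enhanced image; the cord snake
    and the gray-statistics features use the compensated (not enhanced)
    image.  Returns a dict with the compensated image, segmentation result
    and feature vector.
    """
    config = config or RunConfig()
    compensated = preprocess.compensate_brightness(image, config.compensation)
    enhanced = preprocess.enhance(compensated, config.enhance)
    glottis = segmentation.segment_glottis(enhanced, config.screening)
    seeds = segmentation.extract_cord_seeds(glottis, config.segmentation)
    seg = segmentation.segment_cords(compensated, seeds, config=config.segmentation)
    fv = features_mod.extract_features(compensated, seg, config.features)
    return {"compensated": compensated, "segmentation": seg, "features": fv}


def run_pipeline(
    input_path: str | Path,
    config: RunConfig | None = None,
    model: classify_mod.TreeSvmModel | None = None,
) -> dict:
    """Full pipeline on a video, frame directory, or single image.

    A single image bypasses frame selection (no ``frame_selection`` block
    appears in the report).  The report echoes the full configuration so a
    run can be audited and reproduced; per-stage timings go to the log only.
    """
    config = config or RunConfig()
    t0 = time.perf_counter()
    seq = io.read_frames(input_path)
    report: dict = {"input": str(input_path), "params": config.to_dict(), "version": config.version}
    if len(seq) > 1:
        idx, region = screening.select_clearest_frame(seq, config.screening)
        report["frame_selection"] = {
            "selected_frame": idx,
            "n_frames": len(seq),
            "glottal_area": region.area,
        }
        report["selected_frame"] = idx
    else:
        report["selected_frame"] = 0
    frame = seq.frames[report["selected_frame"]]
    log.info("frame selection done in %.3fs", time.perf_counter() - t0)

    t1 = time.perf_counter()
    result = analyze_image(frame, config)
    seg = result["segmentation"]
    fv = result["features"]
    log.info("segmentation + features done in %.3fs", time.perf_counter() - t1)

    report["segmentation"] = {
        "glottis_area": int(seg.glottis_mask.sum()),
        "left_cord_area": int(seg.left_mask.sum()),
        "right_cord_area": int(seg.right_mask.sum()),
        "left_iters": seg.left_iters,
        "right_iters": seg.right_iters,
        "left_entropy_differences": seg.left_trace.differences.tolist(),
        "right_entropy_differences": seg.right_trace.differences.tolist(),
        "provenance": seg.provenance,
    }
    report["features"] = fv.to_row()
    if model is not None:
        label, path = classify_mod.classify(model, fv.to_row())
        report["label"] = label
        report["decision_path"] = path
    return report


def benchmark_features(
    n_per_class: int,
    seed: int,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the analysis pipeline over a phantom benchmark.

    Generates a balanced five-class phantom dataset and pushes every image
    through compensation, enhancement, segmentation and feature
    extraction.  Images whose segmentation fails are recorded with a
    zero-feature row (they stay in the benchmark; a classifier must live
    with them).  Returns the feature table and the true labels.
    """
    config = config or RunConfig()
    dataset = phantom.generate_benchmark(n_per_class, seed, config.phantom)
    rows, labels = [], []
    for img, gt in dataset:
        try:
            fv = analyze_image(img, config)["features"]
            rows.append(fv.to_row())
        except Exception as exc:  # pragma: no cover - rare segmentation failure
            log.warning("pipeline failed on a %s phantom: %s", gt.label, exc)
            rows.append({c: 0.0 for c in features_mod.FEATURE_COLUMNS})
        labels.append(gt.label)
    return pd.DataFrame(rows, columns=features_mod.FEATURE_COLUMNS), labels


def holdout_accuracy(
    table: pd.DataFrame,
    labels: Sequence[str],
    train_fraction: float = 0.7,
    seed: int = 0,
    config: RunConfig | None = None,
) -> dict:
    """Stratified train/test split accuracy of the tree SVM."""
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    train_idx = []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        rng.shuffle(idx)
        n_train = max(int(round(train_fraction * len(idx))), 1)
        train_idx.extend(idx[:n_train])
    train_mask = np.zeros(len(labels), dtype=bool)
    train_mask[train_idx] = True
    model = classify_mod.build_tree(
        table[train_mask], labels[train_mask], config.classify, seed=seed
    )
    predicted = np.asarray(model.predict(table[~train_mask]), dtype=object)
    truth = labels[~train_mask]
    per_class = {c: float((predicted[truth == c] == c).mean()) for c in np.unique(truth)}
    return {
        "accuracy": float((predicted == truth).mean()),
        "per_class": per_class,
        "n_train": int(train_mask.sum()),
        "n_test": int((~train_mask).sum()),
        "model": model,
    }
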