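"""End-to-end orchestration: segment -> contour -> waveform -> rank -> gray
-> classify, with artifact writing and full (config, seed) reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    NORMAL,
    SvmConfig,
    alpha_sweep,
    build_fused_features,
    ellipse_classify,
    evaluate,
    find_dividing_line,
    knn_classify,
    representative_split,
    svm_train_test,
)
from .config import RunConfig
from .contour import distance_waveform, symmetry_waveform, trace_contour
from .errors import DegenerateComponentError, PipelineError
from .fixtures import generate_scene
from .grayfeat import gray_stats, spiral_gray_sequence
from .rankcode import (
    average_rank_difference,
    rank_binarize,
    select_representatives,
    word_histogram,
)
from .segment import SpermCrop, crop_head, extract_components, remove_tail, threshold_segment

__all__ = ["run_pipeline", "segment_image", "extract_features", "PipelineResult"]

log = logging.getLogger("spermwave")


@dataclass
class PipelineResult:
    """All intermediate products of one run plus the final report."""

    crops: list[SpermCrop]
    labels: list[str]
    dards: np.ndarray
    ps: np.ndarray
    contour_profiles: list
    gray_profiles: list
    report: dict
    waveforms: list = field(default_factory=list)


def _stage(stage: str, sperm_id=None):
    """Decorator-free helper: re-raise stage failures with context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, sperm_id, str(exc)) from exc
            return False

    return _Ctx()


def segment_image(image: np.ndarray, config: RunConfig, labels_source=None):
    """Threshold, split into components, strip tails and crop each head.

    ``labels_source`` attaches truth labels to the crops; it is either
    ``("label_image", id_image, labels)`` (ground-truth pixel ids, simulate
    mode) or ``("by_order", labels)`` (manifest rows in row-major component
    order, images mode).
    """
    seg = config.segmentation
    mask = threshold_segment(image, roi=config.input.roi, threshold=seg.threshold)
    comps = extract_components(mask, min_area=seg.min_area)
    crops: list[SpermCrop] = []
    for i, (comp, bbox) in enumerate(comps):
        try:
            head = remove_tail(comp, width_threshold=seg.tail_width)
        except DegenerateComponentError:
            # thinner than a head everywhere: tail fragment or debris, not a sperm
            log.info("dropping thin component %d at %s", i, bbox[:2])
            continue
        label = None
        if labels_source is not None:
            if labels_source[0] == "label_image":
                _, label_image, labels = labels_source
                ids = label_image[bbox[0] : bbox[2], bbox[1] : bbox[3]][head]
                ids = ids[ids > 0]
                if ids.size:
                    label = labels[int(np.bincount(ids).argmax()) - 1]
            else:
                _, labels = labels_source
                if i >= len(labels):
                    raise PipelineError(
                        "segment", i, "more components than manifest rows"
                    )
                label = labels[i]
        with _stage("crop_head", i):
            crops.append(crop_head(image, head, origin=(bbox[0], bbox[1]), label=label))
    return crops


def extract_features(crops: list[SpermCrop], config: RunConfig):
    """Per-crop waveform/rank/gray features.

    Returns ``(contour_profiles, gray_profiles, ps, waveforms)``.
    """
    rank_cfg = config.rank
    contour_profiles = []
    gray_profiles = []
    ps = []
    waveforms = []
    for i, crop in enumerate(crops):
        with _stage("contour", i):
            contour = trace_contour(crop.mask)
            if config.waveform.method == "centroid":
                wf = distance_waveform(contour)
            else:
                wf = symmetry_waveform(contour)
        with _stage("rank", i):
            contour_profiles.append(
                word_histogram(rank_binarize(wf.values), rank_cfg.m_contour)
            )
        with _stage("grayfeat", i):
            ps.append(gray_stats(crop).P)
            seq = spiral_gray_sequence(crop)
            gray_profiles.append(word_histogram(rank_binarize(seq), rank_cfg.m_gray))
        waveforms.append(wf)
    return contour_profiles, gray_profiles, np.asarray(ps), waveforms


def run_pipeline(config: RunConfig, rng_seed: int | None = None) -> PipelineResult:
    """Execute the full pipeline described by ``config``.

    In ``simulate`` mode a synthetic scene is generated from the config seed;
    in ``images`` mode the manifest CSV supplies per-sperm labels (rows per
    image in row-major component order).  The returned report contains one
    entry per classifier; with ``config.output_dir`` set, crops, waveforms,
    profiles and the JSON report are written there.
    """
    seed = config.seed if rng_seed is None else rng_seed

    if config.input.mode == "simulate":
        sim = config.input.simulate
        with _stage("simulate"):
            scene = generate_scene(
                sim.n_normal, sim.n_abnormal, seed, sim.fixtures.to_scene_config()
            )
        images = [(scene.image, ("label_image", scene.label_image, scene.labels))]
    else:
        with _stage("load_images"):
            images = _load_images(config)

    crops: list[SpermCrop] = []
    for image, labels_source in images:
        with _stage("segment"):
            crops.extend(segment_image(image, config, labels_source))
    log.info("segmented %d sperm crops", len(crops))
    if not crops:
        raise PipelineError("segment", None, "no sperm components found")
    labels = [c.label for c in crops]

    contour_profiles, gray_profiles, ps, waveforms = extract_features(crops, config)

    with _stage("models"):
        normal_idx = [i for i, lab in enumerate(labels) if lab == NORMAL]
        if len(normal_idx) < config.rank.n_models:
            raise ValueError(
                f"need >= {config.rank.n_models} normal sperms for the model set"
            )
        models = select_representatives(
            [contour_profiles[i] for i in normal_idx], config.rank.n_models, label=NORMAL
        )
        dards = np.array(
            [average_rank_difference(p, models) for p in contour_profiles]
        )

    with _stage("classify"):
        report = _classify_all(crops, labels, dards, ps, gray_profiles, config)

    report["seed"] = seed
    report["n_sperm"] = len(crops)
    report["config"] = config.model_dump(mode="json")
    report["versions"] = _versions()

    result = PipelineResult(
        crops=crops,
        labels=labels,
        dards=dards,
        ps=ps,
        contour_profiles=contour_profiles,
        gray_profiles=gray_profiles,
        report=report,
        waveforms=waveforms,
    )
    if config.output_dir:
        _write_artifacts(result, Path(config.output_dir))
    return result


def _classify_all(crops, labels, dards, ps, gray_profiles, config: RunConfig) -> dict:
    cls_cfg = config.classifier
    direction = cls_cfg.direction
    out: dict = {"classifiers": {}}

    dl, acc = find_dividing_line(dards, labels, direction)
    out["classifiers"]["rank_only"] = {"dividing_line": dl, "accuracy": acc}

    dl_p, acc_p = find_dividing_line(ps, labels, direction)
    out["classifiers"]["gray_only"] = {"dividing_line": dl_p, "accuracy": acc_p}

    table = alpha_sweep(dards, ps, labels, tuple(cls_cfg.alpha_grid), direction)
    best = table[table["best"]].iloc[0]
    out["classifiers"]["joint"] = {
        "table": table.drop(columns="best").to_dict(orient="records"),
        "best_alpha": float(best["alpha"]),
        "dividing_line": float(best["dl"]),
        "accuracy": float(best["accuracy"]),
    }

    svm_cfg = SvmConfig(
        gamma=config.svm.gamma,
        cost=config.svm.cost,
        cache_mb=config.svm.cache_mb,
        eps=config.svm.eps,
        shrinking=config.svm.shrinking,
    )
    features = build_fused_features(gray_profiles, dards)
    train_idx = representative_split(
        gray_profiles, labels, per_class=config.rank.per_class_train
    )
    svm_report = svm_train_test(features, labels, train_idx, svm_cfg)
    out["classifiers"]["fused_svm"] = svm_report.to_dict()
    out["classifiers"]["fused_svm"]["train_indices"] = [int(i) for i in train_idx]

    preds = []
    for i, crop in enumerate(crops):
        refs = [
            (c.image, lab) for j, (c, lab) in enumerate(zip(crops, labels)) if j != i
        ]
        preds.append(
            knn_classify(
                crop.image, refs, k=cls_cfg.knn_k, normal_cut=cls_cfg.knn_normal_cut
            )
        )
    out["classifiers"]["knn"] = evaluate(
        preds, labels, {"k": cls_cfg.knn_k, "normal_cut": cls_cfg.knn_normal_cut}
    ).to_dict()

    epreds = [ellipse_classify(c.mask, cls_cfg.ovality_band)[1] for c in crops]
    out["classifiers"]["ellipse"] = evaluate(
        epreds, labels, {"band": list(cls_cfg.ovality_band)}
    ).to_dict()
    return out


def _load_images(config: RunConfig):
    import imageio.v3 as iio

    manifest = config.input.manifest
    if manifest is None:
        raise ValueError("images mode requires a manifest CSV")
    table = pd.read_csv(manifest)
    base = Path(config.input.images_dir or Path(manifest).parent)
    images = []
    for image_path, group in table.groupby("image_path", sort=True):
        img = np.asarray(iio.imread(base / str(image_path)))
        if img.ndim == 3:
            img = img[..., 0]
        group = group.sort_values("sperm_id")
        if "mask_path" in group.columns:
            # ground-truth masks available: attach labels by pixel overlap
            label_image = np.zeros(img.shape, dtype=np.int32)
            labels = []
            for j, (_, row) in enumerate(group.iterrows(), start=1):
                mask = np.asarray(iio.imread(base / str(row["mask_path"]))) > 127
                label_image[mask] = j
                labels.append(str(row["label"]))
            images.append((img, ("label_image", label_image, labels)))
        else:
            # no masks: labels attach to components in row-major order
            images.append((img, ("by_order", list(group["label"]))))
    return images


def _versions() -> dict:
    import numpy
    import skimage
    import sklearn

    return {
        "spermwave": __version__,
        "numpy": numpy.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True) + "\n"
    )
    crops_dir = out_dir / "crops"
    crops_dir.mkdir(exist_ok=True)
    rows = []
    wf_rows = []
    for i, (crop, wf) in enumerate(zip(result.crops, result.waveforms)):
        iio.imwrite(crops_dir / f"sperm_{i:03d}.png", crop.image)
        iio.imwrite(
            crops_dir / f"sperm_{i:03d}_mask.png", crop.mask.astype(np.uint8) * 255
        )
        rows.append(
            {
                "sperm_id": i,
                "label": crop.label,
                "origin_row": crop.origin[0],
                "origin_col": crop.origin[1],
                "dard": float(result.dards[i]),
                "p": float(result.ps[i]),
            }
        )
        for j, v in enumerate(wf.values):
            wf_rows.append({"sperm_id": i, "index": j, "value": float(v), "source": wf.source})
    pd.DataFrame(rows).to_csv(out_dir / "sperms.csv", index=False)
    pd.DataFrame(wf_rows).to_csv(out_dir / "waveforms.csv", index=False)
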