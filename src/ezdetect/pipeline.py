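"""End-to-end orchestration: simulate -> preprocess -> classify -> post-process -> evaluate.

A single :class:`PipelineConfig` carries every stage's parameter block plus
the master seed; all randomness (phantom cohort, per-fold under-sampling,
vessel-detector fixtures) derives from it, so a run is fully reproducible
and two runs with the same config produce byte-identical reports.  A SHA-256
digest of the canonical config JSON is embedded in every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluate, features, postprocess, preprocess
from .classify import AdaboostModel
from .features import PcaModel
from .preprocess import BilateralParams, GraphSearchParams
from .postprocess import VesselDetectorConfig
from .synthetic_oct import PhantomConfig, generate_cohort
from .volume_model import VoxelMask, disruption_volume

__all__ = ["SimulateConfig", "FeatureConfig", "AdaboostConfig", "MorphologyConfig",
           "PipelineConfig", "run_all", "train_pooled", "predict_eye",
           "model_to_json", "model_from_json"]


@dataclass
class SimulateConfig:
    n_trauma: int = 4
    n_normal: int = 2
    phantom: PhantomConfig = field(default_factory=PhantomConfig)


@dataclass
class FeatureConfig:
    n_levels: int = 8
    absdiff_agg: str = "mean"


@dataclass
class AdaboostConfig:
    rounds: int = 100


@dataclass
class MorphologyConfig:
    element: str = "disk2d"
    radius: int = 5


@dataclass
class PipelineConfig:
    """All stage parameter blocks plus the master seed."""

    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    graph: GraphSearchParams = field(default_factory=GraphSearchParams)
    tps_regularization: float = 0.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_components: int = 10
    adaboost: AdaboostConfig = field(default_factory=AdaboostConfig)
    vessel: VesselDetectorConfig = field(default_factory=VesselDetectorConfig)
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Strict construction: unknown keys anywhere are rejected."""
        blocks = {
            "simulate": SimulateConfig,
            "bilateral": BilateralParams,
            "graph": GraphSearchParams,
            "features": FeatureConfig,
            "adaboost": AdaboostConfig,
            "vessel": VesselDetectorConfig,
            "morphology": MorphologyConfig,
        }
        kwargs = {}
        for key, value in d.items():
            if key in blocks:
                kwargs[key] = _strict(blocks[key], value)
            elif key in ("tps_regularization", "n_components", "seed"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**kwargs)


def _strict(cls, d: dict):
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in d.items():
        if key not in names:
            raise ValueError(f"unknown config key in {cls.__name__}: {key!r}")
        if key == "phantom":
            value = _strict(PhantomConfig, value)
        elif isinstance(value, list) and isinstance(names[key].default, tuple):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _jsonable(obj):
    """Recursively make report content JSON-clean (NaN -> None, arrays -> lists)."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(float(obj)) else float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


# ---------------------------------------------------------------------------
# Per-eye processing
# ---------------------------------------------------------------------------

def _process_eye(eye, cfg: PipelineConfig):
    """Denoise, segment, smooth, flatten, extract VOI + features for one eye."""
    den = preprocess.bilateral_filter_volume(eye.volume, cfg.bilateral)
    surf = preprocess.segment_surfaces(den, cfg.graph)
    surf = preprocess.smooth_surfaces_tps(surf, cfg.tps_regularization)
    surf.z_of = np.clip(surf.z_of, 0, den.nz - 1)
    shifts = preprocess.flatten_shifts(surf)
    flat_vol, flat_surf = preprocess.flatten(den, surf)
    voi = preprocess.extract_voi(flat_vol, flat_surf)
    gt_flat = preprocess.shift_mask(eye.truth.disruption_mask, shifts)
    fm = features.extract_features(
        flat_vol, voi, n_levels=cfg.features.n_levels,
        absdiff_agg=cfg.features.absdiff_agg,
    )
    c = fm.voxel_indices
    y = np.where(gt_flat.values[c[:, 0], c[:, 1], c[:, 2]], 1, -1)
    return {
        "id": eye.id,
        "group": eye.group,
        "volume": flat_vol,
        "surfaces": flat_surf,
        "voi": voi,
        "gt": gt_flat,
        "X": fm.values,
        "coords": c,
        "y": y,
        "eye": eye,
    }


def _labels_to_mask(proc, labels) -> VoxelMask:
    mask = np.zeros(proc["volume"].shape, dtype=bool)
    pos = proc["coords"][labels > 0]
    mask[pos[:, 0], pos[:, 1], pos[:, 2]] = True
    return VoxelMask(mask, role="disruption")


def _postprocess_eye(proc, cfg: PipelineConfig, raw_mask: VoxelMask,
                     vessel_model) -> dict:
    proj = postprocess.en_face_projection(
        proc["volume"], proc["surfaces"], band=cfg.vessel.band
    )
    vmap = postprocess.detect_vessels(proj, cfg.vessel, model=vessel_model)
    devesseled = postprocess.remove_vessel_detections(raw_mask, vmap)
    final = postprocess.morphological_cleanup(
        devesseled, element=cfg.morphology.element,
        radius=cfg.morphology.radius, voi=proc["voi"],
    )
    return {"vessel_map": vmap, "mask": final}


def _evaluate_eye(proc, final_mask: VoxelMask) -> evaluate.EyeReport:
    vol = proc["volume"]
    tp, fp, tn, fn = evaluate.confusion(final_mask, proc["gt"], proc["voi"])
    sen, spe, bar = evaluate.sen_spe_bar(tp, fp, tn, fn)
    return evaluate.EyeReport(
        eye_id=proc["id"], group=proc["group"], tp=tp, fp=fp, tn=tn, fn=fn,
        sen=sen, spe=spe, bar=bar,
        detected_volume_mm3=disruption_volume(final_mask, vol.voxel_size_um),
        truth_volume_mm3=disruption_volume(proc["gt"], vol.voxel_size_um),
        voi_volume_mm3=disruption_volume(proc["voi"], vol.voxel_size_um),
    )


# ---------------------------------------------------------------------------
# Pooled training (for the predict-with-pretrained-model path)
# ---------------------------------------------------------------------------

def train_pooled(processed: list, cfg: PipelineConfig, seed: int):
    """Train one PCA + AdaBoost model on all eyes pooled (no hold-out)."""
    X = np.concatenate([p["X"] for p in processed])
    y = np.concatenate([p["y"] for p in processed])
    if not np.any(y > 0):
        raise ValueError("pooled training set has no disrupted samples")
    pca = features.fit_pca(X, n_components=cfg.n_components)
    Xb, yb = classify.undersample(features.apply_pca(pca, X), y, seed=seed)
    model = classify.train_adaboost(Xb, yb, T=cfg.adaboost.rounds)
    return {"pca": pca, "model": model}


def predict_eye(pretrained: dict, X: np.ndarray):
    Z = features.apply_pca(pretrained["pca"], X)
    return classify.predict(pretrained["model"], Z)


def model_to_json(pretrained: dict, config_digest: str = "") -> str:
    pca = pretrained["pca"]
    return json.dumps(
        {
            "config_digest": config_digest,
            "pca": {
                "mean": pca.mean.tolist(),
                "scale": pca.scale.tolist(),
                "components": pca.components.tolist(),
                "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
            },
            "adaboost": pretrained["model"].to_dict(),
        },
        sort_keys=True,
    )


def model_from_json(text: str) -> dict:
    d = json.loads(text)
    p = d["pca"]
    pca = PcaModel(
        np.asarray(p["mean"]), np.asarray(p["scale"]),
        np.asarray(p["components"]), np.asarray(p["explained_variance_ratio"]),
    )
    return {"pca": pca, "model": AdaboostModel.from_dict(d["adaboost"])}


# ---------------------------------------------------------------------------
# The full run
# ---------------------------------------------------------------------------

def run_all(cfg: PipelineConfig, out_dir=None, pretrained: dict | None = None,
            log=None) -> dict:
    """Execute the full pipeline on a simulated cohort and return the report.

    Stages: simulate -> denoise -> segment -> TPS smooth -> flatten -> VOI ->
    features -> leave-one-out (PCA + under-sample + AdaBoost) -> predict ->
    vessel removal + morphology -> metrics.  With ``pretrained`` (a dict from
    :func:`train_pooled` / :func:`model_from_json`) the LOO step is skipped
    and the supplied model classifies every eye — required for cohorts with
    no disrupted training voxels (e.g. normal-only cohorts).
    """
    ss = np.random.SeedSequence(cfg.seed)
    seed_cohort, seed_loo = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    digest = cfg.digest()

    def _log(stage, eye_id, **info):
        if log is not None:
            log(f"[{stage}] eye={eye_id} " + " ".join(f"{k}={v}" for k, v in info.items()))

    eyes = generate_cohort(
        cfg.simulate.n_trauma, cfg.simulate.n_normal, cfg.simulate.phantom,
        seed=seed_cohort,
    )
    processed = []
    for eye in eyes:
        proc = _process_eye(eye, cfg)
        _log("preprocess", eye.id, n_voi=int(proc["voi"].count()),
             n_disrupted=int((proc["y"] > 0).sum()))
        processed.append(proc)

    if pretrained is None:
        folds = classify.loo_cv(
            [{"id": p["id"], "X": p["X"], "y": p["y"]} for p in processed],
            T=cfg.adaboost.rounds, seed=seed_loo, n_components=cfg.n_components,
        )
        raw_masks = [_labels_to_mask(p, f.pred_labels)
                     for p, f in zip(processed, folds)]
    else:
        raw_masks = []
        for p in processed:
            labels, _ = predict_eye(pretrained, p["X"])
            raw_masks.append(_labels_to_mask(p, labels))

    vessel_model = postprocess.train_vessel_model(cfg.vessel, cfg.simulate.phantom)
    eye_reports = []
    for proc, raw in zip(processed, raw_masks):
        post = _postprocess_eye(proc, cfg, raw, vessel_model)
        rep = _evaluate_eye(proc, post["mask"])
        _log("postprocess", proc["id"], tp=rep.tp, fp=rep.fp)
        eye_reports.append(rep)

    report = _assemble_report(cfg, digest, processed, eye_reports)
    if out_dir is not None:
        _write_artifacts(report, eye_reports, Path(out_dir))
    return report


def _stats_block(values):
    values = [v for v in values if not (isinstance(v, float) and math.isnan(v))]
    if len(values) < 2:
        return None
    mean, sd, ci = evaluate.cohort_stats(values)
    return {"mean": mean, "std": sd, "ci95": list(ci), "n": len(values)}


def _assemble_report(cfg, digest, processed, eye_reports):
    trauma = [r for r in eye_reports if r.group == "trauma"]
    normal = [r for r in eye_reports if r.group == "normal"]

    report = {
        "config_digest": digest,
        "seed": cfg.seed,
        "eyes": [
            {
                "id": r.eye_id, "group": r.group,
                "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
                "sen_pct": r.sen, "spe_pct": r.spe, "bar_pct": r.bar,
                "detected_volume_mm3": r.detected_volume_mm3,
                "truth_volume_mm3": r.truth_volume_mm3,
                "voi_volume_mm3": r.voi_volume_mm3,
            }
            for r in eye_reports
        ],
        "trauma": {
            "sen_pct": _stats_block([r.sen for r in trauma]),
            "spe_pct": _stats_block([r.spe for r in trauma]),
            "bar_pct": _stats_block([r.bar for r in trauma]),
            "detected_volume_mm3": _stats_block(
                [r.detected_volume_mm3 for r in trauma]),
        },
        "normal": {
            "spe_pct": _stats_block([r.spe for r in normal]),
            "detected_volume_mm3": _stats_block(
                [r.detected_volume_mm3 for r in normal]),
        },
    }

    det = [r.detected_volume_mm3 for r in trauma]
    gt = [r.truth_volume_mm3 for r in trauma]
    if len(det) >= 4 and np.std(det) > 0 and np.std(gt) > 0:
        r_, ci, p = evaluate.correlation_with_ci(det, gt)
        report["correlation"] = {"r": r_, "ci95": list(ci), "p": p}
    else:
        report["correlation"] = None
    if len(det) >= 2:
        mean_d, loa, _ = evaluate.bland_altman(det, gt)
        report["bland_altman"] = {"mean_difference": mean_d, "loa": list(loa)}
    else:
        report["bland_altman"] = None
    ndet = [r.detected_volume_mm3 for r in normal]
    if len(det) >= 2 and len(ndet) >= 2:
        t, p = evaluate.two_sample_ttest(det, ndet)
        report["ttest_trauma_vs_normal"] = {"t": t, "p": p}
    else:
        report["ttest_trauma_vs_normal"] = None
    return _jsonable(report)


def _write_artifacts(report, eye_reports, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    rows = pd.DataFrame([dataclasses.asdict(r) for r in eye_reports])
    rows.to_csv(out_dir / "per_eye.csv", index=False)
    trauma = [r for r in eye_reports if r.group == "trauma"]
    if len(trauma) >= 2:
        evaluate.bland_altman_plot(
            [r.detected_volume_mm3 for r in trauma],
            [r.truth_volume_mm3 for r in trauma],
            out_dir / "bland_altman.png",
        )
    manifest = {}
    for name in ("report.json", "per_eye.csv"):
        manifest[name] = hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
    manifest["config_digest"] = report["config_digest"]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
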