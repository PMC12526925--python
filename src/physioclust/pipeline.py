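"""End-to-end orchestration of the modality scenarios.

``run`` wires the stages together: simulate (or load) a cohort →
preprocess → per modality: DTW dissimilarity matrix → force-directed 3D
embedding → staged clustering (six clusters for the activity task, one
per subject for the identification task) → Hungarian-aligned metrics
against the requested ground-truth label sets.  Every artifact is
serialized under the output directory and the whole run is a pure
function of the configuration seed.

The global seed fans out to per-component sub-seeds through a stable
name hash, so each stochastic component is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (
    ActivityLabel,
    CohortConfig,
    Separability,
    generate_cohort,
    load_cohort,
    save_cohort,
)
from .clustering import StagedParams, silhouette_coefficient, staged_cluster, save_result
from .dissimilarity import (
    DissimilarityParams,
    MODALITY_CHANNELS,
    compute_raw_tensor,
    normalize_and_aggregate,
    save_matrix,
)
from .embedding import LayoutParams, layout, save_layout
from .metrics import classification_report, feature_summary, nmi

logger = logging.getLogger(__name__)

TASKS = ("activity", "subject")


def component_seed(base_seed: int, name: str) -> int:
    """Derive a per-component sub-seed from the global one (< 2**31)."""
    return int(
        np.random.SeedSequence([int(base_seed), zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig | str | Path = field(default_factory=CohortConfig)
    tasks: tuple[str, ...] = TASKS
    modalities: tuple[str, ...] = ("acc", "ecg", "both")
    dissim: DissimilarityParams = field(default_factory=DissimilarityParams)
    layout: LayoutParams = field(default_factory=LayoutParams)
    sc_threshold: float = 0.5
    linkage: str = "ward"
    out_dir: str | Path = "physioclust_run"
    seed: int = 0
    resume: bool = False

    def __post_init__(self) -> None:
        if not self.tasks or not self.modalities:
            raise ValueError("at least one task and one modality are required")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")
        for m in self.modalities:
            if m not in MODALITY_CHANNELS:
                raise ValueError(f"unknown modality {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("cohort"), dict):
            cdata = dict(data["cohort"])
            if isinstance(cdata.get("separability"), dict):
                cdata["separability"] = Separability(**cdata["separability"])
            if "activities" in cdata:
                cdata["activities"] = tuple(ActivityLabel(a) for a in cdata["activities"])
            data["cohort"] = CohortConfig(**cdata)
        if isinstance(data.get("dissim"), dict):
            data["dissim"] = DissimilarityParams(**data["dissim"])
        if isinstance(data.get("layout"), dict):
            data["layout"] = LayoutParams(**data["layout"])
        for key in ("tasks", "modalities"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _modality_slice(channels: tuple[str, ...], modality: str) -> list[int]:
    wanted = [k.value for k in MODALITY_CHANNELS[modality]]
    return [channels.index(name) for name in wanted]


def run(config: RunConfig) -> dict:
    """Execute all requested (modality, task) cells; returns the report."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- cohort -----------------------------------------------------------
    if isinstance(config.cohort, (str, Path)):
        trials = load_cohort(config.cohort)
        cohort_cfg = None
    else:
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=component_seed(config.seed, "cohort")
        )
        trials = generate_cohort(cohort_cfg)
        save_cohort(trials, out / "cohort", cohort_cfg)
    logger.info("cohort: %d trials", len(trials))

    # --- preprocess -------------------------------------------------------
    from .preprocess import PreprocessConfig, preprocess_trial

    pre_cfg = PreprocessConfig()
    pre = [preprocess_trial(tr, pre_cfg) for tr in trials]
    feature_summary(pre).to_csv(out / "features.csv", index=False)

    trial_ids = [tr.trial_id for tr in pre]
    activity_labels = np.array([tr.activity.value for tr in pre])
    subject_labels = np.array([tr.subject_id for tr in pre])
    n_subjects = len(np.unique(subject_labels))

    # --- raw DTW tensor over the union of requested channels --------------
    union = "both" if set(config.modalities) != {"acc"} and set(config.modalities) != {"ecg"} else next(iter(config.modalities))
    if set(config.modalities) == {"acc"}:
        union = "acc"
    elif set(config.modalities) == {"ecg"}:
        union = "ecg"
    raw_path = out / f"raw_dtw_{union}.npy"
    if config.resume and raw_path.exists():
        raw = np.load(raw_path)
        channels = tuple(k.value for k in MODALITY_CHANNELS[union])
        logger.info("resume: reusing raw DTW tensor %s", raw_path)
    else:
        raw, channels = compute_raw_tensor(pre, union, config.dissim)
        np.save(raw_path, raw)
    n_pairs = len(pre) * (len(pre) - 1) // 2
    logger.info("raw tensor ready: %d trials, %d unique pairs", len(pre), n_pairs)

    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "n_trials": len(pre),
            "n_pairs": n_pairs,
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        },
        "cells": {},
    }

    for modality in config.modalities:
        cols = _modality_slice(channels, modality)
        mod_channels = tuple(channels[c] for c in cols)
        matrix = normalize_and_aggregate(
            raw[:, :, cols], mod_channels, tuple(trial_ids), modality
        )
        save_matrix(matrix, out / f"matrix_{modality}.tsv")
        lp = dataclasses.replace(
            config.layout, seed=component_seed(config.seed, f"layout_{modality}")
        )
        full_layout = layout(matrix, lp)
        save_layout(full_layout, trial_ids, out / f"layout_{modality}.csv", lp)

        for task in config.tasks:
            cell_key = f"{modality}/{task}"
            try:
                target_k = 6 if task == "activity" else n_subjects
                target_k = min(target_k, len(pre))
                sp = StagedParams(
                    target_k=target_k, sc_threshold=config.sc_threshold, linkage=config.linkage
                )
                result = staged_cluster(
                    pre, modality, target_k,
                    dissim_params=config.dissim, layout_params=lp,
                    staged_params=sp, matrix=matrix,
                )
                save_result(result, out / f"result_{modality}_{task}.json",
                            params={"target_k": target_k, "modality": modality})
                pred = result.labels_for(trial_ids)
                sc_final = silhouette_coefficient(full_layout.coords, pred) if len(np.unique(pred)) > 1 else None
                truth = activity_labels if task == "activity" else subject_labels
                rep = classification_report(truth, pred, sc=sc_final, task=task, modality=modality)
                cell = rep.to_dict()
                cell["nmi_vs"] = {
                    "activity": nmi(activity_labels, pred),
                    "subject": nmi(subject_labels, pred),
                }
                cell["n_stages"] = len(result.stages)
                cell["artifacts"] = {
                    "matrix": f"matrix_{modality}.tsv",
                    "layout": f"layout_{modality}.csv",
                    "result": f"result_{modality}_{task}.json",
                }
                report["cells"][cell_key] = cell
                logger.info(
                    "%s: NMI=%.3f acc=%.3f (%d stages)",
                    cell_key, cell["nmi"], cell["accuracy"], cell["n_stages"],
                )
            except Exception as exc:  # keep other cells running
                logger.exception("cell %s failed", cell_key)
                report["cells"][cell_key] = {"error": str(exc)}

    report["runtime_s"] = round(time.time() - t_start, 2)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
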