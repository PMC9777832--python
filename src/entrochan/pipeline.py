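"""End-to-end run orchestration and report assembly.

A run ties the stages together for one subject group: per-subject entropy
extraction, PSO channel selection, the cross-subject common channel set, a
three-way accuracy comparison (whole vs optimal vs common channels on
*identical* fold partitions, so the channel-set effect is isolated),
confusion matrices, the FRSOC/OCSR index table and the per-region entropy
summary.  Everything is reproducible from the seeds recorded in the run log;
a failing subject aborts the whole group report with a named error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import KNNConfig, cross_validate, fold_partition
from .consensus import (channel_indices, classify_channels, common_channels,
                        format_indices_table, region_summary, stack_masks)
from .features import EntropyParams, FeatureTable, extract_features
from .io import epoch_segments
from .pso import ChannelMask, PSOConfig, pso_select
from .synth import SynthConfig, generate_subject, load_group

__all__ = ["RunConfig", "compare_channel_sets", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one group run."""

    dataset_dir: str | None = None  # read a generated/real dataset …
    synth: SynthConfig | None = None  # … or generate subjects in memory
    out_dir: str = "entrochan-report"
    entropy: EntropyParams = field(default_factory=EntropyParams)
    knn: KNNConfig = field(default_factory=KNNConfig)
    pso: PSOConfig = field(default_factory=lambda: PSOConfig(n_particles=20, t_max=30))
    consensus_fraction: float = 0.6
    consensus_threshold: int | None = None
    folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def compare_channel_sets(table: FeatureTable, sets: dict[str, tuple[str, ...]],
                         knn_cfg: KNNConfig, folds: int = 10,
                         partition=None) -> pd.DataFrame:
    """CV accuracy of several channel sets on identical folds.

    ``sets`` maps a name (e.g. ``whole``/``optimal``/``common``) to a channel
    tuple.  Returns one row per set with the accuracy in percent plus the
    pairwise differences against every other set, in percentage points.
    """
    for name, chans in sets.items():
        if len(chans) == 0:
            raise ValueError(f"channel set {name!r} is empty")
        missing = set(chans) - set(table.channels)
        if missing:
            raise KeyError(f"set {name!r} has channels outside the table: "
                           f"{sorted(missing)}")
    if partition is None:
        partition = fold_partition(table.n_epochs, folds, knn_cfg.seed)
    acc = {}
    for name, chans in sets.items():
        sub = table.select_channels(chans)
        acc[name] = cross_validate(sub, knn_cfg, folds=folds,
                                   partition=partition).mean_accuracy * 100.0
    rows = []
    for name in sets:
        row = {"set": name, "n_channels": len(sets[name]),
               "accuracy_pct": round(acc[name], 2)}
        for other in sets:
            if other != name:
                row[f"vs_{other}"] = round(acc[name] - acc[other], 2)
        rows.append(row)
    return pd.DataFrame(rows)


def _load_subjects(cfg: RunConfig):
    if cfg.dataset_dir is not None:
        recs, ann, _ = load_group(cfg.dataset_dir)
        return [(r, ann) for r in recs]
    if cfg.synth is not None:
        out = []
        for i in range(cfg.synth.n_subjects):
            rec, ann, _ = generate_subject(cfg.synth, i)
            out.append((rec, ann))
        return out
    raise ValueError("RunConfig needs dataset_dir or synth")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the whole group pipeline and write the report bundle.

    Returns a dict with the in-memory results: per-subject masks, feature
    tables, the selection matrix, common channel set, comparison tables,
    confusion matrices, channel indices and the region summary.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = _load_subjects(cfg)

    tables: list[FeatureTable] = []
    masks: list[ChannelMask] = []
    subject_ids: list[str] = []
    comparisons: dict[str, pd.DataFrame] = {}
    confusions: dict[str, pd.DataFrame] = {}

    for i, (rec, ann) in enumerate(subjects):
        sid = rec.subject_id or f"subject-{i}"
        try:
            epochs = epoch_segments(rec, ann)
            params = (cfg.entropy if cfg.entropy.n == int(round(rec.rate))
                      else EntropyParams(cfg.entropy.m, cfg.entropy.r_coeff,
                                         int(round(rec.rate))))
            table = extract_features(epochs, params, subject_id=sid)
            pso_cfg = dataclasses.replace(cfg.pso, seed=cfg.pso.seed + i)
            mask, _trace = pso_select(table, pso_cfg, cfg.knn, folds=cfg.folds)
        except Exception as exc:  # partial failure aborts the group report
            raise RuntimeError(f"subject {sid!r} failed: {exc}") from exc
        tables.append(table)
        masks.append(mask)
        subject_ids.append(sid)

    sel = stack_masks(masks, subject_ids)
    common = common_channels(sel, threshold=cfg.consensus_threshold,
                             fraction=cfg.consensus_fraction)
    idx = classify_channels(channel_indices(sel))

    for sid, table, mask in zip(subject_ids, tables, masks):
        sets = {"whole": table.channels, "optimal": mask.selected}
        if common:
            sets["common"] = common
        part = fold_partition(table.n_epochs, cfg.folds, cfg.knn.seed)
        comparisons[sid] = compare_channel_sets(table, sets, cfg.knn,
                                                folds=cfg.folds, partition=part)
        sub = table.select_channels(mask.selected)
        cv = cross_validate(sub, cfg.knn, folds=cfg.folds, partition=part)
        confusions[sid] = cv.confusion

    summary, summary_flags = region_summary(tables, channels=common or None)

    # ---- report bundle -------------------------------------------------
    sel_out = sel.copy()
    sel_out["Total"] = sel_out.sum(axis=1)
    sel_out.index.name = "Channel"
    sel_out.to_csv(out_dir / "selection_matrix.tsv", sep="\t")
    (out_dir / "common_channels.txt").write_text("\n".join(common) + "\n")
    for sid, mask in zip(subject_ids, masks):
        mask.to_json(out_dir / f"mask_{sid}.json")
    comparison_all = pd.concat(
        [c.assign(subject=sid) for sid, c in comparisons.items()],
        ignore_index=True)
    comparison_all.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
    for sid, cm in confusions.items():
        cm.round(2).to_csv(out_dir / f"confusion_{sid}.tsv", sep="\t")
    (out_dir / "indices.tsv").write_text(format_indices_table(idx))
    idx.reset_index(names="channel").to_json(out_dir / "indices.json",
                                             orient="records", indent=1)
    summary.round(6).to_csv(out_dir / "region_summary.tsv", sep="\t", index=False)
    log = {
        "entrochan_version": __version__,
        "config": _jsonable(cfg.to_dict()),
        "subjects": subject_ids,
        "n_common_channels": len(common),
        "region_summary_flags": summary_flags,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")

    return {
        "subject_ids": subject_ids,
        "tables": tables,
        "masks": masks,
        "selection_matrix": sel,
        "common_channels": common,
        "comparisons": comparisons,
        "confusions": confusions,
        "indices": idx,
        "region_summary": summary,
        "out_dir": out_dir,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
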