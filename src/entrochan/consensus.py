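"""Cross-subject consensus channels and channel-importance indices.

A subject's optimal channel set is a 0/1 column; stacking subjects gives a
channel x subject selection matrix.  From it:

* the *common channel set* keeps every channel selected by at least a
  threshold number of subjects (six of ten in the original protocol, stored
  as the fraction 0.6 so other group sizes scale);
* *FRSOC* (frequency ratio of selecting optimal channel) is a channel's
  total selection count divided by the average per-channel count — a
  strength index whose mean over channels is exactly 1;
* *OCSR* (optimal channel selection rate) is the fraction of subjects whose
  optimal set contains the channel — a breadth index in [0, 1].

Channels strong and broad (FRSOC >= 1.25 and OCSR >= 0.70 by default) are
classed *principal*; channels weak on both counts (FRSOC <= 0.70 and
OCSR <= 0.40) are *weak*; the rest are *ordinary*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureTable
from .montage import default_region_map

__all__ = ["common_channels", "stack_masks", "channel_indices",
           "classify_channels", "region_summary", "format_indices_table"]


def stack_masks(masks, subject_ids=None) -> pd.DataFrame:
    """Stack per-subject channel masks into a channel x subject 0/1 matrix.

    Masks are keyed by channel *name*; all subjects must share the channel
    set (a missing channel is an error, never silently dropped).
    """
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to stack")
    channels = tuple(masks[0].channels)
    for m in masks[1:]:
        if set(m.channels) != set(channels):
            raise ValueError("subjects disagree on the channel set")
    if subject_ids is None:
        subject_ids = [str(i + 1) for i in range(len(masks))]
    data = {
        str(sid): pd.Series(m.bits, index=list(m.channels)).reindex(list(channels))
        for sid, m in zip(subject_ids, masks)
    }
    return pd.DataFrame(data, index=list(channels)).astype(int)


def common_channels(sel: pd.DataFrame, threshold: int | None = None,
                    fraction: float = 0.6) -> tuple[str, ...]:
    """Channels selected by at least ``threshold`` subjects, in row order.

    ``threshold`` defaults to ``ceil(fraction * n_subjects)`` (0.6 of the
    group reproduces the six-of-ten rule); an explicit integer overrides it.
    """
    n_subjects = sel.shape[1]
    if threshold is None:
        threshold = math.ceil(fraction * n_subjects)
    if not 0 <= threshold <= n_subjects + 1:
        raise ValueError(f"threshold {threshold} out of range for {n_subjects} subjects")
    counts = sel.sum(axis=1)
    return tuple(ch for ch in sel.index if counts[ch] >= threshold)


def channel_indices(stacked: pd.DataFrame) -> pd.DataFrame:
    """Selection count, FRSOC and OCSR per channel.

    ``count_c`` is the row sum; ``average = total / n_channels``;
    ``frsoc_c = count_c / average``; ``ocsr_c = count_c / n_subjects``.
    """
    counts = stacked.sum(axis=1).astype(int)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("all-zero selection matrix: FRSOC undefined")
    n_channels = stacked.shape[0]
    n_subjects = stacked.shape[1]
    average = total / n_channels
    out = pd.DataFrame(
        {
            "count": counts,
            "frsoc": counts / average,
            "ocsr": counts / n_subjects,
        },
        index=stacked.index,
    )
    out.attrs["total"] = total
    out.attrs["average"] = average
    out.attrs["n_subjects"] = n_subjects
    return out


def classify_channels(idx: pd.DataFrame, frsoc_hi: float = 1.25,
                      ocsr_hi: float = 0.70, frsoc_lo: float = 0.70,
                      ocsr_lo: float = 0.40) -> pd.DataFrame:
    """Attach a principal/weak/ordinary class to each channel."""
    for thr in (frsoc_hi, ocsr_hi, frsoc_lo, ocsr_lo):
        if thr <= 0:
            raise ValueError("thresholds must be positive")
    out = idx.copy()
    principal = (out["frsoc"] >= frsoc_hi) & (out["ocsr"] >= ocsr_hi)
    weak = (out["frsoc"] <= frsoc_lo) & (out["ocsr"] <= ocsr_lo)
    cls = np.where(principal, "principal", np.where(weak, "weak", "ordinary"))
    out["class"] = cls
    out.attrs.update(idx.attrs)
    return out


def region_summary(tables: list[FeatureTable], channels=None,
                   region_map: dict[str, str] | None = None
                   ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-emotion per-channel mean ApEn/SampEn over a group of subjects.

    Means pool all epochs of all subjects carrying each emotion label; a
    subject lacking an emotion contributes nothing to that emotion's mean
    and the (subject, emotion) pair is returned as a flag.
    """
    if not tables:
        raise ValueError("no feature tables")
    if region_map is None:
        region_map = default_region_map()
    if channels is None:
        channels = tables[0].channels
    channels = list(channels)
    for t in tables:
        missing = set(channels) - set(t.channels)
        if missing:
            raise KeyError(f"channels {sorted(missing)} absent from subject "
                           f"{t.subject_id!r}")

    emotions = sorted({lab for t in tables for lab in t.labels}, key=str)
    flags = [(t.subject_id, emo) for t in tables for emo in emotions
             if emo not in set(t.labels)]

    rows = []
    for ch in channels:
        region = region_map.get(ch, "unknown")
        for emo in emotions:
            ap_chunks, se_chunks = [], []
            for t in tables:
                sel = t.labels == emo
                if sel.any():
                    ap_chunks.append(t.values[f"{ch}:ApEn"].to_numpy()[sel])
                    se_chunks.append(t.values[f"{ch}:SampEn"].to_numpy()[sel])
            rows.append({
                "channel": ch,
                "region": region,
                "emotion": emo,
                "apen_mean": float(np.concatenate(ap_chunks).mean()),
                "sampen_mean": float(np.concatenate(se_chunks).mean()),
            })
    return pd.DataFrame(rows), flags


def format_indices_table(idx: pd.DataFrame) -> str:
    """Render indices in the two-row report style: an FRSOC row (3 decimals)
    and an OCSR row (1-decimal percent) per channel block of ten."""
    chans = list(idx.index)
    lines = []
    for lo in range(0, len(chans), 10):
        block = chans[lo : lo + 10]
        lines.append("Channel\t" + "\t".join(block))
        lines.append("FRSOC\t" + "\t".join(f"{idx.loc[c, 'frsoc']:.3f}" for c in block))
        lines.append("OCSR (%)\t" + "\t".join(f"{idx.loc[c, 'ocsr'] * 100:.1f}" for c in block))
    return "\n".join(lines) + "\n"
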