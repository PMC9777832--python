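"""Bundled reference data from the motivating 30-subject musical-emotion study.

Three subject groups (ten subjects each) listened to one long musical piece
with multiple labelled emotion segments; per subject, a PSO-optimized 0/1
channel mask over the 30-channel 10-20 montage was reported.  The package
ships, as plain text:

* the emotion-segment schedule of each piece (``annotations_*.txt``, in the
  ``M:SS–M:SS<TAB>Label`` dialect), and
* each group's channel x subject selection matrix (``selection_*.tsv``,
  channel rows / subject columns / 0/1 cells / Total column / accuracy row).

These are the inputs for every combinatorial check the raw EEG is not needed
for: epoch-count arithmetic, common-channel construction and the FRSOC/OCSR
channel-importance indices.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import (SegmentAnnotation, parse_annotations, read_selection_accuracy,
                 read_selection_matrix)

__all__ = ["GROUPS", "load_selection", "load_selection_accuracy",
           "load_stacked_selection", "load_annotations"]

#: Group keys, keyed by the musical piece each group listened to.
GROUPS: tuple[str, ...] = ("waltz", "couplets", "symphony")


def _data_path(name: str):
    return resources.files("entrochan.data") / name


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")


def load_selection(group: str) -> pd.DataFrame:
    """One group's 30-channel x 10-subject 0/1 selection matrix."""
    _check_group(group)
    with resources.as_file(_data_path(f"selection_{group}.tsv")) as path:
        return read_selection_matrix(path)


def load_selection_accuracy(group: str) -> pd.Series:
    """The per-subject optimal-channel recognition accuracies (percent)."""
    _check_group(group)
    with resources.as_file(_data_path(f"selection_{group}.tsv")) as path:
        acc = read_selection_accuracy(path)
    assert acc is not None
    return acc


def load_stacked_selection() -> pd.DataFrame:
    """All three groups stacked: 30 channels x 30 subjects."""
    frames = [load_selection(g) for g in GROUPS]
    return pd.concat(frames, axis=1)


def load_annotations(group: str) -> SegmentAnnotation:
    """The emotion-segment schedule of one group's musical piece."""
    _check_group(group)
    text = _data_path(f"annotations_{group}.txt").read_text()
    return parse_annotations(text)
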