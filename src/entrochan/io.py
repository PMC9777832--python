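"""Recording/annotation/selection-matrix I/O and 1-s epoching.

Two recording dialects are supported:

* a delimited channel x sample matrix (TSV) with a small YAML sidecar holding
  the sampling rate, channel names and subject id — the portable, exactly
  round-tripping format;
* BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``), read through :mod:`mne`.
  A minimal triplet writer (IEEE float32, multiplexed) is provided for
  fixtures; round-trips through it are exact to float32 storage precision.

Emotion annotations use a plain text dialect, one segment per line::

    0:20–1:16<TAB>Pleasure

with integer-second ``M:SS`` bounds, inclusive at both ends (a 0:43–0:52
segment spans ten labelled seconds and yields ten 1-s epochs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import MONTAGE_30, default_region_map  # noqa: F401  (re-export)

__all__ = [
    "Recording",
    "SegmentAnnotation",
    "Epochs",
    "read_recording",
    "write_recording",
    "parse_annotations",
    "format_annotations",
    "read_annotations",
    "epoch_segments",
    "read_selection_matrix",
    "write_selection_matrix",
    "default_region_map",
]


@dataclass
class Recording:
    """Multi-channel EEG recording (channel x sample, microvolts)."""

    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel names but {self.data.shape[0]} rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one channel")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class SegmentAnnotation:
    """Labelled time spans, integer seconds, inclusive at both ends."""

    segments: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        segs = [(int(s), int(e), str(lab)) for s, e, lab in self.segments]
        for s, e, lab in segs:
            if e < s:
                raise ValueError(f"segment ({s}, {e}, {lab!r}) ends before it starts")
        by_start = sorted(segs)
        for (s0, e0, _), (s1, _, _) in zip(by_start, by_start[1:]):
            if s1 <= e0:
                raise ValueError("segments overlap after sorting")
        self.segments = segs

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for _, _, lab in self.segments:
            if lab not in seen:
                seen.append(lab)
        return seen

    def n_epochs(self) -> dict[str, int]:
        """Epoch count per label under the inclusive 1-s convention."""
        out: dict[str, int] = {}
        for s, e, lab in self.segments:
            out[lab] = out.get(lab, 0) + (e - s + 1)
        return out


@dataclass
class Epochs:
    """Channel-major container of labelled 1-s epochs.

    ``x`` has shape (n_epochs, n_channels, n) with ``n = rate`` samples.
    """

    x: np.ndarray
    labels: np.ndarray
    t0: np.ndarray
    channels: tuple[str, ...]
    rate: float

    @property
    def n_epochs(self) -> int:
        return self.x.shape[0]


_TIME_RE = re.compile(
    r"^\s*(\d+):(\d{1,2})\s*[–—-]\s*(\d+):(\d{1,2})\s+(.+?)\s*$"
)


def _to_seconds(minutes: str, seconds: str) -> int:
    sec = int(seconds)
    if sec >= 60:
        raise ValueError(f"invalid seconds field {seconds!r}")
    return int(minutes) * 60 + sec


def parse_annotations(text: str) -> SegmentAnnotation:
    """Parse segment lines of the form ``M:SS–M:SS<sep>Label``.

    Hyphen and en/em dash are accepted as range separators.  Blank lines and
    ``#`` comments are skipped.  Times are integer seconds; a segment's end
    must not precede its start.
    """
    segments: list[tuple[int, int, str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _TIME_RE.match(stripped.replace("\t", " "))
        if m is None:
            raise ValueError(f"line {lineno}: cannot parse segment {stripped!r}")
        start = _to_seconds(m.group(1), m.group(2))
        end = _to_seconds(m.group(3), m.group(4))
        if end < start:
            raise ValueError(f"line {lineno}: segment ends before it starts")
        segments.append((start, end, m.group(5)))
    return SegmentAnnotation(segments)


def format_annotations(ann: SegmentAnnotation) -> str:
    lines = []
    for s, e, lab in ann.segments:
        lines.append(f"{s // 60}:{s % 60:02d}–{e // 60}:{e % 60:02d}\t{lab}")
    return "\n".join(lines) + "\n"


def read_annotations(path: str | Path) -> SegmentAnnotation:
    return parse_annotations(Path(path).read_text())


def epoch_segments(rec: Recording, ann: SegmentAnnotation) -> Epochs:
    """Cut labelled 1-s epochs from a recording.

    Each segment ``(s, e, L)`` yields ``e - s + 1`` epochs labelled ``L``
    (bounds inclusive); epoch ``k`` covers samples
    ``[(s + k) * rate, (s + k + 1) * rate)``.
    """
    n = int(round(rec.rate))
    if abs(rec.rate - n) > 1e-9:
        raise ValueError("non-integer samples per 1-s epoch")
    chunks: list[np.ndarray] = []
    labels: list[str] = []
    t0s: list[int] = []
    for s, e, lab in ann.segments:
        if (e + 1) * n > rec.n_samples:
            raise ValueError(
                f"segment ({s}, {e}, {lab!r}) extends past recording end "
                f"({rec.n_samples} samples at {rec.rate} Hz)"
            )
        for k in range(e - s + 1):
            lo = (s + k) * n
            chunks.append(rec.data[:, lo : lo + n])
            labels.append(lab)
            t0s.append(s + k)
    x = np.stack(chunks, axis=0) if chunks else np.empty((0, rec.n_channels, n))
    return Epochs(
        x=x,
        labels=np.array(labels, dtype=object),
        t0=np.array(t0s, dtype=int),
        channels=rec.channels,
        rate=rec.rate,
    )


# ---------------------------------------------------------------------------
# Delimited-matrix dialect (TSV + YAML sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _read_delimited(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    try:
        data = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return Recording(
        data=data,
        rate=float(meta["rate"]),
        channels=tuple(meta["channels"]),
        subject_id=str(meta.get("subject_id", "")),
    )


def _write_delimited(rec: Recording, path: Path) -> None:
    np.savetxt(path, rec.data, fmt="%.17g", delimiter="\t")
    meta = {
        "rate": float(rec.rate),
        "channels": list(rec.channels),
        "subject_id": rec.subject_id,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


# ---------------------------------------------------------------------------
# BrainVision dialect
# ---------------------------------------------------------------------------

def _read_brainvision(path: Path) -> Recording:
    import mne

    for ext in (".vmrk", ".eeg"):
        if not path.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing triplet member {path.with_suffix(ext)}")
    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    # mne rescales to volts internally; recordings are kept in microvolts
    data = raw.get_data() * 1e6
    return Recording(
        data=data,
        rate=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        subject_id=path.stem,
    )


def _write_brainvision(rec: Recording, path: Path) -> None:
    """Minimal BrainVision triplet writer (IEEE float32, multiplexed, µV)."""
    base = path.stem
    eeg = path.with_suffix(".eeg")
    vmrk = path.with_suffix(".vmrk")
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        f"MarkerFile={base}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.rate:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.channels, 1):
        header.append(f"Ch{i}={ch},,1,µV")
    path.write_text("\n".join(header) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={base}.eeg\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    rec.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major


def read_recording(path: str | Path, format: str = "delimited") -> Recording:
    """Read a recording in either supported dialect.

    Parameters
    ----------
    path
        Data file: the TSV matrix (delimited) or the ``.vhdr`` (brainvision).
    format
        ``"delimited"`` or ``"brainvision"``.
    """
    path = Path(path)
    if format == "delimited":
        return _read_delimited(path)
    if format == "brainvision":
        return _read_brainvision(path)
    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: Recording, path: str | Path, format: str = "delimited") -> None:
    path = Path(path)
    if format == "delimited":
        _write_delimited(rec, path)
    elif format == "brainvision":
        _write_brainvision(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Selection matrices (channel rows, subject columns, 0/1 cells, Total column)
# ---------------------------------------------------------------------------

def read_selection_matrix(path: str | Path) -> pd.DataFrame:
    """Read a 0/1 channel x subject selection matrix.

    Layout: a header row of subject ids, one row per channel, an optional
    trailing ``Total`` column (validated against the row sums) and an optional
    trailing ``Accuracy (%)`` row (ignored here, retrievable via
    :func:`read_selection_accuracy`).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame = frame[~frame.index.str.startswith("Accuracy")]
    if "Total" in frame.columns:
        totals = frame.pop("Total").astype(int)
    else:
        totals = None
    matrix = frame.astype(int)
    bad = ~matrix.isin([0, 1]).all(axis=None)
    if bad:
        raise ValueError(f"non-binary cell in selection matrix {path}")
    if totals is not None and not (matrix.sum(axis=1) == totals).all():
        raise ValueError(f"Total column does not match row sums in {path}")
    return matrix


def read_selection_accuracy(path: str | Path) -> pd.Series | None:
    """Per-subject accuracy row of a selection-matrix file, if present."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    rows = frame.index[frame.index.str.startswith("Accuracy")]
    if len(rows) == 0:
        return None
    ser = frame.loc[rows[0]].drop(labels=["Total"], errors="ignore")
    return ser.astype(float)


def write_selection_matrix(
    matrix: pd.DataFrame, path: str | Path, accuracy: pd.Series | None = None
) -> None:
    out = matrix.astype(int).copy()
    out["Total"] = out.sum(axis=1)
    out.index.name = "Channel"
    text = out.to_csv(sep="\t")
    if accuracy is not None:
        vals = "\t".join(f"{accuracy[c]:.2f}" for c in matrix.columns)
        text += f"Accuracy (%)\t{vals}\t\n"
    Path(path).write_text(text)
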