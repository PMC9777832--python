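"""Approximate entropy (ApEn) and sample entropy (SampEn) features.

Both statistics quantify the regularity of a short time series by comparing
the frequency of matching templates of length ``m`` against templates of
length ``m + 1``, under the Chebyshev (maximum-coordinate) distance and a
tolerance ``r = r_coeff * STD`` where STD is the population standard
deviation of the series itself.  Matching here is *strict* (``d < r``), and
ApEn includes the self-comparison ``i = j`` while SampEn excludes it — the
conventions this pipeline is defined with.

Definitions used (embedding dimension ``m``, N samples, templates
``X_m(i) = (x(i), ..., x(i+m-1))`` for ``i = 1..N-m+1``):

* ApEn:  ``C_i^m = #{j : d(X_m(i), X_m(j)) < r} / (N-m+1)`` (self-match
  included), ``phi^m = mean_i ln C_i^m``; ``ApEn = phi^m - phi^{m+1}``.
* SampEn: ``B_i^m = #{j != i : d < r} / (N-m)``, ``A^m = mean_i B_i^m`` over
  the ``N-m+1`` templates; ``SampEn = ln A^m - ln A^{m+1}`` (the ``m+1``
  level uses ``N-m`` templates and divisor ``N-m-1``).

Degenerate constant epochs (STD = 0) return 0 for both entropies: every
template matches every other, i.e. perfect regularity.  A zero match count
at either SampEn level is replaced by the smallest attainable positive mean
(a single matching ordered pair) so the logarithm stays defined; such epochs
are flagged via a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Epochs, Recording

__all__ = [
    "EntropyParams",
    "FeatureTable",
    "apen",
    "sampen",
    "entropy_pair",
    "extract_features",
    "prefilter",
]


@dataclass(frozen=True)
class EntropyParams:
    """Template length ``m``, tolerance coefficient and epoch length."""

    m: int = 2
    r_coeff: float = 0.15
    n: int = 500

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r_coeff > 0:
            raise ValueError("r_coeff must be positive")
        if self.n <= self.m + 1:
            raise ValueError("epoch length must exceed m + 1")


def _template_distance_counts(x: np.ndarray, m: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Strict-< Chebyshev match counts at template lengths m and m+1.

    Returns (counts_m, counts_m1) where counts_m[i] includes the self match.
    Built from the running maximum of the lag-aligned |x_i - x_j| matrix, so
    both levels share one pass.
    """
    n = len(x)
    d = np.abs(x[:, None] - x[None, :])
    cur = d
    for k in range(1, m):
        cur = np.maximum(cur[:-1, :-1], d[k:, k:])
    counts_m = (cur[: n - m + 1, : n - m + 1] < r).sum(axis=1)
    nxt = np.maximum(cur[:-1, :-1], d[m:, m:])
    counts_m1 = (nxt < r).sum(axis=1)
    return counts_m, counts_m1


def entropy_pair(x: np.ndarray, params: EntropyParams = EntropyParams()) -> tuple[float, float]:
    """Compute (ApEn, SampEn) of one epoch, sharing the distance pass."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be a 1-D vector")
    n = len(x)
    m = params.m
    if n <= m + 1:
        raise ValueError(f"epoch length {n} too short for m={m}")
    std = x.std()  # population (divisor N)
    if std == 0 or np.ptp(x) == 0:  # constant series (ptp catches fp-dust std)
        warnings.warn("degenerate constant epoch: entropies set to 0", stacklevel=2)
        return 0.0, 0.0
    r = params.r_coeff * std
    counts_m, counts_m1 = _template_distance_counts(x, m, r)

    # ApEn: self-match included, so counts >= 1 and the log is defined
    phi_m = np.log(counts_m / (n - m + 1)).mean()
    phi_m1 = np.log(counts_m1 / (n - m)).mean()
    ap = float(phi_m - phi_m1)

    # SampEn: self-match excluded
    a_m = float((counts_m - 1).sum()) / ((n - m) * (n - m + 1))
    a_m1 = float((counts_m1 - 1).sum()) / ((n - m - 1) * (n - m))
    if a_m == 0.0:
        warnings.warn("no m-length matches: SampEn floored", stacklevel=2)
        a_m = 1.0 / ((n - m) * (n - m + 1))
    if a_m1 == 0.0:
        warnings.warn("no (m+1)-length matches: SampEn floored", stacklevel=2)
        a_m1 = 1.0 / ((n - m - 1) * (n - m))
    se = float(np.log(a_m) - np.log(a_m1))
    return ap, se


def apen(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Approximate entropy of one epoch."""
    return entropy_pair(x, params)[0]


def sampen(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Sample entropy of one epoch."""
    return entropy_pair(x, params)[1]


@dataclass
class FeatureTable:
    """Epoch x feature matrix: two entropy columns per channel, plus labels.

    Columns are named ``<channel>:ApEn`` and ``<channel>:SampEn``; rows align
    with ``labels``.
    """

    values: pd.DataFrame
    labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.values) != len(self.labels):
            raise ValueError("row/label count mismatch")
        if self.values.isna().any(axis=None):
            raise ValueError("feature table contains missing values")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def channels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for col in self.values.columns:
            ch = col.rsplit(":", 1)[0]
            if ch not in seen:
                seen.append(ch)
        return tuple(seen)

    @property
    def n_epochs(self) -> int:
        return len(self.values)

    def select_channels(self, channels) -> "FeatureTable":
        """Restrict to the entropy columns of the named channels."""
        channels = list(channels)
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise KeyError(f"channels not in table: {missing}")
        cols = [f"{c}:{kind}" for c in channels for kind in ("ApEn", "SampEn")]
        return FeatureTable(self.values[cols].copy(), self.labels.copy(), self.subject_id)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, subject_id: str = "") -> "FeatureTable":
        frame = pd.read_csv(path, sep="\t")
        labels = frame.pop("label").to_numpy(dtype=object)
        return cls(frame, labels, subject_id)


def extract_features(epochs: Epochs, params: EntropyParams | None = None,
                     subject_id: str | None = None) -> FeatureTable:
    """Compute the ApEn/SampEn feature table of a set of labelled epochs.

    One row per epoch, two columns per channel; deterministic.
    """
    if params is None:
        params = EntropyParams(n=int(round(epochs.rate)))
    n_ep, n_ch, _ = epochs.x.shape
    values = np.empty((n_ep, 2 * n_ch))
    for c in range(n_ch):
        for i in range(n_ep):
            ap, se = entropy_pair(epochs.x[i, c], params)
            values[i, 2 * c] = ap
            values[i, 2 * c + 1] = se
    cols = [f"{ch}:{kind}" for ch in epochs.channels for kind in ("ApEn", "SampEn")]
    frame = pd.DataFrame(values, columns=cols)
    return FeatureTable(frame, epochs.labels.copy(), subject_id or "")


def prefilter(rec: Recording, notch_hz: float | None = 50.0,
              band: tuple[float, float] | None = (0.5, 47.0)) -> Recording:
    """Optional zero-phase mains notch and band-pass stage.

    Both stages default to the acquisition convention (50 Hz notch,
    0.5–47 Hz band) but the whole stage is opt-in: the pipeline never calls
    it implicitly.  Pass ``None`` to skip either stage.
    """
    from scipy import signal

    nyq = rec.rate / 2.0
    data = rec.data
    if band is not None:
        low, high = band
        if not (0 < low < high < nyq):
            raise ValueError(f"band {band} outside (0, {nyq}) Hz")
        sos = signal.butter(1, [low, high], btype="bandpass", fs=rec.rate, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    if notch_hz is not None:
        if not (0 < notch_hz < nyq):
            raise ValueError(f"notch {notch_hz} Hz outside (0, {nyq}) Hz")
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=rec.rate)
        data = signal.filtfilt(b, a, data, axis=1)
    return Recording(data=data, rate=rec.rate, channels=rec.channels,
                     subject_id=rec.subject_id)
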