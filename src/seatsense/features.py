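"""Sliding-window segmentation and Std / ApEn feature extraction.

The classifier sees one feature row per analysis window over the 4-channel
signal (CoP_x, CoP_y, Gyro_x, Gyro_y).  Two feature families are supported:

* **Std** — the sample standard deviation of each channel in the window,
  a direct measure of sway/swing amplitude.
* **ApEn** — approximate entropy (Pincus), a regularity statistic: it counts
  how often length-m patterns that match within tolerance r continue to
  match at length m+1.  Repetitive signals (a pure swing) score near 0,
  irregular ones (exercise bursts) score high, typically within [0, 2].

ApEn definition used (original Pincus convention):

    x(i) = (u(i), ..., u(i+m-1)),             i = 1..N-m+1
    C_i^m(r) = #{ j : d[x(i), x(j)] <= r } / (N-m+1)   (self-match included)
    Phi^m(r) = (N-m+1)^{-1} sum_i ln C_i^m(r)
    ApEn(N, m, r) = Phi^m(r) - Phi^{m+1}(r)

with d the Chebyshev (max-abs component) distance and r = r_coef * sd of the
window (sample sd, ddof=1).  A constant window has r = 0 and returns ApEn = 0
by convention (a perfectly regular series).  Defaults m = 2, r_coef = 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .cop import CoPSeries
from .datamodel import (
    FEATURE_COLUMNS,
    META_COLUMNS,
    Activity,
    RawStream,
    ValidationError,
    level_of,
)

__all__ = [
    "WindowConfig",
    "ApEnParams",
    "FeatureRow",
    "segment",
    "std_feature",
    "apen",
    "extract_features",
    "feature_frame",
]

logger = logging.getLogger(__name__)

FeatureSet = Literal["std", "apen", "both"]

#: Minimum fraction of window samples that must share the majority label for
#: the window to be kept (windows straddling activity transitions are noise).
DEFAULT_PURITY = 0.9


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: length ``tw`` seconds, fractional overlap."""

    tw: float = 30.0
    overlap: float = 0.5
    fs: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValidationError("overlap must be in [0, 1)")
        if self.n_samples < 4:
            raise ValidationError(
                "window too short: need round(fs*tw) >= 4 samples"
            )

    @property
    def n_samples(self) -> int:
        """Samples per window, N = round(fs * tw)."""
        return int(round(self.fs * self.tw))

    @property
    def stride(self) -> int:
        """Hop between window starts, N*(1-overlap) rounded, at least 1."""
        return max(1, int(round(self.n_samples * (1.0 - self.overlap))))


@dataclass(frozen=True)
class ApEnParams:
    """ApEn parameters: embedding length m and tolerance coefficient.

    The tolerance is r = r_coef * sd(window); 0.2 is the conventional choice
    and m = 2 the standard embedding for short physiological records.
    """

    m: int = 2
    r_coef: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.r_coef <= 0:
            raise ValidationError("r_coef must be > 0")


@dataclass
class FeatureRow:
    """One analysis window: features + label metadata."""

    features: dict[str, float]
    activity: Optional[Activity]
    level: Optional[str]
    subject: Optional[str]
    window_start_s: float


def segment(stream_length: int, cfg: WindowConfig) -> list[tuple[int, int]]:
    """Half-open sample intervals of the sliding windows.

    Windows have exactly ``cfg.n_samples`` samples and consecutive starts
    differ by ``cfg.stride``; a trailing partial window is discarded.  A
    stream shorter than one window yields an empty list.
    """
    n = cfg.n_samples
    if stream_length < n:
        return []
    stride = cfg.stride
    count = (stream_length - n) // stride + 1
    return [(i * stride, i * stride + n) for i in range(count)]


def std_feature(x: np.ndarray) -> float:
    """Sample standard deviation (ddof=1) of a window; requires N >= 2.

    Exactly 0 for a constant window (the mean of a constant float is not
    always bit-exact, so the constant case is detected explicitly).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("std_feature needs at least 2 samples")
    if x.max() == x.min():
        return 0.0
    return float(np.std(x, ddof=1))


def _phi(u: np.ndarray, m: int, r: float) -> float:
    """Phi^m(r): mean log fraction of templates matching within r."""
    n_vec = len(u) - m + 1
    # (n_vec, m) embedding matrix; Chebyshev distances via per-dimension
    # broadcast, taking the running max to avoid a 3-D intermediate.
    emb = np.lib.stride_tricks.sliding_window_view(u, m)
    dist = np.abs(emb[:, None, 0] - emb[None, :, 0])
    for k in range(1, m):
        np.maximum(dist, np.abs(emb[:, None, k] - emb[None, :, k]), out=dist)
    counts = (dist <= r).sum(axis=1)  # self-match included => counts >= 1
    return float(np.mean(np.log(counts / n_vec)))


def apen(x: np.ndarray, p: ApEnParams = ApEnParams()) -> float:
    """Approximate entropy of a window, ApEn = Phi^m - Phi^{m+1}.

    Tolerance r = r_coef * sample sd of the window.  Constant windows
    (r = 0) return 0 by convention.  Requires N >= m + 2 so that the
    (m+1)-embedding has at least two vectors.
    """
    x = np.asarray(x, dtype=float)
    if x.size < p.m + 2:
        raise ValidationError(f"window too short for ApEn: N={x.size}, m={p.m}")
    r = p.r_coef * std_feature(x)
    if r == 0.0:
        return 0.0
    return _phi(x, p.m, r) - _phi(x, p.m + 1, r)


_CHANNEL_SUFFIX = ["cx", "cy", "gx", "gy"]


def extract_features(
    stream: RawStream,
    cop: CoPSeries,
    cfg: WindowConfig = WindowConfig(),
    p: ApEnParams = ApEnParams(),
    sets: FeatureSet = "both",
    purity: float = DEFAULT_PURITY,
) -> list[FeatureRow]:
    """Window the 4-channel signal and compute one feature row per window.

    Windows containing invalid CoP samples (unoccupied seat) are dropped.
    When per-sample labels are present the window label is the majority
    label, and windows whose majority fraction falls below ``purity`` —
    windows straddling an activity transition — are dropped too.  Drops are
    logged, not raised.
    """
    if len(cop) != len(stream):
        raise ValidationError("cop series not aligned with stream")
    if sets not in ("std", "apen", "both"):
        raise ValidationError(f"unknown feature set {sets!r}")
    channels = [cop.cop_x, cop.cop_y, stream.gyro_x, stream.gyro_y]
    rows: list[FeatureRow] = []
    n_dropped_invalid = 0
    n_dropped_impure = 0
    for start, end in segment(len(stream), cfg):
        if not np.all(cop.valid[start:end]):
            n_dropped_invalid += 1
            continue
        activity = None
        if stream.label is not None:
            labels, counts = np.unique(
                stream.label[start:end].astype(str), return_counts=True
            )
            top = int(np.argmax(counts))
            if counts[top] / (end - start) < purity:
                n_dropped_impure += 1
                continue
            activity = Activity(labels[top])
        features: dict[str, float] = {}
        if sets in ("std", "both"):
            for suffix, ch in zip(_CHANNEL_SUFFIX, channels):
                features[f"std_{suffix}"] = std_feature(ch[start:end])
        if sets in ("apen", "both"):
            for suffix, ch in zip(_CHANNEL_SUFFIX, channels):
                features[f"apen_{suffix}"] = apen(ch[start:end], p)
        rows.append(
            FeatureRow(
                features=features,
                activity=activity,
                level=level_of(activity).value if activity else None,
                subject=stream.subject,
                window_start_s=float(stream.t[start]),
            )
        )
    if n_dropped_invalid or n_dropped_impure:
        logger.info(
            "dropped %d window(s) with unoccupied-seat samples and %d with "
            "mixed labels (purity < %.2f)",
            n_dropped_invalid,
            n_dropped_impure,
            purity,
        )
    return rows


def feature_frame(rows: Sequence[FeatureRow]) -> pd.DataFrame:
    """Feature rows as a DataFrame in the canonical column order."""
    if not rows:
        return pd.DataFrame(columns=FEATURE_COLUMNS + META_COLUMNS)
    feature_cols = [c for c in FEATURE_COLUMNS if c in rows[0].features]
    data = {c: [r.features[c] for r in rows] for c in feature_cols}
    data["activity"] = [r.activity.value if r.activity else None for r in rows]
    data["level"] = [r.level for r in rows]
    data["subject"] = [r.subject for r in rows]
    data["window_start_s"] = [r.window_start_s for r in rows]
    return pd.DataFrame(data)
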