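"""Reading, writing and aligning chest-belt sessions.

A *session* is a uniformly sampled single-channel breathing signal (ADC
counts from a piezoelectric chest belt, nominally 12-bit at 100 Hz)
together with an annotation track of ground-truth intake events
(swallow / drink timestamps from a push button, video review, or the
simulator).

File formats are deliberately plain text:

* signal file — two tab-separated columns ``time_s`` and ``adc_count``
  with a header line;
* annotation file — one event per line, ``time_s`` optionally followed
  by a tab and an event kind (``swallow`` is assumed when absent);
* models — JSON (see :mod:`swallowsense.svm` / :mod:`swallowsense.hmm`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawSignal",
    "AnnotationTrack",
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "read_session",
    "label_cycles",
]

EVENT_KINDS = ("swallow", "drink")


@dataclass
class RawSignal:
    """A timestamped ADC sample stream.

    Attributes
    ----------
    times : ndarray of float
        Sample timestamps in seconds, strictly increasing and uniform at
        ``1 / sampling_rate``.
    samples : ndarray of float
        ADC counts (integers for quantized data; filtering produces floats).
    sampling_rate : float
        Nominal sampling rate in Hz.
    subject_id, session_id : str
        Opaque identifiers carried through the pipeline.
    """

    times: np.ndarray
    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty signal")
        if len(self.times) != len(self.samples):
            raise ValueError(
                f"times ({len(self.times)}) and samples ({len(self.samples)}) "
                "must have equal length"
            )
        dt = np.diff(self.times)
        if dt.size and dt.min() <= 0:
            raise ValueError("timestamps must be strictly increasing")
        if dt.size and dt.max() > 1.5 / self.sampling_rate:
            raise ValueError(
                "gap between consecutive samples exceeds 1.5 / sampling_rate"
            )

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class AnnotationTrack:
    """Ground-truth intake events aligned to a signal's clock."""

    event_times: np.ndarray
    event_kinds: Sequence[str] = field(default_factory=list)
    source: str = "button"

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if len(self.event_kinds) == 0:
            self.event_kinds = ["swallow"] * len(self.event_times)
        if len(self.event_kinds) != len(self.event_times):
            raise ValueError("event_kinds and event_times length mismatch")
        for k in self.event_kinds:
            if k not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {k!r}")
        order = np.argsort(self.event_times, kind="stable")
        self.event_times = self.event_times[order]
        self.event_kinds = [self.event_kinds[i] for i in order]

    def shifted(self, offset: float) -> "AnnotationTrack":
        """Return a copy with a constant clock offset added (seconds)."""
        return AnnotationTrack(self.event_times + offset, list(self.event_kinds), self.source)

    def __len__(self) -> int:
        return len(self.event_times)


def write_signal(path: str | Path, signal: RawSignal) -> None:
    df = pd.DataFrame({"time_s": signal.times, "adc_count": signal.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_signal(
    path: str | Path,
    sampling_rate: float | None = None,
    subject_id: str = "",
    session_id: str = "",
) -> RawSignal:
    """Read a two-column tab-separated signal file.

    The sampling rate is inferred from the median timestamp spacing when
    not given explicitly.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse signal file {path}: {exc}") from exc
    for col in ("time_s", "adc_count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    numeric = df[["time_s", "adc_count"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric[numeric.isna().any(axis=1)]
    if len(bad):
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: malformed value on line {bad.index[0] + 2}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty signal")
    df = numeric
    times = df["time_s"].to_numpy(float)
    if sampling_rate is None:
        if len(times) < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from one sample")
        sampling_rate = 1.0 / float(np.median(np.diff(times)))
    return RawSignal(times, df["adc_count"].to_numpy(float), sampling_rate,
                     subject_id=subject_id, session_id=session_id or path.stem)


def write_annotations(path: str | Path, track: AnnotationTrack) -> None:
    with open(path, "w") as fh:
        for t, kind in zip(track.event_times, track.event_kinds):
            if kind == "swallow":
                fh.write(f"{t:.10g}\n")
            else:
                fh.write(f"{t:.10g}\t{kind}\n")


def read_annotations(path: str | Path, source: str = "button") -> AnnotationTrack:
    path = Path(path)
    times: list[float] = []
    kinds: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                times.append(float(parts[0]))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            kind = parts[1].strip() if len(parts) > 1 else "swallow"
            if kind not in EVENT_KINDS:
                raise ValueError(f"{path}: malformed line {lineno}: unknown kind {kind!r}")
            kinds.append(kind)
    return AnnotationTrack(np.asarray(times), kinds, source=source)


def read_session(
    signal_path: str | Path,
    annotation_path: str | Path | None = None,
    *,
    sampling_rate: float | None = None,
    annotation_offset: float = 0.0,
    subject_id: str = "",
    session_id: str = "",
) -> tuple[RawSignal, AnnotationTrack]:
    """Read a signal + annotation pair and validate their alignment.

    Annotations are assumed pre-synchronized to the signal clock; pass
    ``annotation_offset`` (seconds) to correct a known constant skew.
    Events falling outside the signal's time span are kept but reported
    with a warning.
    """
    signal = read_signal(signal_path, sampling_rate=sampling_rate,
                         subject_id=subject_id, session_id=session_id)
    if annotation_path is None:
        track = AnnotationTrack(np.empty(0), [])
    else:
        track = read_annotations(annotation_path)
    if annotation_offset:
        track = track.shifted(annotation_offset)
    out_of_span = (track.event_times < signal.times[0]) | (track.event_times > signal.times[-1])
    if out_of_span.any():
        warnings.warn(
            f"{int(out_of_span.sum())} annotation(s) outside the signal time span "
            f"[{signal.times[0]:.3f}, {signal.times[-1]:.3f}] s",
            stacklevel=2,
        )
    return signal, track


def label_cycles(cycles, annotations: AnnotationTrack):
    """Assign per-cycle labels from an annotation track.

    A cycle is labeled *swallow* (1) iff at least one swallow event time
    falls in its half-open interval ``[start, end)``; a drink event flags
    the containing cycle for exclusion from training and evaluation
    (the study removed drinking cycles before processing).

    Parameters
    ----------
    cycles : sequence of BreathingCycle
        Non-overlapping, time-sorted cycles.
    annotations : AnnotationTrack

    Returns
    -------
    labels : ndarray of int
        1 for swallow cycles, 0 for normal cycles.
    excluded : ndarray of bool
        True for cycles containing a drink event.
    """
    starts = np.array([c.start_time for c in cycles])
    ends = np.array([c.end_time for c in cycles])
    labels = np.zeros(len(cycles), dtype=int)
    excluded = np.zeros(len(cycles), dtype=bool)
    for t, kind in zip(annotations.event_times, annotations.event_kinds):
        hit = np.flatnonzero((starts <= t) & (t < ends))
        if hit.size == 0:
            warnings.warn(f"event at t={t:.3f} s falls in no cycle; ignored", stacklevel=2)
            continue
        i = int(hit[0])
        if kind == "swallow":
            labels[i] = 1
        else:
            excluded[i] = True
    return labels, excluded
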