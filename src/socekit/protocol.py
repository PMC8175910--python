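"""Solution-exchange protocols for SOCE imaging experiments.

A :class:`SolutionProtocol` is an ordered, contiguous list of solution
segments, each with an extracellular Ca2+ concentration ([Ca2+]o, mM) and a
flag for thapsigargin (Tg) presence.  The standard store-operated Ca2+ entry
(SOCE) protocol has four phases:

1. Ca2+-free baseline (no Tg),
2. Ca2+-free store depletion with Tg (SERCA block empties the ER),
3. Ca2+ re-addition (SOCE influx: a peak decaying to a plateau),
4. Ca2+ removal (pure-efflux decay driven by plasma-membrane extrusion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .errors import ProtocolError, ValidationError

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """One solution segment: ``[start_s, end_s)`` with fixed [Ca2+]o and Tg."""

    start_s: float
    end_s: float
    ca_o_mm: float
    tg: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite([self.start_s, self.end_s, self.ca_o_mm]).all():
            raise ValidationError("segment fields must be finite")
        if self.end_s <= self.start_s:
            raise ValidationError(
                f"segment must have positive duration, got [{self.start_s}, {self.end_s}]"
            )
        if self.ca_o_mm < 0:
            raise ValidationError(f"[Ca2+]o must be >= 0, got {self.ca_o_mm}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SolutionProtocol:
    """Ordered, contiguous, non-overlapping solution segments."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValidationError("protocol needs at least one segment")
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if abs(nxt.start_s - prev.end_s) > _EPS:
                raise ValidationError(
                    f"segments must be contiguous: {prev.end_s} != {nxt.start_s}"
                )

    # -- basic geometry ---------------------------------------------------
    @property
    def start_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    # -- segment lookup ----------------------------------------------------
    def ca_o(self, t):
        """[Ca2+]o (mM) at time(s) ``t``; the final segment is closed at its end."""
        return self._field_at(t, np.array([s.ca_o_mm for s in self.segments]))

    def tg_active(self, t):
        """Whether Tg is present at time(s) ``t``."""
        vals = np.array([float(s.tg) for s in self.segments])
        return self._field_at(t, vals) > 0.5

    def _field_at(self, t, values: np.ndarray):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.start_s - _EPS) or np.any(t > self.end_s + _EPS):
            raise ValidationError("time outside protocol span")
        starts = np.array([s.start_s for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t + _EPS, side="right") - 1, 0, len(starts) - 1)
        out = values[idx]
        return out if out.ndim else out[()]

    @property
    def tg_onset_s(self) -> float | None:
        """Start time of the first Tg-containing segment, or None."""
        for s in self.segments:
            if s.tg:
                return s.start_s
        return None

    # -- named segments of the standard SOCE protocol ---------------------
    @property
    def baseline_segment(self) -> Segment:
        """Pre-Tg Ca2+-free segment (the first segment)."""
        s = self.segments[0]
        if s.tg or s.ca_o_mm != 0:
            raise ProtocolError("protocol has no Ca2+-free, Tg-free baseline segment")
        return s

    @property
    def readdition_segment(self) -> Segment:
        """The unique segment with maximal [Ca2+]o (the re-addition phase)."""
        ca = [s.ca_o_mm for s in self.segments]
        top = max(ca)
        if top <= 0:
            raise ProtocolError("protocol has no Ca2+ re-addition segment")
        hits = [s for s in self.segments if s.ca_o_mm == top]
        if len(hits) != 1:
            raise ProtocolError("re-addition segment is ambiguous (ties in max [Ca2+]o)")
        return hits[0]

    @property
    def removal_segment(self) -> Segment:
        """Terminal 0-Ca2+ segment following re-addition."""
        s = self.segments[-1]
        if s.ca_o_mm != 0:
            raise ProtocolError("terminal segment is not Ca2+-free (no removal phase)")
        if s.start_s < self.readdition_segment.end_s - _EPS:
            raise ProtocolError("removal segment must follow the re-addition segment")
        return s

    def segment_mask(self, t: np.ndarray, segment: Segment) -> np.ndarray:
        """Boolean mask of samples in ``[start, end)``; the last protocol
        segment also owns its right endpoint."""
        t = np.asarray(t, dtype=float)
        mask = (t >= segment.start_s - _EPS) & (t < segment.end_s - _EPS)
        if segment == self.segments[-1]:
            mask |= np.abs(t - segment.end_s) <= _EPS
        return mask

    # -- transforms & serialization ---------------------------------------
    def shift(self, offset_s: float) -> "SolutionProtocol":
        """Uniform time shift of every segment (metrics are shift-invariant)."""
        return SolutionProtocol(
            tuple(
                replace(s, start_s=s.start_s + offset_s, end_s=s.end_s + offset_s)
                for s in self.segments
            )
        )

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "start_s": float(s.start_s),
                    "end_s": float(s.end_s),
                    "ca_o_mm": float(s.ca_o_mm),
                    "tg": bool(s.tg),
                }
                for s in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SolutionProtocol":
        return cls(
            tuple(
                Segment(seg["start_s"], seg["end_s"], seg["ca_o_mm"], bool(seg["tg"]))
                for seg in d["segments"]
            )
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SolutionProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_standard_protocol(
    baseline_s: float = 60.0,
    tg_s: float = 240.0,
    readd_s: float = 300.0,
    removal_s: float = 120.0,
    ca_readd_mm: float = 1.0,
) -> SolutionProtocol:
    """Standard four-phase SOCE protocol.

    Parameters are phase durations in seconds plus the re-addition [Ca2+]o
    in mM.  Returns contiguous segments: Ca2+-free baseline, Ca2+-free + Tg,
    Ca2+ re-addition (Tg), Ca2+ removal (Tg).
    """
    durations = (baseline_s, tg_s, readd_s, removal_s)
    if any(d <= 0 for d in durations):
        raise ValidationError(f"all phase durations must be > 0, got {durations}")
    if ca_readd_mm <= 0:
        raise ValidationError(f"re-addition [Ca2+]o must be > 0, got {ca_readd_mm}")
    b = np.cumsum((0.0,) + durations)
    return SolutionProtocol(
        (
            Segment(b[0], b[1], 0.0, tg=False),
            Segment(b[1], b[2], 0.0, tg=True),
            Segment(b[2], b[3], ca_readd_mm, tg=True),
            Segment(b[3], b[4], 0.0, tg=True),
        )
    )
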