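"""Per-cell SOCE descriptors: baseline, Peak, Plateau, retained fraction.

Conventions follow common practice for Tg/re-addition SOCE experiments:

* **Peak** — maximum [Ca2+]i restricted to the Ca2+ re-addition segment
  (the Tg store-release transient is deliberately excluded), reported with
  the time of first attainment.
* **Plateau** — mean [Ca2+]i over the 25 s immediately preceding external
  Ca2+ removal (window closed on the left, open on the right; the sample
  values themselves are averaged, no interpolation).
* **Retained fraction** — Plateau/Peak computed *per cell*, never as a
  ratio of population means.

Cells whose response above baseline is smaller than a noise-based threshold
are flagged ``non_responder`` and should be excluded from population
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ProtocolError, ValidationError, WindowError
from .simulate import CalciumTrace

DEFAULT_PLATEAU_WINDOW_S = 25.0


@dataclass
class SoceMetrics:
    cell_id: str
    population: str
    baseline: float
    peak: float
    peak_time: float
    plateau: float
    retained_fraction: float
    qc_flags: set[str] = field(default_factory=set)


def compute_baseline(trace: CalciumTrace) -> float:
    """Mean [Ca2+]i over the pre-Tg Ca2+-free segment (needs >= 3 samples)."""
    seg = trace.protocol.baseline_segment
    mask = trace.protocol.segment_mask(trace.t, seg)
    if mask.sum() < 3:
        raise ProtocolError(
            f"baseline segment holds {int(mask.sum())} samples; >= 3 required"
        )
    return float(trace.ca_i[mask].mean())


def compute_peak(trace: CalciumTrace) -> tuple[float, float]:
    """(peak, peak_time) within the re-addition segment; ties -> earliest."""
    seg = trace.protocol.readdition_segment
    mask = trace.protocol.segment_mask(trace.t, seg)
    if mask.sum() < 3:
        raise ProtocolError("re-addition segment holds < 3 samples")
    ca = trace.ca_i[mask]
    t = trace.t[mask]
    i = int(np.argmax(ca))  # argmax returns the first maximum
    return float(ca[i]), float(t[i])


def compute_plateau(trace: CalciumTrace, window_s: float = DEFAULT_PLATEAU_WINDOW_S) -> float:
    """Mean [Ca2+]i over ``[t_removal - window_s, t_removal)``."""
    t_removal = trace.protocol.removal_segment.start_s
    readd = trace.protocol.readdition_segment
    if readd.duration_s < window_s:
        raise WindowError(
            f"plateau window {window_s} s exceeds re-addition duration "
            f"{readd.duration_s} s"
        )
    mask = (trace.t >= t_removal - window_s) & (trace.t < t_removal)
    if not mask.any():
        raise WindowError("no samples inside the plateau window")
    return float(trace.ca_i[mask].mean())


def compute_retained_fraction(metrics: SoceMetrics) -> float:
    """Plateau/Peak for one cell; peak <= 0 flags a non-responder (NaN)."""
    if metrics.peak <= 0:
        metrics.qc_flags.add("non_responder")
        return float("nan")
    return metrics.plateau / metrics.peak


class SoceMetricsExtractor(BaseEstimator, TransformerMixin):
    """Extract per-cell SOCE metrics from annotated traces.

    Parameters
    ----------
    plateau_window_s : float, default 25
        Averaging window before Ca2+ removal defining the Plateau.
    subtract_baseline : bool, default False
        Report peak/plateau (and their ratio) relative to the pre-Tg
        baseline instead of raw values.
    nonresponder_factor : float, default 3
        Cells with ``peak - baseline`` below this multiple of the noise sd
        estimate are flagged ``non_responder``.
    noise_sd : float or None
        Measurement noise sd in nM.  When None, :meth:`fit` estimates it as
        the median over cells of ``std(diff(baseline)) / sqrt(2)``.

    Attributes
    ----------
    noise_sd_ : float
        Noise sd used for the non-responder threshold.
    """

    def __init__(
        self,
        plateau_window_s: float = DEFAULT_PLATEAU_WINDOW_S,
        subtract_baseline: bool = False,
        nonresponder_factor: float = 3.0,
        noise_sd: float | None = None,
    ):
        self.plateau_window_s = plateau_window_s
        self.subtract_baseline = subtract_baseline
        self.nonresponder_factor = nonresponder_factor
        self.noise_sd = noise_sd

    def fit(self, X, y=None):
        if not X:
            raise ValidationError("no traces provided")
        if self.noise_sd is not None:
            self.noise_sd_ = float(self.noise_sd)
        else:
            ests = []
            for tr in X:
                mask = tr.protocol.segment_mask(tr.t, tr.protocol.baseline_segment)
                if mask.sum() >= 3:
                    ests.append(np.diff(tr.ca_i[mask]).std(ddof=1) / np.sqrt(2.0))
            self.noise_sd_ = float(np.median(ests)) if ests else 0.0
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "noise_sd_"):
            self.fit(X)
        rows = []
        for tr in X:
            m = self.extract(tr)
            rows.append(
                {
                    "cell_id": m.cell_id,
                    "population": m.population,
                    "baseline": m.baseline,
                    "peak": m.peak,
                    "peak_time": m.peak_time,
                    "plateau": m.plateau,
                    "retained_fraction": m.retained_fraction,
                    "qc_flags": ";".join(sorted(m.qc_flags)),
                }
            )
        return pd.DataFrame(rows)

    def extract(self, trace: CalciumTrace) -> SoceMetrics:
        """Metrics of one trace, applying the configured conventions."""
        baseline = compute_baseline(trace)
        peak, peak_time = compute_peak(trace)
        plateau = compute_plateau(trace, self.plateau_window_s)
        if self.subtract_baseline:
            peak_v, plateau_v = peak - baseline, plateau - baseline
        else:
            peak_v, plateau_v = peak, plateau
        m = SoceMetrics(
            cell_id=trace.cell_id,
            population=trace.population,
            baseline=baseline,
            peak=peak_v,
            peak_time=peak_time,
            plateau=plateau_v,
            retained_fraction=float("nan"),
        )
        noise_sd = getattr(self, "noise_sd_", self.noise_sd or 0.0)
        if peak - baseline < self.nonresponder_factor * noise_sd:
            m.qc_flags.add("non_responder")
        m.retained_fraction = compute_retained_fraction(m)
        return m


def extract_metrics(traces, **kwargs) -> pd.DataFrame:
    """Functional wrapper around :class:`SoceMetricsExtractor`."""
    return SoceMetricsExtractor(**kwargs).fit(traces).transform(traces)
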