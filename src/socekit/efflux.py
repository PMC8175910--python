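"""Ca2+ efflux-rate estimation and iso-cell binning.

Two per-cell efflux estimators are provided, mirroring the two phases of
the SOCE protocol in which clearance can be read out:

* ``rate_with_cao`` — magnitude of the steepest negative slope of the
  (lightly smoothed) trace between the peak and external Ca2+ removal,
  i.e. clearance while influx is still present.
* ``rate_post_removal`` — a constrained mono-exponential fit
  ``C(t) = C_inf + (C0 - C_inf) * exp(-(t - t0)/tau)`` over the terminal
  0-Ca2+ segment; the reported rate is the initial-slope magnitude
  ``(C0 - C_inf)/tau``.  When the fit fails the steepest-slope estimator
  is used as a fallback and ``tau`` is reported absent.

Because extrusion is steeply Ca2+-dependent, raw rates are only comparable
between cells at matched [Ca2+]i.  ``bin_iso_cells`` therefore groups cells
into left-closed [Ca2+]i bins ("iso-cells") by their peak or plateau and
summarises the matched rate per bin and population; ``compare_iso_bins``
runs the two-group decision scheme per sufficiently populated bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .metrics import SoceMetricsExtractor
from .simulate import CalciumTrace
from .stats import select_two_group_test

DEFAULT_BIN_EDGES = np.arange(0.0, 1000.0 + 1e-9, 50.0)

#: bin key -> rate column compared within that binning
RATE_FOR_KEY = {"peak": "rate_with_cao", "plateau": "rate_post_removal"}


@dataclass
class EffluxEstimate:
    cell_id: str
    rate_with_cao: float
    rate_post_removal: float
    tau: float
    fit_rsq: float
    method: str
    qc_flags: set[str]


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="valid")


def _steepest_negative_slope(t: np.ndarray, y: np.ndarray, window: int) -> float:
    """|steepest negative slope| after moving-average smoothing; 0 if the
    trace never decreases."""
    ys = _smooth(y, window)
    ts = t[(window - 1) // 2 : len(t) - window // 2] if window > 1 else t
    grad = np.gradient(ys, ts)
    steepest = float(grad.min())
    return max(0.0, -steepest)


def estimate_rate_with_cao(
    trace: CalciumTrace,
    peak_time: float,
    smooth_window: int = 3,
    min_samples: int = 5,
) -> tuple[float, set[str]]:
    """Efflux rate in the presence of [Ca2+]o (peak -> removal window).

    Returns ``(rate, qc_flags)``; a too-short decay window yields NaN with
    the ``short_decay_window`` flag instead of an error.
    """
    t_removal = trace.protocol.removal_segment.start_s
    mask = (trace.t >= peak_time) & (trace.t < t_removal)
    if mask.sum() < max(min_samples, smooth_window + 2):
        return float("nan"), {"short_decay_window"}
    rate = _steepest_negative_slope(trace.t[mask], trace.ca_i[mask], smooth_window)
    return rate, set()


def estimate_post_removal_decay(
    trace: CalciumTrace,
    smooth_window: int = 3,
    min_samples: int = 8,
) -> EffluxEstimate:
    """Mono-exponential decay fit over the terminal 0-Ca2+ segment.

    ``C_inf >= 0`` is enforced; initial guesses come from the first/last
    samples.  Flat segments are flagged with ``tau`` undefined; fit failures
    fall back to the steepest-slope estimator.
    """
    seg = trace.protocol.removal_segment
    mask = trace.protocol.segment_mask(trace.t, seg)
    if mask.sum() < min_samples:
        raise ValidationError(
            f"removal segment holds {int(mask.sum())} samples; >= {min_samples} required"
        )
    t = trace.t[mask]
    y = trace.ca_i[mask]
    t0 = t[0]
    flags: set[str] = set()

    if np.ptp(y) == 0.0:
        return EffluxEstimate(
            trace.cell_id, float("nan"), float("nan"), float("nan"), 0.0,
            "none", {"flat_segment"},
        )

    def model(tt, c_inf, amp, tau):
        return c_inf + amp * np.exp(-(tt - t0) / tau)

    amp0 = max(float(y[0] - y[-1]), 1e-6)
    p0 = (max(float(y[-1]), 0.0), amp0, max((t[-1] - t0) / 3.0, 1e-3))
    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            xtol=1e-8, ftol=1e-8, maxfev=2000,
        )
        c_inf, amp, tau = (float(v) for v in popt)
        resid = y - model(t, *popt)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        rsq = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
        rmse = float(np.sqrt((resid ** 2).mean()))
        if amp <= 3.0 * rmse:
            flags.add("flat_decay")
            return EffluxEstimate(
                trace.cell_id, float("nan"), float("nan"), float("nan"),
                max(rsq, 0.0), "none", flags,
            )
        rate = amp / tau
        return EffluxEstimate(
            trace.cell_id, float("nan"), rate, tau, min(max(rsq, 0.0), 1.0),
            "exponential", flags,
        )
    except RuntimeError:
        flags.add("fit_failed")
        rate = _steepest_negative_slope(t, y, smooth_window)
        return EffluxEstimate(
            trace.cell_id, float("nan"), rate, float("nan"), 0.0,
            "steepest_slope", flags,
        )


class EffluxEstimator(BaseEstimator, TransformerMixin):
    """Per-cell efflux rates from annotated traces.

    The peak time needed to open the in-Ca2+ decay window is computed with
    a :class:`~socekit.metrics.SoceMetricsExtractor` sharing this
    estimator's plateau window.
    """

    def __init__(
        self,
        smooth_window: int = 3,
        min_decay_samples: int = 5,
        min_removal_samples: int = 8,
        plateau_window_s: float = 25.0,
    ):
        self.smooth_window = smooth_window
        self.min_decay_samples = min_decay_samples
        self.min_removal_samples = min_removal_samples
        self.plateau_window_s = plateau_window_s

    def fit(self, X, y=None):
        if not X:
            raise ValidationError("no traces provided")
        self.n_traces_ = len(X)
        return self

    def transform(self, X) -> pd.DataFrame:
        extractor = SoceMetricsExtractor(plateau_window_s=self.plateau_window_s)
        extractor.fit(X)
        rows = []
        for tr in X:
            m = extractor.extract(tr)
            rate_cao, flags = estimate_rate_with_cao(
                tr, m.peak_time, self.smooth_window, self.min_decay_samples
            )
            est = estimate_post_removal_decay(
                tr, self.smooth_window, self.min_removal_samples
            )
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "population": tr.population,
                    "rate_with_cao": rate_cao,
                    "rate_post_removal": est.rate_post_removal,
                    "tau": est.tau,
                    "fit_rsq": est.fit_rsq,
                    "method": est.method,
                    "qc_flags": ";".join(sorted(flags | est.qc_flags)),
                }
            )
        return pd.DataFrame(rows)


def estimate_efflux(traces, **kwargs) -> pd.DataFrame:
    """Functional wrapper around :class:`EffluxEstimator`."""
    return EffluxEstimator(**kwargs).fit(traces).transform(traces)


# ---------------------------------------------------------------------------
# iso-cell binning
# ---------------------------------------------------------------------------

@dataclass
class IsoBinTable:
    """Iso-cell binning result.

    ``cells`` carries one row per binnable cell with its assigned bin;
    ``summary`` holds per-bin, per-population n/mean/sem of the matched
    rate.  ``n_below`` and ``n_dropped`` count cells below the first and at
    or above the last edge (reported, not silently lost).
    """

    bin_key: str
    bin_edges: np.ndarray
    cells: pd.DataFrame
    summary: pd.DataFrame
    n_below: int
    n_dropped: int

    @property
    def n_binnable(self) -> int:
        return len(self.cells) + self.n_below + self.n_dropped


def bin_iso_cells(
    table: pd.DataFrame,
    bin_key: str = "peak",
    bin_edges=None,
) -> IsoBinTable:
    """Assign cells to left-closed [Ca2+]i bins and summarise matched rates.

    ``table`` must hold the merged metrics + efflux columns (``peak`` or
    ``plateau``, ``population`` and the matched rate column).  Cells with a
    NaN bin value or NaN rate are not binnable and are excluded up front.
    """
    if bin_key not in RATE_FOR_KEY:
        raise ValidationError(f"bin_key must be one of {sorted(RATE_FOR_KEY)}")
    rate_col = RATE_FOR_KEY[bin_key]
    for col in (bin_key, rate_col, "population"):
        if col not in table.columns:
            raise ValidationError(f"table missing column {col!r}")
    edges = np.asarray(
        DEFAULT_BIN_EDGES if bin_edges is None else bin_edges, dtype=float
    )
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be >= 2 strictly increasing values")

    if table.empty:
        empty = pd.DataFrame(columns=["bin", "population", "n", "mean_rate", "sem_rate"])
        return IsoBinTable(bin_key, edges, table.copy(), empty, 0, 0)

    ok = table[bin_key].notna() & table[rate_col].notna()
    if "qc_flags" in table.columns:
        ok &= ~table["qc_flags"].fillna("").str.contains("non_responder")
    binnable = table[ok].copy()
    vals = binnable[bin_key].to_numpy(float)
    n_below = int((vals < edges[0]).sum())
    n_dropped = int((vals >= edges[-1]).sum())
    inside = (vals >= edges[0]) & (vals < edges[-1])
    cells = binnable[inside].copy()
    cells["bin"] = pd.cut(cells[bin_key], bins=edges, right=False)

    grouped = cells.groupby(["bin", "population"], observed=True)[rate_col]
    summary = grouped.agg(n="count", mean_rate="mean", sem_rate="sem").reset_index()
    summary = summary[summary["n"] > 0].reset_index(drop=True)
    return IsoBinTable(bin_key, edges, cells, summary, n_below, n_dropped)


def compare_iso_bins(
    table: IsoBinTable,
    min_n: int = 10,
    alpha_norm: float = 0.05,
) -> pd.DataFrame:
    """Two-group decision-scheme test of per-cell rates in each iso-bin.

    Bins where either population has fewer than ``min_n`` cells are
    reported as ``untested`` (sparse bins do not support inference).
    """
    pops = sorted(table.cells["population"].unique()) if len(table.cells) else []
    if len(pops) != 2:
        raise ValidationError(
            f"compare_iso_bins needs exactly two populations, got {pops!r}; "
            "use socekit.stats.compare_groups for the multi-group path"
        )
    rate_col = RATE_FOR_KEY[table.bin_key]
    rows = []
    for b, grp in table.cells.groupby("bin", observed=True):
        a = grp.loc[grp["population"] == pops[0], rate_col].to_numpy(float)
        c = grp.loc[grp["population"] == pops[1], rate_col].to_numpy(float)
        row = {
            "bin": b,
            f"n_{pops[0]}": len(a),
            f"n_{pops[1]}": len(c),
            f"mean_{pops[0]}": a.mean() if len(a) else float("nan"),
            f"mean_{pops[1]}": c.mean() if len(c) else float("nan"),
        }
        if len(a) >= min_n and len(c) >= min_n:
            res = select_two_group_test(a, c, alpha_norm=alpha_norm)
            row.update(
                status="tested", test_name=res.test_name,
                statistic=res.statistic, p_value=res.p_value, stars=res.stars,
            )
        else:
            row.update(
                status="untested", test_name="", statistic=float("nan"),
                p_value=float("nan"), stars="",
            )
        rows.append(row)
    return pd.DataFrame(rows)


class IsoCellBinner(BaseEstimator):
    """sklearn-style wrapper: ``fit`` bins the table, ``compare`` tests bins.

    Attributes (after ``fit``): ``table_`` (:class:`IsoBinTable`).
    """

    def __init__(self, bin_key: str = "peak", bin_edges=None, min_n: int = 10):
        self.bin_key = bin_key
        self.bin_edges = bin_edges
        self.min_n = min_n

    def fit(self, X: pd.DataFrame, y=None):
        self.table_ = bin_iso_cells(X, self.bin_key, self.bin_edges)
        return self

    def compare(self) -> pd.DataFrame:
        if not hasattr(self, "table_"):
            raise ValidationError("IsoCellBinner is not fitted")
        return compare_iso_bins(self.table_, min_n=self.min_n)
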