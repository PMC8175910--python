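"""Mechanistic synthetic Fura-2-style Ca2+ trace generator.

The single-cell model tracks cytosolic [Ca2+]i ``C`` (nM) driven by
store-operated influx, a transient store-release pulse, a constant leak and
a Ca2+-dependent plasma-membrane extrusion pump (PMCA-like Hill kinetics)::

    dC/dt = influx_gain * ca_o(t) * d(t) + r(t) + leak - v_max * m(t)
    dm/dt = (Hill(C) - m) / tau_m,         Hill(C) = C^h / (k_half^h + C^h)
    tau_m = pump_tau       while Hill(C) > m   (slow activation)
          = pump_tau_down  while Hill(C) <= m  (faster relaxation)

``d(t)`` is the store-depletion state, rising from 0 to 1 after Tg onset
with time constant ``store_release_tau`` (Tg blocks SERCA, so stores stay
empty and SOCE stays on).  ``r(t)`` is the store-release flux pulse after
Tg onset carrying a total of ``store_release_amp`` nM.  The pump activation
``m`` follows the instantaneous Hill drive with a first-order lag,
reflecting the well-described slow Ca2+-dependent modulation of PMCA
activity; the slow build-up is what produces the influx peak that relaxes
to a plateau while extracellular Ca2+ is still present, while the faster
relaxation keeps the pump from running [Ca2+]i unphysiologically close to
zero once influx stops.  At steady state ``m = Hill(C)``, so the plateau
C* satisfies the balance::

    influx_gain * ca_o + leak = v_max * C*^h / (k_half^h + C*^h)

Gaussian measurement noise (sd ``noise_sd``) is added to the emitted
samples after integration.  Integration uses a fixed-step explicit scheme
with 0.1 s substeps; emitted traces are sampled at ``dt`` (default 2 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError, ValidationError
from .protocol import SolutionProtocol

_SUBSTEP_S = 0.1  # internal integration step

#: CellParams fields that vary log-normally between cells by default
DEFAULT_VARIABLE_FIELDS: Mapping[str, float] = {
    "v_max": 0.25,
    "influx_gain": 0.25,
    "baseline_ca": 0.25,
}


@dataclass(frozen=True)
class CellParams:
    """Ground-truth parameters of one simulated cell.

    Units: rates nM/s, concentrations nM, times s; ``influx_gain`` is
    nM/s per mM extracellular Ca2+.  Defaults describe a naive-like CD4+
    T cell; memory-like cells carry roughly double the extrusion capacity
    ``v_max``.
    """

    v_max: float = 40.0
    k_half: float = 400.0
    hill_h: float = 2.0
    influx_gain: float = 10.0
    store_release_amp: float = 150.0
    store_release_tau: float = 30.0
    leak: float = 1.5
    baseline_ca: float = 80.0
    pump_tau: float = 40.0
    pump_tau_down: float = 10.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = (
            "v_max", "k_half", "influx_gain", "store_release_amp",
            "store_release_tau", "leak", "baseline_ca", "noise_sd",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.hill_h < 1:
            raise ValidationError(f"hill_h must be >= 1, got {self.hill_h}")
        if self.pump_tau <= 0 or self.pump_tau_down <= 0:
            raise ValidationError("pump_tau and pump_tau_down must be > 0")


@dataclass(frozen=True)
class PopulationSpec:
    """A population of cells sharing parameter medians.

    ``cv`` gives the per-field coefficient of variation of log-normal
    cell-to-cell variability (median-preserving).  ``pump_scale``
    multiplies each cell's drawn ``v_max`` and models pharmacological PMCA
    block or siRNA knockdown when < 1.
    """

    label: str
    n_cells: int
    base: CellParams = field(default_factory=CellParams)
    cv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VARIABLE_FIELDS))
    pump_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.pump_scale <= 0:
            raise ValidationError(f"pump_scale must be > 0, got {self.pump_scale}")
        valid = {f.name for f in fields(CellParams)}
        for name, c in self.cv.items():
            if name not in valid:
                raise ValidationError(f"unknown CellParams field in cv: {name!r}")
            if c < 0:
                raise ValidationError(f"cv[{name!r}] must be >= 0, got {c}")


@dataclass(frozen=True)
class CalciumTrace:
    """One cell's uniformly sampled [Ca2+]i time series bound to a protocol."""

    cell_id: str
    population: str
    t: np.ndarray
    ca_i: np.ndarray
    protocol: SolutionProtocol

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        ca = np.asarray(self.ca_i, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ca_i", ca)
        if t.ndim != 1 or t.size < 2 or ca.shape != t.shape:
            raise ValidationError("trace needs matching 1-d t and ca_i with >= 2 samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValidationError("trace times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("trace must be uniformly sampled")
        if not np.all(np.isfinite(ca)):
            raise ValidationError(f"trace {self.cell_id!r} contains non-finite [Ca2+]i")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def hill_activation(c, k_half: float, hill_h: float):
    """Hill drive C^h / (k^h + C^h) of the extrusion pump."""
    c = np.maximum(np.asarray(c, dtype=float), 0.0)
    ch = c ** hill_h
    return ch / (k_half ** hill_h + ch)


def steady_state_plateau(params: CellParams, ca_o_mm: float) -> float:
    """Analytic fixed point C* of influx/efflux balance during re-addition.

    Solves ``influx_gain*ca_o + leak = v_max * Hill(C*)`` for C*.  Raises
    :class:`ValidationError` when total influx exceeds pump capacity (no
    steady state exists; the trace rises for the whole segment).
    """
    j = params.influx_gain * ca_o_mm + params.leak
    if params.v_max <= j:
        raise ValidationError("influx exceeds v_max: no finite steady state")
    ratio = j / params.v_max
    return params.k_half * (ratio / (1.0 - ratio)) ** (1.0 / params.hill_h)


def _check_dt(protocol: SolutionProtocol, dt: float) -> None:
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    shortest = min(s.duration_s for s in protocol.segments)
    if dt > shortest / 2:
        raise ValidationError(
            f"dt={dt} too coarse: must be <= half the shortest segment ({shortest} s)"
        )


def _integrate(
    arrays: Mapping[str, np.ndarray],
    protocol: SolutionProtocol,
    dt: float,
    return_pump_state: bool = False,
):
    """Vectorised fixed-step integration of n cells over the protocol.

    ``arrays`` maps CellParams field names to shape-(n,) arrays.  Returns
    ``(t_out, C)`` with C of shape (n_samples, n); noise is *not* added here.
    """
    _check_dt(protocol, dt)
    t0, t1 = protocol.start_s, protocol.end_s
    t_out = t0 + np.arange(int(round((t1 - t0) / dt)) + 1) * dt
    n_sub = max(1, int(round(dt / _SUBSTEP_S)))
    h = dt / n_sub
    n_steps = (len(t_out) - 1) * n_sub
    tt = t0 + np.arange(n_steps) * h
    ca_o_tt = np.asarray(protocol.ca_o(np.minimum(tt, t1)), dtype=float)

    t_tg = protocol.tg_onset_s
    v_max = arrays["v_max"]
    k_half = arrays["k_half"]
    hill_h = arrays["hill_h"]
    gain = arrays["influx_gain"]
    amp = arrays["store_release_amp"]
    rel_tau = np.maximum(arrays["store_release_tau"], 1e-6)
    leak = arrays["leak"]
    pump_tau = arrays["pump_tau"]
    pump_tau_down = arrays["pump_tau_down"]

    def _hill(c):
        with np.errstate(over="ignore", invalid="ignore"):
            ch = np.maximum(c, 0.0) ** hill_h
            return ch / (k_half ** hill_h + ch)

    c = arrays["baseline_ca"].astype(float).copy()
    m = _hill(c)
    n = c.shape[0]
    out = np.empty((len(t_out), n))
    out[0] = c
    m_out = np.empty_like(out) if return_pump_state else None
    if return_pump_state:
        m_out[0] = m

    for k in range(n_steps):
        t = tt[k]
        if t_tg is not None and t >= t_tg:
            decay = np.exp(-(t - t_tg) / rel_tau)
            depletion = 1.0 - decay
            release = amp / rel_tau * decay
        else:
            depletion = 0.0
            release = 0.0
        influx = gain * ca_o_tt[k] * depletion + release + leak
        c = np.maximum(c + h * (influx - v_max * m), 0.0)
        drive = _hill(c)
        tau_m = np.where(drive > m, pump_tau, pump_tau_down)
        m = m + h * (drive - m) / tau_m
        if (k + 1) % n_sub == 0:
            out[(k + 1) // n_sub] = c
            if return_pump_state:
                m_out[(k + 1) // n_sub] = m

    if not np.all(np.isfinite(out)):
        bad = int(np.argwhere(~np.isfinite(out).all(axis=0))[0, 0])
        raise SimulationError(
            "integration produced non-finite [Ca2+]i for parameter set "
            + repr({k: float(v[bad]) for k, v in arrays.items()})
        )
    if return_pump_state:
        return t_out, out, m_out
    return t_out, out


def _params_to_arrays(params_list: Sequence[CellParams]) -> dict[str, np.ndarray]:
    names = [f.name for f in fields(CellParams) if f.name != "seed"]
    return {n: np.array([getattr(p, n) for p in params_list], dtype=float) for n in names}


def simulate_cell(
    params: CellParams,
    protocol: SolutionProtocol,
    dt: float = 2.0,
    cell_id: str = "cell_0000",
    population: str = "sim",
) -> CalciumTrace:
    """Simulate one cell over the full protocol.

    With ``noise_sd == 0`` the output is deterministic given ``params``;
    otherwise i.i.d. Gaussian measurement noise seeded by ``params.seed``
    is added to the emitted samples.
    """
    t_out, c = _integrate(_params_to_arrays([params]), protocol, dt)
    ca = c[:, 0]
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        ca = ca + rng.normal(0.0, params.noise_sd, size=ca.shape)
    return CalciumTrace(cell_id, population, t_out, ca, protocol)


def simulate_population(
    spec: PopulationSpec,
    protocol: SolutionProtocol,
    dt: float = 2.0,
    seed: int = 0,
) -> tuple[list[CalciumTrace], pd.DataFrame]:
    """Simulate a population with log-normal cell-to-cell variability.

    The master ``seed`` is expanded into one independent substream per cell
    (``numpy.random.SeedSequence.spawn``), from which that cell's parameter
    draws and its measurement noise are taken in a fixed order, so results
    are reproducible independent of iteration order.  Returns the traces and
    a ground-truth table (one row per cell, post ``pump_scale``).
    """
    children = np.random.SeedSequence(seed).spawn(spec.n_cells)
    cells: list[CellParams] = []
    noise: list[np.ndarray | None] = []
    t0, t1 = protocol.start_s, protocol.end_s
    n_samples = int(round((t1 - t0) / dt)) + 1
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        cv_map = dict(spec.cv)
        draws = {}
        for name in sorted(cv_map):  # fixed draw order keeps substreams stable
            cv = cv_map[name]
            median = getattr(spec.base, name)
            if cv > 0:
                sigma = np.sqrt(np.log1p(cv ** 2))
                draws[name] = median * np.exp(sigma * rng.standard_normal())
            else:
                draws[name] = median
        p = replace(spec.base, **draws)
        p = replace(p, v_max=p.v_max * spec.pump_scale, seed=i)
        cells.append(p)
        if p.noise_sd > 0:
            noise.append(rng.normal(0.0, p.noise_sd, size=n_samples))
        else:
            noise.append(None)

    t_out, c = _integrate(_params_to_arrays(cells), protocol, dt)
    traces = []
    rows = []
    for i, p in enumerate(cells):
        ca = c[:, i] if noise[i] is None else c[:, i] + noise[i]
        cid = f"{spec.label}_{i:04d}"
        traces.append(CalciumTrace(cid, spec.label, t_out, ca, protocol))
        row = {"cell_id": cid, "population": spec.label, "pump_scale": spec.pump_scale}
        row.update({f.name: getattr(p, f.name) for f in fields(CellParams)})
        rows.append(row)
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# long-format CSV I/O
# ---------------------------------------------------------------------------

def traces_to_frame(traces: Sequence[CalciumTrace]) -> pd.DataFrame:
    """Long-format table with columns cell_id, population, t_s, ca_nM."""
    return pd.concat(
        [
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "population": tr.population,
                    "t_s": tr.t,
                    "ca_nM": tr.ca_i,
                }
            )
            for tr in traces
        ],
        ignore_index=True,
    )


def frame_to_traces(df: pd.DataFrame, protocol: SolutionProtocol) -> list[CalciumTrace]:
    required = {"cell_id", "population", "t_s", "ca_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_s")
        traces.append(
            CalciumTrace(
                str(cid),
                str(grp["population"].iloc[0]),
                grp["t_s"].to_numpy(float),
                grp["ca_nM"].to_numpy(float),
                protocol,
            )
        )
    return traces


def write_traces(traces: Sequence[CalciumTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.10g")


def read_traces(path: str | Path, protocol: SolutionProtocol) -> list[CalciumTrace]:
    return frame_to_traces(pd.read_csv(path), protocol)
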