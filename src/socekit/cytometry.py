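"""Synthetic flow-cytometry events and quadrant gating of CD4+ compartments.

Compartments are assigned by two-marker threshold (rectangular) gating with
a strict "positive = intensity > threshold" convention::

    N    marker1+ CD45RO-      (naive)
    CM   marker1+ CD45RO+      (central memory)
    EM   marker1- CD45RO+      (effector memory)
    EMRA marker1- CD45RO-      (terminally differentiated effector memory)

where marker1 is CD62L or CCR7 depending on the scheme.  The synthetic
event generator draws a compartment per event (multinomial at target
frequencies) and then log-normal marker intensities from well-separated
negative/positive modes straddling the gate thresholds, emulating
post-compensation bimodal marker distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InsufficientDataError, ValidationError
from .stats import select_two_group_test

COMPARTMENTS = ("N", "CM", "EM", "EMRA")

#: compartment -> (marker1 positive?, CD45RO positive?)
COMPARTMENT_RULES: Mapping[str, tuple[bool, bool]] = {
    "N": (True, False),
    "CM": (True, True),
    "EM": (False, True),
    "EMRA": (False, False),
}

SCHEMES: Mapping[str, tuple[str, str]] = {
    "CD62LxCD45RO": ("CD62L", "CD45RO"),
    "CCR7xCD45RO": ("CCR7", "CD45RO"),
}


@dataclass(frozen=True)
class MarkerModel:
    """Log-normal negative/positive intensity modes of one marker (a.u.)."""

    neg_median: float = 100.0
    pos_median: float = 2000.0
    sigma: float = 0.5  # log-space sd shared by both modes

    def __post_init__(self) -> None:
        if self.neg_median <= 0 or self.pos_median <= 0 or self.sigma <= 0:
            raise ValidationError("marker model parameters must be > 0")

    def draw(self, rng: np.random.Generator, positive: np.ndarray) -> np.ndarray:
        med = np.where(positive, self.pos_median, self.neg_median)
        return med * np.exp(self.sigma * rng.standard_normal(len(positive)))


DEFAULT_THRESHOLD = 500.0


def default_gates(markers: Sequence[str]) -> dict[str, float]:
    """One threshold per marker, midway (geometrically) between the default
    negative and positive modes."""
    return {m: DEFAULT_THRESHOLD for m in markers}


def gates_to_yaml(gates: Mapping[str, float], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({k: float(v) for k, v in gates.items()}))


def gates_from_yaml(path: str | Path) -> dict[str, float]:
    return {str(k): float(v) for k, v in yaml.safe_load(Path(path).read_text()).items()}


def generate_synthetic_events(
    freqs: Mapping[str, float],
    n_events: int,
    seed: int,
    marker_models: Mapping[str, MarkerModel] | None = None,
    scheme: str = "CD62LxCD45RO",
    condition: str = "ctrl",
    positive_fractions: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a seeded event table at target compartment frequencies.

    ``freqs`` maps the four compartments to target percentages (must sum to
    100 +/- 0.01).  ``positive_fractions`` optionally adds further markers
    (e.g. activation markers CD69/CD154) with the given percent of positive
    events, independent of compartment.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    if n_events < 1:
        raise ValidationError(f"n_events must be >= 1, got {n_events}")
    missing = set(COMPARTMENTS) - set(freqs)
    if missing:
        raise ValidationError(f"freqs missing compartments: {sorted(missing)}")
    total = float(sum(freqs[c] for c in COMPARTMENTS))
    if abs(total - 100.0) > 0.01:
        raise ValidationError(f"freqs must sum to 100 +/- 0.01, got {total}")

    m1, m2 = SCHEMES[scheme]
    models = dict(marker_models or {})
    for m in (m1, m2):
        models.setdefault(m, MarkerModel())

    rng = np.random.default_rng(seed)
    probs = np.array([freqs[c] for c in COMPARTMENTS], dtype=float) / total
    counts = rng.multinomial(n_events, probs)
    compartment = np.repeat(COMPARTMENTS, counts)
    rng.shuffle(compartment)

    pos1 = np.array([COMPARTMENT_RULES[c][0] for c in compartment])
    pos2 = np.array([COMPARTMENT_RULES[c][1] for c in compartment])
    df = pd.DataFrame(
        {
            "event_id": [f"{condition}_{i:06d}" for i in range(n_events)],
            "condition": condition,
            m1: models[m1].draw(rng, pos1),
            m2: models[m2].draw(rng, pos2),
        }
    )
    for marker, pct in (positive_fractions or {}).items():
        if not (0.0 <= pct <= 100.0):
            raise ValidationError(f"positive fraction for {marker!r} outside [0, 100]")
        model = models.get(marker, MarkerModel())
        pos = rng.random(n_events) < pct / 100.0
        df[marker] = model.draw(rng, pos)
    return df


def quadrant_gate(
    events: pd.DataFrame,
    gates: Mapping[str, float],
    scheme: str = "CD62LxCD45RO",
) -> pd.DataFrame:
    """Assign every event to exactly one compartment by its sign pattern."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    m1, m2 = SCHEMES[scheme]
    for m in (m1, m2):
        if m not in events.columns:
            raise ValidationError(f"events lack required marker column {m!r}")
        if m not in gates:
            raise ValidationError(f"gates lack threshold for marker {m!r}")
        bad = ~np.isfinite(events[m].to_numpy(float))
        if bad.any():
            ev = events.loc[bad].iloc[0]
            raise ValidationError(
                f"event {ev.get('event_id', bad.argmax())!r} has non-finite {m!r}"
            )
    pos1 = events[m1].to_numpy(float) > gates[m1]
    pos2 = events[m2].to_numpy(float) > gates[m2]
    label = np.where(
        pos1,
        np.where(pos2, "CM", "N"),
        np.where(pos2, "EM", "EMRA"),
    )
    out = events.copy()
    out["compartment"] = label
    return out


def compartment_frequencies(
    labeled: pd.DataFrame, by: str = "condition"
) -> pd.DataFrame:
    """Percent of events per compartment within each condition (sums to 100)."""
    if "compartment" not in labeled.columns:
        raise ValidationError("events are not gated (no 'compartment' column)")
    if labeled.empty:
        raise ValidationError("no labeled events")
    rows = []
    for cond, grp in labeled.groupby(by, sort=False):
        n = len(grp)
        counts = grp["compartment"].value_counts()
        for comp in COMPARTMENTS:
            k = int(counts.get(comp, 0))
            rows.append(
                {by: cond, "compartment": comp, "n_events": k, "pct": 100.0 * k / n}
            )
    return pd.DataFrame(rows)


def marker_positive_fraction(
    events: pd.DataFrame,
    marker: str,
    threshold: float,
    by: str = "condition",
) -> pd.DataFrame:
    """Percent of events with ``marker`` intensity strictly above threshold."""
    if marker not in events.columns:
        raise ValidationError(f"events lack marker column {marker!r}")
    rows = []
    for cond, grp in events.groupby(by, sort=False):
        vals = grp[marker].to_numpy(float)
        rows.append(
            {
                by: cond,
                "marker": marker,
                "n_events": len(grp),
                "pct_positive": 100.0 * float((vals > threshold).mean()),
            }
        )
    return pd.DataFrame(rows)


def compare_conditions(
    freq_a: pd.DataFrame,
    freq_b: pd.DataFrame,
    labels: tuple[str, str] = ("a", "b"),
    alpha_norm: float = 0.05,
) -> pd.DataFrame:
    """Per-compartment two-group test on replicate-level frequencies.

    Inputs are wide tables with one row per independent experiment and one
    column per compartment; each needs >= 3 replicates.
    """
    for name, df in zip(labels, (freq_a, freq_b)):
        missing = set(COMPARTMENTS) - set(df.columns)
        if missing:
            raise ValidationError(f"{name!r} table missing compartments {sorted(missing)}")
        if len(df) < 3:
            raise InsufficientDataError(
                f"condition {name!r} has {len(df)} replicates; >= 3 required"
            )
    rows = []
    for comp in COMPARTMENTS:
        res = select_two_group_test(
            freq_a[comp].to_numpy(float),
            freq_b[comp].to_numpy(float),
            alpha_norm=alpha_norm,
        )
        rows.append(
            {
                "compartment": comp,
                f"mean_{labels[0]}": freq_a[comp].mean(),
                f"mean_{labels[1]}": freq_b[comp].mean(),
                "test_name": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(rows)


class QuadrantGate(BaseEstimator, TransformerMixin):
    """sklearn-style transformer assigning compartments to event tables."""

    def __init__(self, gates: Mapping[str, float] | None = None, scheme: str = "CD62LxCD45RO"):
        self.gates = gates
        self.scheme = scheme

    def fit(self, X: pd.DataFrame, y=None):
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        markers = SCHEMES[self.scheme]
        self.gates_ = dict(self.gates) if self.gates else default_gates(markers)
        self.markers_ = markers
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "gates_"):
            self.fit(X)
        return quadrant_gate(X, self.gates_, self.scheme)
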