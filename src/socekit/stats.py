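"""Statistical decision scheme and small-assay quantifications.

Two-group comparisons follow the common imaging-lab scheme: test each group
for normality (Shapiro-Wilk); use an unpaired two-tailed Student t-test
when both groups look normal and are large enough to trust the normality
test (n >= 8 each), otherwise a two-tailed Mann-Whitney U test.  Multi-group
comparisons use classical one-way ANOVA when all groups are normal with
equal variances (Levene gate), otherwise Kruskal-Wallis with the
tie-corrected H statistic.  Significance stars map strict thresholds:
``* p < 0.05, ** p < 0.01, *** p < 0.001``.

The module also implements 2^-ddCq relative qPCR quantification and
dual-luciferase (firefly/renilla) normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    stars: str
    note: str = ""


def p_to_stars(p: float) -> str:
    """Map a p-value to significance stars with strict inequalities."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value must lie in [0, 1], got {p}")
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"sample {name!r} contains non-finite values")
    return arr


def select_two_group_test(
    a, b, alpha_norm: float = 0.05, min_n_normal: int = 8
) -> StatResult:
    """Two-group decision scheme: Shapiro-Wilk gate, then t-test or
    Mann-Whitney U (both two-tailed).

    The t-test branch additionally requires n >= ``min_n_normal`` in each
    group: with fewer observations the normality test is uninformative and
    the nonparametric branch is forced.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"need n >= 3 per group, got {len(a)} and {len(b)}"
        )
    normal = False
    if len(a) >= min_n_normal and len(b) >= min_n_normal:
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            normal = (
                sps.shapiro(a).pvalue >= alpha_norm
                and sps.shapiro(b).pvalue >= alpha_norm
            )
    if normal:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "student-t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    p = float(res.pvalue)
    return StatResult(name, float(res.statistic), p, (len(a), len(b)), p_to_stars(p))


def kruskal_wallis(
    groups,
    method: str = "asymptotic",
    n_resamples: int = 10000,
    seed: int | None = None,
) -> StatResult:
    """Kruskal-Wallis one-way ANOVA on ranks (tie-corrected H).

    ``method="asymptotic"`` takes p from the chi-square approximation with
    k-1 df; ``method="permutation"`` estimates p by Monte-Carlo label
    permutation of the same H statistic (recommended when all groups are
    tiny).  Totally tied data (every value identical) makes H undefined and
    is flagged degenerate rather than raising.
    """
    samples = [_as_sample(g, f"group{i}") for i, g in enumerate(groups)]
    if len(samples) < 3:
        raise InsufficientDataError(
            "Kruskal-Wallis needs >= 3 groups; use select_two_group_test for two"
        )
    ns = tuple(len(g) for g in samples)
    if any(n < 2 for n in ns):
        raise InsufficientDataError(f"each group needs n >= 2, got {ns}")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return StatResult(
            "kruskal-wallis", float("nan"), float("nan"), ns, "",
            note="degenerate: all values identical",
        )
    h, p_asym = sps.kruskal(*samples)
    if method == "asymptotic":
        p = float(p_asym)
        note = ""
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        splits = np.cumsum(ns)[:-1]
        count = 0
        for _ in range(n_resamples):
            perm = rng.permutation(pooled)
            h_perm, _ = sps.kruskal(*np.split(perm, splits))
            if h_perm >= h - 1e-12:
                count += 1
        p = (count + 1) / (n_resamples + 1)
        note = f"permutation p, {n_resamples} resamples"
    else:
        raise ValidationError(f"unknown method {method!r}")
    return StatResult("kruskal-wallis", float(h), float(p), ns, p_to_stars(p), note)


def compare_groups(groups, alpha_norm: float = 0.05) -> StatResult:
    """Multi-group scheme: classical ANOVA when every group is normal
    (Shapiro-Wilk) with equal variances (Levene), else Kruskal-Wallis."""
    samples = [_as_sample(g, f"group{i}") for i, g in enumerate(groups)]
    if len(samples) < 3:
        raise InsufficientDataError(
            "compare_groups needs >= 3 groups; use select_two_group_test for two"
        )
    ns = tuple(len(g) for g in samples)
    normal = all(
        len(g) >= 3 and np.ptp(g) > 0 and sps.shapiro(g).pvalue >= alpha_norm
        for g in samples
    )
    if normal and sps.levene(*samples).pvalue >= alpha_norm:
        res = sps.f_oneway(*samples)
        p = float(res.pvalue)
        return StatResult("anova", float(res.statistic), p, ns, p_to_stars(p))
    return kruskal_wallis(samples)


def dunn_posthoc(groups, labels=None) -> pd.DataFrame:
    """Pairwise Dunn tests with Holm adjustment (optional follow-up to a
    significant Kruskal-Wallis omnibus)."""
    samples = [_as_sample(g, f"group{i}") for i, g in enumerate(groups)]
    k = len(samples)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    idx = np.cumsum([0] + [len(g) for g in samples])
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(k)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(samples[i]), len(samples[j])
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"a": labels[i], "b": labels[j], "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(df["p_raw"].to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * df["p_raw"].iloc[i])
        adj[i] = min(1.0, running)
    df["p_holm"] = adj
    df["stars"] = [p_to_stars(p) for p in df["p_holm"]]
    return df


# ---------------------------------------------------------------------------
# qPCR 2^-ddCq
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: gene-of-interest and reference-gene Cq values."""

    sample: str
    gene: str
    reference_gene: str
    cq_gene: float
    cq_ref: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.cq_gene, self.cq_ref]).all():
            raise ValidationError("Cq values must be finite")


def relative_expression(record: QpcrRecord) -> float:
    """2^-dCq of one record (expression relative to the reference gene)."""
    return float(2.0 ** -(record.cq_gene - record.cq_ref))


def ddcq_fold_change(target: QpcrRecord, control: QpcrRecord) -> float:
    """Fold change of target vs control by the 2^-ddCq method."""
    if target.gene != control.gene or target.reference_gene != control.reference_gene:
        raise ValidationError(
            "target and control must share gene and reference_gene "
            f"({target.gene}/{target.reference_gene} vs "
            f"{control.gene}/{control.reference_gene})"
        )
    dcq_target = target.cq_gene - target.cq_ref
    dcq_control = control.cq_gene - control.cq_ref
    return float(2.0 ** -(dcq_target - dcq_control))


# ---------------------------------------------------------------------------
# dual-luciferase normalisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LuciferaseRecord:
    """One well: firefly (reporter) and renilla (transfection control)."""

    condition: str
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.firefly, self.renilla]).all():
            raise ValidationError("luminescence values must be finite")
        if self.renilla <= 0:
            raise ValidationError(f"renilla must be > 0, got {self.renilla}")


def luciferase_relative_activity(
    records, control_condition: str
) -> pd.DataFrame:
    """Firefly/renilla ratios normalised to the control-condition mean.

    Normalisation order is fixed: per-well ratio, then division of every
    ratio by the mean control ratio, then per-condition mean +/- SEM over
    the normalised replicate ratios.
    """
    recs = list(records)
    if not recs:
        raise ValidationError("no luciferase records provided")
    df = pd.DataFrame(
        {
            "condition": [r.condition for r in recs],
            "ratio": [r.firefly / r.renilla for r in recs],
        }
    )
    if control_condition not in set(df["condition"]):
        raise ValidationError(f"control condition {control_condition!r} not present")
    ctrl_mean = df.loc[df["condition"] == control_condition, "ratio"].mean()
    df["relative"] = df["ratio"] / ctrl_mean
    out = (
        df.groupby("condition", sort=False)["relative"]
        .agg(n="count", relative_mean="mean", relative_sem="sem")
        .reset_index()
    )
    return out
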