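"""Frequency-weighted, severity-scaled condition scoring.

Each surviving individual is scored at the repeat survey on four ordinal
condition metrics: growth (the only positive change; 0-4), tissue loss (0-4),
biofouling (0-4) and vertical orientation change (0-2). Raw ordinal scores
are not directly comparable across metrics — three of the four measure
negative change, and rates of decline far exceed rates of growth in
slow-growing deep-sea taxa — so each metric is rescaled in two steps:

1. **Frequency weighting.** Within a metric, the weight of score ``s`` is the
   cumulative occurrence proportion ``w(s) = (n_1 + ... + n_s) / n_total``
   over the assessed cohort, where ``n_k`` counts individuals with initial
   score ``k`` and ``n_total`` counts the metric's nonzero scorers. Rare,
   extreme scores are thereby down-weighted relative to their ordinal rank
   only when intermediate levels are rare too; the maximum observed level
   always carries weight 1.
2. **Severity scaling.** The weight is multiplied by ``s / s_max`` so that a
   higher raw score can never end up below a lower one within the same
   metric.

Negative metrics are sign-flipped, components are summed across the four
metrics, and the total is clamped to [-1, 1] to give the overall condition
score; baseline (T0) individuals are identically 0 by definition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import METRIC_COLUMNS, METRIC_MAX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricSpec:
    """Name, maximum ordinal score, and sign (+1 positive change, -1 negative)."""

    name: str
    s_max: int
    sign: int


#: The four condition metrics. Growth is the only positive change.
METRICS: dict[str, MetricSpec] = {
    "growth": MetricSpec("growth", 4, +1),
    "tissue_loss": MetricSpec("tissue_loss", 4, -1),
    "biofouling": MetricSpec("biofouling", 4, -1),
    "orientation": MetricSpec("orientation", 2, -1),
}


@dataclass
class WeightTable:
    """Cumulative-frequency weights for one metric over one cohort."""

    metric: MetricSpec
    counts: dict[int, int]
    n_total: int
    weights: dict[int, float]

    def weight(self, s: int) -> float:
        if s not in self.weights:
            raise ValueError(
                f"score {s} outside the weight domain 0-{self.metric.s_max} "
                f"for metric {self.metric.name}"
            )
        return self.weights[s]


@dataclass
class ConditionScore:
    """Signed overall condition of one individual, with per-metric components."""

    individual_id: str
    components: dict[str, float]
    value: float
    clamped: bool


def tabulate_metric_counts(
    table: pd.DataFrame, metric: MetricSpec | str, denominator: str = "per_metric"
) -> tuple[dict[int, int], int]:
    """Tally nonzero scores of one metric over a repeat-survey cohort.

    Returns ``(counts, n_total)`` where ``counts[s]`` is the number of
    individuals with initial score ``s >= 1`` and ``n_total`` is the weight
    denominator: with ``denominator='per_metric'`` (default) the number of
    individuals with a nonzero score on *this* metric — the choice under which
    the maximum observed level has cumulative weight exactly 1 — and with
    ``denominator='global'`` the number of individuals with a change on *any*
    metric.
    """
    spec = METRICS[metric] if isinstance(metric, str) else metric
    if len(table) == 0:
        raise ValueError("empty cohort: no individuals to tabulate")
    scores = table[spec.name].to_numpy()
    nonzero = scores[scores > 0]
    counts = {int(s): int(n) for s, n in zip(*np.unique(nonzero, return_counts=True))}
    if denominator == "per_metric":
        n_total = int(len(nonzero))
    elif denominator == "global":
        any_change = table[list(METRIC_COLUMNS)].to_numpy().sum(axis=1) > 0
        n_total = int(any_change.sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if n_total == 0:
        raise ValueError(
            f"no condition changes to weight for metric {spec.name} (all scores zero)"
        )
    return counts, n_total


def frequency_weights(
    counts: Mapping[int, int], n_total: int, metric: MetricSpec | str = "growth"
) -> WeightTable:
    """Build the cumulative-occurrence weight table for one metric.

    ``w(0) = 0`` and ``w(s) = (sum of counts at 1..s) / n_total``; scores with
    no occurrences inherit the cumulative value carried forward, so weights
    are non-decreasing and the maximum observed score reaches the top of the
    cumulative ladder.
    """
    spec = METRICS[metric] if isinstance(metric, str) else metric
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    bad = [s for s in counts if not 1 <= s <= spec.s_max]
    if bad:
        raise ValueError(f"count keys {bad} outside 1-{spec.s_max} for {spec.name}")
    weights = {0: 0.0}
    cum = 0
    for s in range(1, spec.s_max + 1):
        cum += counts.get(s, 0)
        weights[s] = cum / n_total
    return WeightTable(metric=spec, counts=dict(counts), n_total=int(n_total),
                       weights=weights)


def severity_scaled_score(w: float, s: int, s_max: int) -> float:
    """Severity-scale a frequency weight: ``w * s / s_max``.

    Preserves ordinal severity ranking within a metric — a higher raw score
    never scores below a lower one carrying the same or smaller weight.
    """
    if not 0 <= w <= 1:
        raise ValueError(f"weight {w} outside [0, 1]")
    if s < 0 or s > s_max:
        raise ValueError(f"score {s} outside 0-{s_max}")
    return w * s / s_max


def individual_condition(
    metrics: Mapping[str, int],
    weight_tables: Mapping[str, WeightTable],
    individual_id: str = "",
) -> ConditionScore:
    """Overall condition of one individual: signed component sum, clamped to [-1, 1].

    Components are recorded pre-clamp. The weight tables must come from the
    same cohort the individual belongs to.
    """
    components: dict[str, float] = {}
    total = 0.0
    for name, spec in METRICS.items():
        s = int(metrics.get(name, 0))
        wt = weight_tables[name]
        comp = spec.sign * severity_scaled_score(wt.weight(s), s, spec.s_max)
        components[name] = comp
        total += comp
    clamped = total < -1.0 or total > 1.0
    value = min(1.0, max(-1.0, total))
    return ConditionScore(individual_id=individual_id, components=components,
                          value=value, clamped=clamped)


def build_weight_tables(
    table: pd.DataFrame, pooling: str = "global", denominator: str = "per_metric"
) -> dict:
    """Weight tables for every metric, pooled globally or per site.

    With ``pooling='global'`` returns ``{metric: WeightTable}`` over the whole
    cohort; with ``pooling='per_site'`` returns ``{site_id: {metric: WeightTable}}``.
    Metrics with no nonzero scores in a cohort get a degenerate all-zero
    weight table (every individual scores 0 on them, contributing nothing).
    """
    def _tables(cohort: pd.DataFrame) -> dict[str, WeightTable]:
        out = {}
        for name, spec in METRICS.items():
            try:
                counts, n_total = tabulate_metric_counts(cohort, spec, denominator)
            except ValueError:
                # No change recorded on this metric: weight table is all-zero,
                # which only ever multiplies score 0.
                out[name] = WeightTable(spec, {}, 0,
                                        {s: 0.0 for s in range(spec.s_max + 1)})
                continue
            out[name] = frequency_weights(counts, n_total, spec)
        return out

    if pooling == "global":
        return _tables(table)
    if pooling == "per_site":
        return {sid: _tables(g) for sid, g in table.groupby("site_id")}
    raise ValueError(f"unknown pooling mode {pooling!r}")


def score_table(
    table: pd.DataFrame, pooling: str = "global", denominator: str = "per_metric"
) -> pd.DataFrame:
    """Score every individual in a repeat-survey cohort.

    Returns a per-individual frame with identity columns, one signed
    component column per metric, the clamped overall ``condition`` and a
    ``clamped`` flag.
    """
    tables = build_weight_tables(table, pooling=pooling, denominator=denominator)
    rows = []
    for _, rec in table.iterrows():
        wt = tables[rec["site_id"]] if pooling == "per_site" else tables
        cs = individual_condition(
            {m: rec[m] for m in METRIC_COLUMNS}, wt, individual_id=rec["individual_id"]
        )
        row = {
            "individual_id": rec["individual_id"],
            "site_id": rec["site_id"],
            "phylum": rec["phylum"],
            "otu": rec["otu"],
        }
        row.update({f"component_{m}": cs.components[m] for m in METRIC_COLUMNS})
        row["condition"] = cs.value
        row["clamped"] = cs.clamped
        rows.append(row)
    return pd.DataFrame(rows)


def factor_condition_summary(
    scores: pd.DataFrame,
    by: str,
    value_col: str = "condition",
    include_zero_change: bool = True,
) -> pd.DataFrame:
    """Per-level mean +/- SE of individual condition within a factor.

    Individuals are pooled directly within each level (never first aggregated
    by OTU). ``include_zero_change=False`` restricts to individuals whose
    condition changed, matching summaries counted over changed individuals
    only. Levels with no individuals are omitted with a log note; the SE of a
    single observation is reported as NaN.
    """
    df = scores
    if not include_zero_change:
        df = df[df[value_col] != 0]
    rows = []
    for level, g in df.groupby(by, sort=True):
        vals = g[value_col].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({by: level, "mean": mean, "se": se, "n": n})
    observed = {r[by] for r in rows}
    for level in set(scores[by].unique()) - observed:
        logger.info("factor level %r has no scored individuals; omitted", level)
    return pd.DataFrame(rows, columns=[by, "mean", "se", "n"])
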