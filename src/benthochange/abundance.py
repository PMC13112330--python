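"""Fate accounting and per-OTU percent abundance change between surveys.

Given fate-resolved matchings (survived / lost / recruit) and the annotation
tables they reference, this module tallies counts per factor level (site,
phylum, oxygen zone, seamount) and computes the per-OTU percent change in
abundance, ``delta = 100 * (A1 - A0) / A0``, where A0 and A1 are the OTU's
counts within the level at the baseline and repeat surveys. Counts are pooled
across a level's member sites before the ratio is taken (never averaged over
per-site ratios). OTUs absent at baseline within a level (pure recruitment)
leave the ratio undefined; they are excluded from delta summaries, flagged,
and still appear in the fate tallies.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .annotations import MatchSet

logger = logging.getLogger(__name__)


def delta_abundance(a0: int, a1: int) -> float:
    """Percent abundance change ``100 * (a1 - a0) / a0``; NaN (undefined) if a0 = 0."""
    if a0 < 0 or a1 < 0:
        raise ValueError("abundances must be non-negative counts")
    if a0 == 0:
        return float("nan")
    return 100.0 * (a1 - a0) / a0


def fate_table(
    matchsets: Iterable[MatchSet],
    annotations: pd.DataFrame,
    extra_factors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per individual-fate, joined with identity and factor columns.

    ``annotations`` must contain every id referenced by the matchsets (both
    timepoints). ``extra_factors`` optionally maps ``site_id`` to additional
    factor columns (e.g. oxygen zone, seamount) that are merged in.
    """
    keyed = annotations.set_index(["site_id", "timepoint", "individual_id"])
    rows = []
    for ms in matchsets:
        for _, p in ms.pairs.iterrows():
            ref_tp, ref_id = ("T0", p["t0_id"]) if p["t0_id"] is not None else ("T1", p["t1_id"])
            key = (ms.site_id, ref_tp, ref_id)
            if key not in keyed.index:
                raise KeyError(f"individual {ref_id!r} ({ref_tp}, site {ms.site_id}) "
                               "referenced by a matchset but missing from annotations")
            rec = keyed.loc[key]
            rows.append({
                "site_id": ms.site_id,
                "phylum": rec["phylum"],
                "otu": p["otu"],
                "fate": p["fate"],
                "t0_id": p["t0_id"],
                "t1_id": p["t1_id"],
            })
    df = pd.DataFrame(rows, columns=["site_id", "phylum", "otu", "fate", "t0_id", "t1_id"])
    if extra_factors is not None:
        df = df.merge(extra_factors, on="site_id", how="left")
    return df


def fate_tally(fates: pd.DataFrame, by: str = "site_id") -> pd.DataFrame:
    """Per-level totals: n_t0, n_t1, survivors, lost, recruits, net change.

    Satisfies ``n_t0 = survivors + lost`` and ``n_t1 = survivors + recruits``
    for every level of any disjoint factor.
    """
    rows = []
    for level, g in fates.groupby(by, sort=True):
        survivors = int((g["fate"] == "survived").sum())
        lost = int((g["fate"] == "lost").sum())
        recruits = int((g["fate"] == "recruit").sum())
        rows.append({
            by: level,
            "n_t0": survivors + lost,
            "n_t1": survivors + recruits,
            "survivors": survivors,
            "lost": lost,
            "recruits": recruits,
            "net_change": recruits - lost,
        })
    return pd.DataFrame(
        rows, columns=[by, "n_t0", "n_t1", "survivors", "lost", "recruits", "net_change"]
    )


def tally_from_counts(n_t0: int, lost: int, recruits: int, level: str = "") -> dict:
    """Fate tally from printed aggregate counts (baseline count, losses, recruits)."""
    if min(n_t0, lost, recruits) < 0 or lost > n_t0:
        raise ValueError("counts must be non-negative with lost <= n_t0")
    survivors = n_t0 - lost
    return {
        "level": level,
        "n_t0": n_t0,
        "n_t1": survivors + recruits,
        "survivors": survivors,
        "lost": lost,
        "recruits": recruits,
        "net_change": recruits - lost,
    }


def per_otu_delta(fates: pd.DataFrame, by: str = "site_id") -> pd.DataFrame:
    """Per-OTU percent abundance change within each level of a factor.

    Counts A0 (= survivors + lost) and A1 (= survivors + recruits) are pooled
    over the level's member sites per OTU before the ratio. OTUs with A0 = 0
    at a level carry ``delta_pct = NaN`` and ``defined = False``; they are
    logged and excluded from downstream delta summaries.
    """
    rows = []
    for (level, otu), g in fates.groupby([by, "otu"], sort=True):
        survivors = int((g["fate"] == "survived").sum())
        a0 = survivors + int((g["fate"] == "lost").sum())
        a1 = survivors + int((g["fate"] == "recruit").sum())
        d = delta_abundance(a0, a1)
        if a0 == 0:
            logger.info("OTU %r at level %r has no baseline individuals; "
                        "delta undefined (recruit-only)", otu, level)
        rows.append({by: level, "otu": otu, "a0": a0, "a1": a1,
                     "delta_pct": d, "defined": a0 > 0})
    return pd.DataFrame(rows, columns=[by, "otu", "a0", "a1", "delta_pct", "defined"])


def delta_summary(deltas: pd.DataFrame, by: str) -> pd.DataFrame:
    """Mean +/- SE of defined per-OTU delta values within each factor level."""
    rows = []
    for level, g in deltas.groupby(by, sort=True):
        vals = g.loc[g["defined"], "delta_pct"].to_numpy(dtype=float)
        if len(vals) == 0:
            logger.info("level %r has no defined per-OTU deltas; omitted", level)
            continue
        n = len(vals)
        mean = float(vals.mean())
        se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({by: level, "mean_delta_pct": mean, "se": se, "n_otus": n})
    return pd.DataFrame(rows, columns=[by, "mean_delta_pct", "se", "n_otus"])
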