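"""Site-level dissolved-oxygen means and oxygen-minimum-zone classification.

Each monitoring site carries a dissolved-oxygen sensor series (mL/L) recorded
during the survey dive. The site is summarised by the arithmetic mean
concentration over a time window and classified into one of three
concentration zones commonly used to stratify the Northeast Pacific oxygen
minimum zone: above 1 mL/L, between 0.5 and 1 mL/L, and below 0.5 mL/L.
Because absolute readings from different instruments are not directly
comparable between surveys, only zone membership — never the raw
concentration difference — is compared across timepoints.
"""

from __future__ import annotations

import enum
import math

import pandas as pd


class OxygenZone(enum.Enum):
    """Oxygen-minimum-zone concentration stratum of a site."""

    LOW = "LOW"    # [O2] < 0.5 mL/L (near-anoxic OMZ core)
    MID = "MID"    # 0.5 <= [O2] < 1 mL/L
    HIGH = "HIGH"  # [O2] >= 1 mL/L


def read_oxygen_series(path) -> pd.DataFrame:
    """Read a sensor CSV with columns site_id, timepoint, timestamp, o2_ml_per_l."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"site_id", "timepoint", "timestamp", "o2_ml_per_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"oxygen series missing column(s): {sorted(missing)}")
    if (df["o2_ml_per_l"] < 0).any():
        raise ValueError("negative dissolved-oxygen concentration in series")
    return df


def mean_site_oxygen(series: pd.DataFrame, window=None) -> float:
    """Arithmetic mean concentration over a closed time window.

    Parameters
    ----------
    series :
        DataFrame with ``timestamp`` and ``o2_ml_per_l`` columns.
    window :
        Optional (start, end) pair; samples with start <= t <= end are
        averaged. ``None`` averages the whole series (the full survey
        duration).

    Raises
    ------
    ValueError
        If no sample falls inside the window — an empty window is "no data",
        not a zero concentration.
    """
    conc = series["o2_ml_per_l"]
    if window is not None:
        start, end = window
        inside = (series["timestamp"] >= start) & (series["timestamp"] <= end)
        conc = conc[inside]
    if len(conc) == 0:
        raise ValueError("no oxygen samples inside the averaging window (no data)")
    return float(conc.mean())


def classify_zone(mean_conc: float) -> OxygenZone:
    """Classify a site mean concentration (mL/L) into its OMZ zone.

    Boundaries are assigned upward (0.5 -> MID, 1.0 -> HIGH) so the partition
    of [0, inf) is total; no observed site mean falls on a boundary.
    """
    if not math.isfinite(mean_conc) or mean_conc < 0:
        raise ValueError(f"mean concentration must be finite and >= 0, got {mean_conc!r}")
    if mean_conc < 0.5:
        return OxygenZone.LOW
    if mean_conc < 1.0:
        return OxygenZone.MID
    return OxygenZone.HIGH


def zone_stability(mean_t0: float, mean_t1: float) -> bool:
    """True iff the site occupies the same OMZ zone at both surveys."""
    return classify_zone(mean_t0) is classify_zone(mean_t1)
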