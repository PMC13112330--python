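"""Configuration-driven end-to-end analysis runner.

Executes the full change-detection flow on either real input files or a
simulated study: read and validate annotations -> clip baselines to the
repeat-survey overlap -> match individuals -> classify oxygen zones ->
frequency-weight and score condition -> per-OTU abundance change -> the
nonparametric test battery (paired one-sided Wilcoxon tests with Bonferroni
correction for the two headline families; Kruskal-Wallis across sites, zones
and seamounts with Dunn's post hoc on significance; rank-sum tests between
phyla). All tables plus a machine-readable summary with a config hash, seed
and library versions are written to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import delta_summary, fate_table, fate_tally, per_otu_delta
from .annotations import (
    DEFAULT_TOLERANCE_M,
    clip_to_overlap,
    match_individuals,
    read_annotations,
    read_overlap_regions,
)
from .condition import factor_condition_summary, score_table
from .oxygen import classify_zone, mean_site_oxygen, read_oxygen_series, zone_stability
from .simulate import generate_study, seamount_study_config, write_bundle
from .stats import TestResult, adjust_pvalues, dunn_posthoc, kruskal_wallis, rank_sum_test, signed_rank_test

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run configuration; every module-level default surfaces as a named key."""

    # inputs: either file paths ...
    annotations_t0: str | None = None
    annotations_t1: str | None = None
    sites: str | None = None
    oxygen: str | None = None
    polygons: str | None = None
    # ... or a packaged simulation
    simulate: bool = False
    seed: int = 0
    # analysis knobs
    tolerance_m: float = DEFAULT_TOLERANCE_M
    weight_pooling: str = "global"          # or "per_site"
    weight_denominator: str = "per_metric"  # or "global"
    clamp_condition: bool = True
    test_pairing: str = "per_otu"           # or "per_site_otu"
    adjustment: str = "holm"                # Dunn post hoc adjustment
    alpha: float = 0.05
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"stage config: unknown key(s) {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise PipelineError("stage config: alpha must lie in (0, 1)")
        if not self.simulate:
            for key in ("annotations_t0", "annotations_t1"):
                path = getattr(self, key)
                if path is None:
                    raise PipelineError(f"stage config: missing input {key!r}")
                if not Path(path).exists():
                    raise PipelineError(f"stage config: input file not found: {path}")


@dataclass
class ReportBundle:
    """Every table the run produced, plus the headline summary and run log."""

    sites: pd.DataFrame
    zones: pd.DataFrame
    fates: pd.DataFrame
    fate_tallies: dict[str, pd.DataFrame]
    otu_deltas: dict[str, pd.DataFrame]
    delta_summaries: dict[str, pd.DataFrame]
    condition_scores: pd.DataFrame
    condition_summaries: dict[str, pd.DataFrame]
    statistics: pd.DataFrame
    dunn_tables: dict[str, pd.DataFrame]
    headline: dict
    log: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


@_stage("zones")
def _zone_table(sites: pd.DataFrame, oxygen: pd.DataFrame | None) -> pd.DataFrame:
    rows = []
    for _, rec in sites.iterrows():
        sid = rec["site_id"]
        means = {}
        for tp, col in (("T0", "o2_t0_ml_per_l"), ("T1", "o2_t1_ml_per_l")):
            if oxygen is not None:
                sel = oxygen[(oxygen["site_id"] == sid) & (oxygen["timepoint"] == tp)]
                means[tp] = mean_site_oxygen(sel) if len(sel) else None
            else:
                v = rec.get(col)
                means[tp] = None if pd.isna(v) else float(v)
        zone_t0 = classify_zone(means["T0"]).value if means["T0"] is not None else None
        zone_t1 = classify_zone(means["T1"]).value if means["T1"] is not None else None
        stable = (
            zone_stability(means["T0"], means["T1"])
            if means["T0"] is not None and means["T1"] is not None
            else None
        )
        rows.append({"site_id": sid, "seamount": rec["seamount"],
                     "o2_mean_t0": means["T0"], "o2_mean_t1": means["T1"],
                     "zone_t0": zone_t0, "zone_t1": zone_t1, "zone_stable": stable})
    return pd.DataFrame(rows)


def _paired_tests(fates, cond_scores, pairing, alpha) -> list[TestResult]:
    """The two headline paired tests (abundance, condition), Bonferroni m = 2."""
    keys = ["otu"] if pairing == "per_otu" else ["site_id", "otu"]
    counts = fates.groupby(keys)["fate"].agg(
        a0=lambda f: ((f == "survived") | (f == "lost")).sum(),
        a1=lambda f: ((f == "survived") | (f == "recruit")).sum(),
    ).reset_index()
    results = []
    # abundance: T0 count minus T1 count per pairing unit, "greater" = decline
    d_abund = (counts["a0"] - counts["a1"]).to_numpy(dtype=float)
    try:
        res_a = signed_rank_test(d_abund, alternative="greater")
    except ValueError as exc:
        logger.info("paired abundance test skipped: %s", exc)
        res_a = None
    # condition: zero baseline minus mean T1 condition per pairing unit
    if len(cond_scores):
        mean_cond = cond_scores.groupby(keys)["condition"].mean()
        d_cond = (0.0 - mean_cond).to_numpy(dtype=float)
        try:
            res_c = signed_rank_test(d_cond, alternative="greater")
        except ValueError as exc:
            logger.info("paired condition test skipped: %s", exc)
            res_c = None
    else:
        res_c = None
    for res, what in ((res_a, "abundance"), (res_c, "condition")):
        if res is None:
            continue
        res = res.adjusted(m=2, method="bonferroni")
        res.method = f"paired_{what}_{res.method}"
        results.append(res)
    return results


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and return (and optionally write) the report."""
    config.validate()

    # ---- load or simulate ------------------------------------------------
    if config.simulate:
        bundle = generate_study(seamount_study_config(), seed=config.seed)
        sites, oxygen = bundle.sites, bundle.oxygen
        t0_all, t1_all = bundle.annotations_t0, bundle.annotations_t1
        polygons = bundle.polygons
        if config.outdir:
            write_bundle(bundle, Path(config.outdir) / "simulated_inputs")
    else:
        try:
            t0_all = read_annotations(config.annotations_t0, timepoint="T0")
            t1_all = read_annotations(config.annotations_t1, timepoint="T1")
            sites = pd.read_csv(config.sites) if config.sites else None
            oxygen = read_oxygen_series(config.oxygen) if config.oxygen else None
            polygons = read_overlap_regions(config.polygons) if config.polygons else {}
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage read: {exc}") from exc
    if sites is None:
        sites = pd.DataFrame({
            "site_id": sorted(set(t0_all["site_id"]) | set(t1_all["site_id"]))})
        sites["seamount"] = "unknown"

    # ---- oxygen zones ----------------------------------------------------
    zones = _zone_table(sites, oxygen)
    factors = zones[["site_id", "seamount", "zone_t0"]].rename(
        columns={"zone_t0": "zone"})

    # ---- clip and match --------------------------------------------------
    matchsets = []
    t0_clipped = []
    try:
        for sid in sites["site_id"]:
            t0 = t0_all[t0_all["site_id"] == sid].reset_index(drop=True)
            t1 = t1_all[t1_all["site_id"] == sid].reset_index(drop=True)
            region = polygons.get(sid)
            t0 = clip_to_overlap(t0, region)
            t0_clipped.append(t0)
            if len(t0) == 0 and len(t1) == 0:
                continue
            matchsets.append(match_individuals(t0, t1, tolerance=config.tolerance_m))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage match (site {sid}): {exc}") from exc
    t0_overlap = pd.concat(t0_clipped, ignore_index=True) if t0_clipped else t0_all
    annotations = pd.concat([t0_overlap, t1_all], ignore_index=True)

    # ---- fates and abundance --------------------------------------------
    fates = fate_table(matchsets, annotations, extra_factors=factors)
    factor_cols = ["site_id", "phylum", "zone", "seamount"]
    fate_tallies = {f: fate_tally(fates, by=f) for f in factor_cols}
    otu_deltas = {f: per_otu_delta(fates, by=f) for f in factor_cols}
    delta_summaries = {f: delta_summary(otu_deltas[f], by=f) for f in factor_cols}

    # ---- condition -------------------------------------------------------
    survivor_t1_ids = set(
        fates.loc[fates["fate"] == "survived", "t1_id"].dropna())
    cohort = t1_all[t1_all["individual_id"].isin(survivor_t1_ids)].reset_index(drop=True)
    if len(cohort):
        try:
            cond = score_table(cohort, pooling=config.weight_pooling,
                               denominator=config.weight_denominator)
        except Exception as exc:
            raise PipelineError(f"stage condition: {exc}") from exc
        cond = cond.merge(factors, on="site_id", how="left")
    else:
        cond = pd.DataFrame(columns=["individual_id", "site_id", "phylum", "otu",
                                     "condition", "clamped", "zone", "seamount"])
    condition_summaries = {
        f: factor_condition_summary(cond, by=f) for f in factor_cols if len(cond)
    }

    # ---- statistics ------------------------------------------------------
    stat_rows: list[dict] = []
    dunn_tables: dict[str, pd.DataFrame] = {}

    def record(res: TestResult, factor: str) -> None:
        stat_rows.append({
            "test": res.method, "factor": factor, "statistic": res.statistic,
            "n": res.n_effective, "alternative": res.alternative,
            "p_value": res.p_value, "p_adjusted": res.p_adjusted,
            "exact": res.exact, "adjustment": res.adjustment,
        })

    for res in _paired_tests(fates, cond, config.test_pairing, config.alpha):
        record(res, "headline")

    def _groups(df, by, col):
        levels = [(lvl, g[col].dropna().to_numpy(dtype=float))
                  for lvl, g in df.groupby(by, sort=True)]
        return [(lvl, v) for lvl, v in levels if len(v)]

    for what, df, col in (
        ("delta_abundance", None, "delta_pct"),
        ("condition", cond, "condition"),
    ):
        for factor in ("site_id", "zone", "seamount", "phylum"):
            if what == "delta_abundance":
                src = otu_deltas[factor]
                src = src[src["defined"]]
            else:
                src = df
            if src is None or not len(src):
                continue
            grp = _groups(src, factor, col)
            if len(grp) < 2:
                continue
            labels, values = zip(*grp)
            if factor == "phylum" and len(labels) == 2:
                res = rank_sum_test(values[0], values[1], alternative="two_sided")
                res.method = f"{what}_{res.method}"
                record(res, factor)
                continue
            res = kruskal_wallis(values)
            res.method = f"{what}_{res.method}"
            record(res, factor)
            if res.p_value <= config.alpha:
                dunn_tables[f"{what}_{factor}"] = dunn_posthoc(
                    values, labels=list(labels), adjustment=config.adjustment)

    statistics = pd.DataFrame(stat_rows)

    # ---- headline and log ------------------------------------------------
    bundle_out = ReportBundle(
        sites=sites, zones=zones, fates=fates, fate_tallies=fate_tallies,
        otu_deltas=otu_deltas, delta_summaries=delta_summaries,
        condition_scores=cond, condition_summaries=condition_summaries,
        statistics=statistics, dunn_tables=dunn_tables, headline={},
    )
    bundle_out.headline = summarize_headline(bundle_out)
    bundle_out.log = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": {
            "benthochange": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "matcher_note": (matchsets[0].note if matchsets else None),
    }

    if config.outdir:
        _write_report(bundle_out, config.outdir)
    return bundle_out


def summarize_headline(bundle: ReportBundle) -> dict:
    """Study-wide headline metrics.

    A site "declined in abundance" when its net individual change is
    negative; it "declined in condition" when the mean condition of its
    assessed survivors is negative.
    """
    site_tally = bundle.fate_tallies["site_id"]
    phylum_tally = bundle.fate_tallies["phylum"].set_index("phylum")
    n_abund_decline = int((site_tally["net_change"] < 0).sum())
    if len(bundle.condition_scores):
        site_cond = bundle.condition_scores.groupby("site_id")["condition"].mean()
        n_cond_decline = int((site_cond < 0).sum())
    else:
        n_cond_decline = 0
    out = {
        "n_sites": int(len(bundle.sites)),
        "total_t0": int(site_tally["n_t0"].sum()),
        "total_t1": int(site_tally["n_t1"].sum()),
        "total_lost": int(site_tally["lost"].sum()),
        "total_recruits": int(site_tally["recruits"].sum()),
        "net_change": int(site_tally["net_change"].sum()),
        "sites_abundance_declined": n_abund_decline,
        "sites_condition_declined": n_cond_decline,
    }
    for ph in ("Porifera", "Cnidaria"):
        if ph in phylum_tally.index:
            n0 = int(phylum_tally.loc[ph, "n_t0"])
            lost = int(phylum_tally.loc[ph, "lost"])
            out[f"{ph.lower()}_lost"] = lost
            out[f"{ph.lower()}_t0"] = n0
            out[f"{ph.lower()}_loss_pct"] = 100.0 * lost / n0 if n0 else float("nan")
    return out


def _write_report(bundle: ReportBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.zones.to_csv(out / "zones.csv", index=False)
    bundle.fates.to_csv(out / "fates.csv", index=False)
    for factor, df in bundle.fate_tallies.items():
        df.to_csv(out / f"fate_tally_{factor}.csv", index=False)
    for factor, df in bundle.otu_deltas.items():
        df.to_csv(out / f"otu_delta_{factor}.csv", index=False)
    for factor, df in bundle.delta_summaries.items():
        df.to_csv(out / f"delta_summary_{factor}.csv", index=False)
    bundle.condition_scores.to_csv(out / "condition_individuals.csv", index=False)
    for factor, df in bundle.condition_summaries.items():
        df.to_csv(out / f"condition_summary_{factor}.csv", index=False)
    bundle.statistics.to_csv(out / "statistics.csv", index=False)
    for name, df in bundle.dunn_tables.items():
        df.to_csv(out / f"dunn_{name}.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump({"headline": bundle.headline, "log": bundle.log}, fh, indent=2,
                  default=str)
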