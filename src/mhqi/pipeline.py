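"""End-to-end orchestration: load -> cohorts -> indicators -> pooling.

A run is described by a :class:`RunConfig` (region bundle paths, recruitment
year, gap thresholds, coding-map overrides) and produces a deterministic
report bundle: per-region cohorts and exclusion traces, the regional
indicator grid, the pooled whole-sample grid with heterogeneity statistics,
and rendered tables.  A hash of the configuration is embedded in every
output file header so reports are traceable to their settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coding import CodingMaps, DEFAULT_MAPS
from .cohorts import select_newly_taken_in_care, select_prevalent
from .indicators import INDICATORS, compute_indicators, patient_features
from .io import read_region
from .model import EventStore
from .pooling import PoolingError, pool_medians, pool_proportions, pool_smr
from .synthetic import DEFAULT_MORTALITY

COHORTS = ("prevalent", "newly_taken_in_care")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and region."""


@dataclass
class RunConfig:
    bundles: list  # paths of region bundle directories
    recruitment_year: int = 2015
    gap_days: int = 90
    readmission_windows: tuple = (7, 30)
    discharge_followup_days: int = 14
    coding_maps: Optional[str] = None  # YAML path; None -> shipped defaults
    reference_mortality: dict = field(default_factory=lambda: dict(DEFAULT_MORTALITY))
    rounding: int = 1

    def maps(self) -> CodingMaps:
        return CodingMaps.from_yaml(self.coding_maps) if self.coding_maps else DEFAULT_MAPS

    def hash(self) -> str:
        payload = json.dumps(
            {
                "bundles": [str(b) for b in self.bundles],
                "recruitment_year": self.recruitment_year,
                "gap_days": self.gap_days,
                "readmission_windows": list(self.readmission_windows),
                "discharge_followup_days": self.discharge_followup_days,
                "coding_maps": self.coding_maps,
                "reference_mortality": {f"{k[0]}|{k[1]}": v for k, v in sorted(self.reference_mortality.items())},
                "rounding": self.rounding,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ref = raw.get("reference_mortality")
        if ref:
            raw["reference_mortality"] = {
                tuple(k.split("|")): float(v) for k, v in ref.items()
            }
        if "readmission_windows" in raw:
            raw["readmission_windows"] = tuple(raw["readmission_windows"])
        return cls(**raw)


@dataclass
class RunReport:
    config_hash: str
    cohorts: pd.DataFrame
    traces: pd.DataFrame
    regional: pd.DataFrame
    pooled: pd.DataFrame
    load_reports: list


def _pool_all(regional: pd.DataFrame, samples: dict) -> pd.DataFrame:
    rows = []
    for (ind_id, cohort), grp in regional.groupby(["indicator_id", "cohort"], sort=False):
        kind = grp["kind"].iloc[0]
        base = {
            "indicator_id": ind_id,
            "cohort": cohort,
            "kind": kind,
            "n_regions": int(grp["n_available"].astype(bool).sum()),
        }
        try:
            if kind == "proportion":
                est = pool_proportions(grp, ind_id, cohort)
            elif kind == "median_per_py":
                reg_samples = {
                    r: samples.get((r, cohort, ind_id), np.array([]))
                    for r in grp["region"]
                }
                est = pool_medians(grp, reg_samples, ind_id, cohort)
            else:
                avail = grp[grp["n_available"].astype(bool)]
                res = pool_smr(avail)  # may raise on an empty cohort (E = 0)
                rows.append(
                    {
                        **base,
                        "pooled_value": res.smr,
                        "numerator": res.observed,
                        "denominator": res.expected,
                        "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1],
                        "q": np.nan,
                        "df": np.nan,
                        "p_hom": np.nan,
                        "i2": np.nan,
                        "band": "",
                    }
                )
                continue
        except (PoolingError, ValueError):
            rows.append({**base, "pooled_value": np.nan, "numerator": np.nan,
                         "denominator": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "q": np.nan, "df": np.nan, "p_hom": np.nan, "i2": np.nan, "band": ""})
            continue
        rows.append(
            {
                **base,
                "pooled_value": est.pooled_value,
                "numerator": est.numerator,
                "denominator": est.denominator,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "q": est.q,
                "df": est.df,
                "p_hom": est.p_hom,
                "i2": est.i2,
                "band": est.band,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig, stores: Optional[list[EventStore]] = None
) -> RunReport:
    """Execute the full pipeline; ``stores`` bypasses bundle reading when
    regions are already in memory (e.g. straight from the generator)."""
    maps = config.maps()
    load_reports = []
    if stores is None:
        stores = []
        for b in config.bundles:
            try:
                store, rep = read_region(b, maps)
            except Exception as exc:  # noqa: BLE001 - annotate stage and region
                raise PipelineError(f"load failed for bundle {b}: {exc}") from exc
            stores.append(store)
            load_reports.append(rep)

    cohort_frames, trace_frames, regional_frames = [], [], []
    samples: dict = {}
    for store in stores:
        try:
            prevalent = select_prevalent(store, config.recruitment_year, maps)
            newly, traces = select_newly_taken_in_care(
                store, prevalent, maps, gap_days=config.gap_days
            )
        except Exception as exc:
            raise PipelineError(f"cohort selection failed for {store.region}: {exc}") from exc
        prevalent = prevalent.assign(region=store.region)
        newly = newly.assign(region=store.region)
        traces = traces.assign(region=store.region)
        cohort_frames += [prevalent, newly]
        trace_frames.append(traces)
        for cohort_label, members in (
            ("prevalent", prevalent),
            ("newly_taken_in_care", newly),
        ):
            try:
                feats = patient_features(store, members, maps, gap_days=config.gap_days)
                res, smp = compute_indicators(
                    store,
                    members,
                    cohort_label,
                    maps,
                    reference_mortality=config.reference_mortality,
                    gap_days=config.gap_days,
                    features=feats,
                )
            except Exception as exc:
                raise PipelineError(
                    f"indicator computation failed for {store.region}/{cohort_label}: {exc}"
                ) from exc
            regional_frames.append(res)
            for ind_id, arr in smp.items():
                samples[(store.region, cohort_label, ind_id)] = arr

    regional = pd.concat(regional_frames, ignore_index=True)
    pooled = _pool_all(regional, samples)
    return RunReport(
        config_hash=config.hash(),
        cohorts=pd.concat(cohort_frames, ignore_index=True),
        traces=pd.concat(trace_frames, ignore_index=True),
        regional=regional,
        pooled=pooled,
        load_reports=load_reports,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _fmt(value: float, kind: str, rounding: int) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    if kind == "proportion":
        return f"{round(float(value) + 1e-12, rounding):.{rounding}f}%"
    if kind == "smr":
        return f"{round(float(value) + 1e-12, 2):.2f}"
    return f"{round(float(value) + 1e-12, rounding):.{rounding}f}"


def render_table(
    regional: pd.DataFrame, pooled: pd.DataFrame, cohort: str, rounding: int = 1
) -> str:
    """Render one cohort's indicator grid as a Markdown table.

    One row per indicator: regional values, the whole-sample value and I²;
    regionally unavailable indicators appear blank with a footnote marker.
    """
    reg = regional[regional["cohort"] == cohort]
    poo = pooled[pooled["cohort"] == cohort].set_index("indicator_id")
    regions = list(dict.fromkeys(reg["region"]))
    lines = [
        "| id | indicator | " + " | ".join(regions) + " | whole sample | I2 |",
        "|" + "---|" * (len(regions) + 4),
    ]
    for defn in INDICATORS:
        sub = reg[reg["indicator_id"] == defn.id].set_index("region")
        if sub.empty:
            continue
        cells = []
        for r in regions:
            if r not in sub.index or not bool(sub.at[r, "n_available"]):
                cells.append("— (a)")
            else:
                cells.append(_fmt(sub.at[r, "value"], defn.kind, rounding))
        if defn.id in poo.index:
            prow = poo.loc[defn.id]
            pooled_cell = _fmt(prow["pooled_value"], defn.kind, rounding)
            i2_cell = "" if defn.kind == "smr" else _fmt(prow["i2"], "median", 0)
        else:
            pooled_cell, i2_cell = "", ""
        label = defn.label.replace("|", "/")
        lines.append(
            f"| {defn.id} | {label} | " + " | ".join(cells) + f" | {pooled_cell} | {i2_cell} |"
        )
    lines.append("")
    lines.append("(a) information not available in this region's systems.")
    return "\n".join(lines)


def parse_rendered_table(text: str) -> pd.DataFrame:
    """Parse a rendered table back to numeric cells (round-trip checking)."""
    rows = []
    lines = [ln for ln in text.splitlines() if ln.startswith("|")]
    header = [c.strip() for c in lines[0].strip("|").split("|")]
    for ln in lines[2:]:
        cells = [c.strip() for c in ln.strip("|").split("|")]
        rec = dict(zip(header, cells))
        for key, raw in list(rec.items()):
            if key in ("id", "indicator"):
                continue
            raw = raw.rstrip("%")
            try:
                rec[key] = float(raw)
            except ValueError:
                rec[key] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir, rounding: int = 1) -> None:
    """Write the report bundle (CSVs with a config-hash header, Markdown
    tables, run log) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# mhqi {__version__} config_hash={report.config_hash}\n"
    for name, df in (
        ("cohorts", report.cohorts),
        ("exclusion_traces", report.traces),
        ("indicators_regional", report.regional),
        ("indicators_pooled", report.pooled),
    ):
        path = out / f"{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    for cohort in COHORTS:
        text = render_table(report.regional, report.pooled, cohort, rounding)
        (out / f"table_{cohort}.md").write_text(header + text, encoding="utf-8")
    log = {
        "version": __version__,
        "config_hash": report.config_hash,
        "n_members": {
            c: int((report.cohorts["cohort"] == c).sum()) for c in COHORTS
        },
        "load_reports": [
            {"region": r.region, "rows": r.rows, "dropped": r.dropped_unknown_patient}
            for r in report.load_reports
        ],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")
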