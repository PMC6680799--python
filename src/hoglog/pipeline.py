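"""End-to-end pipeline: simulate -> features -> classify -> rhythm -> DFC ->
space use -> nest survival -> phase comparison, with a reproducibility
manifest.

The pipeline is a thin composition of the library stages with fixed CSV file
contracts, meant for scaled synthetic studies and as the template for real
deployments.  Every stage's row counts and output checksums are recorded in
``manifest.json``; identical (config, seed) runs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

from . import classify, features, nests, rhythm, spatial
from .dfc import moving_dfc
from .compare import ChangeEstimates, estimate_changes, summarize_changes
from .config import StudyConfig
from .synthetic import StudyData, generate_study


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclasses.dataclass
class PipelineParams:
    """Stage parameters not already fixed by the study configuration."""

    tau: float = 0.7
    train_per_class: int = 60
    onset_run_k: int = 1
    min_fixes: int = 5
    kde_grid: int = 200
    ci_method: str = "conditional"
    min_bursts: int | None = None  # None: scale 1430/1440 to bursts_per_day

    def resolved_min_bursts(self, config: StudyConfig) -> int:
        if self.min_bursts is not None:
            return self.min_bursts
        return int(np.ceil(config.bursts_per_day * 1430 / 1440))


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Schema and sanity diagnostics for the pipeline input tables.

    Returns human-readable problem descriptions; an empty list means clean.
    Diagnostics only — never raises.
    """
    problems: list[str] = []
    schemas = {
        "bursts": {"individual_id", "burst_id", "timestamp", "sample_idx", "ax_g", "ay_g", "az_g"},
        "gps": {"individual_id", "timestamp", "x_m", "y_m"},
        "nests": {"individual_id", "sex", "date", "nest_id"},
        "twilight": {"date", "civil_dawn", "civil_dusk"},
    }
    for name, needed in schemas.items():
        if name not in tables:
            continue
        cols = set(tables[name].columns)
        missing = needed - cols
        if missing:
            problems.append(f"{name}: missing columns {sorted(missing)}")
        extra_axes = {c for c in cols if c.startswith("a") and c.endswith("_g")} - {
            "ax_g", "ay_g", "az_g"
        }
        if name == "bursts" and extra_axes:
            problems.append(f"bursts: unexpected axis columns {sorted(extra_axes)}")
    if "nests" in tables and not ({"individual_id", "date"} - set(tables["nests"].columns)):
        n = tables["nests"]
        dup = n.duplicated(["individual_id", "date"], keep=False)
        if dup.any():
            dates = sorted({str(d) for d in n.loc[dup, "date"]})
            problems.append(f"nests: duplicated daily checks on {dates}")
    for name in ("bursts", "gps"):
        if name in tables and {"individual_id", "timestamp"} <= set(tables[name].columns):
            t = tables[name]
            ts = pd.to_datetime(t["timestamp"])
            mono = ts.groupby(t["individual_id"]).apply(lambda s: s.is_monotonic_increasing)
            for ind, ok in mono.items():
                if not ok:
                    problems.append(f"{name}: timestamps not sorted for {ind}")
    return problems


def run_pipeline(
    config: StudyConfig,
    outdir,
    params: PipelineParams | None = None,
    study: StudyData | None = None,
) -> dict:
    """Run every stage on a (generated) study and write the report bundle.

    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    params = params or PipelineParams()
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "params": dataclasses.asdict(params),
        "stages": {},
    }
    cal = config.calendar()
    min_bursts = params.resolved_min_bursts(config)

    def stage(name):
        def deco(fn):
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return out

        return deco

    @stage("simulate")
    def study_data() -> StudyData:
        return study if study is not None else generate_study(config)

    manifest["stages"]["simulate"] = {
        "bursts_rows": 0 if study_data.bursts is None else len(study_data.bursts),
        "gps_rows": len(study_data.gps),
        "nest_rows": len(study_data.nests),
    }

    @stage("features")
    def feat() -> pd.DataFrame:
        kept, dropped = features.validate_bursts(
            study_data.bursts, expected_n=config.samples_per_burst
        )
        tab = features.featurize(kept, expected_n=config.samples_per_burst, hz=config.burst_hz)
        manifest["stages"]["features"] = {
            "bursts_kept": len(tab),
            "bursts_dropped": len(dropped),
        }
        return tab

    @stage("classify")
    def predictions() -> pd.DataFrame:
        labels = study_data.truth.burst_labels.set_index("burst_id")["behavior"]
        train_tab = feat[~feat["missing"]].copy()
        train_tab["label"] = train_tab["burst_id"].map(labels)
        train_tab = train_tab[train_tab["label"].isin(classify.CLASSES)]
        idx = []
        for _, g in train_tab.groupby("label"):
            take = min(len(g), params.train_per_class)
            idx.extend(g.sample(take, random_state=config.seed).index)
        sample = train_tab.loc[idx].reset_index(drop=True)
        model = classify.train(sample, sample["label"], tau=params.tau, random_state=config.seed)
        pred = feat[["individual_id", "burst_id", "timestamp"]].copy()
        pred["label"] = classify.predict_gated(model, feat, tau=params.tau).to_numpy()
        manifest["stages"]["classify"] = {
            "n_train": len(sample),
            "n_predicted": len(pred),
            "other_fraction": float((pred["label"] == classify.OTHER).mean()),
        }
        return pred

    @stage("budgets")
    def budgets() -> pd.DataFrame:
        b = classify.daily_budget(predictions, min_bursts=min_bursts)
        manifest["stages"]["budgets"] = {"days_kept": len(b)}
        return b

    @stage("rhythm")
    def rhythm_tab() -> pd.DataFrame:
        r = rhythm.rhythm_table(
            feat, study_data.twilight, k=params.onset_run_k, min_bursts=min_bursts
        )
        manifest["stages"]["rhythm"] = {"days": len(r)}
        return r

    @stage("dfc")
    def dfc_tab() -> pd.DataFrame:
        series = rhythm.minute_series(feat)
        d = moving_dfc(series)
        manifest["stages"]["dfc"] = {
            "windows": len(d),
            "windows_ok": int(d["window_ok"].sum()) if len(d) else 0,
        }
        return d

    @stage("spatial")
    def areas() -> pd.DataFrame:
        events = spatial.clean_fixes(
            study_data.gps, event_interval_min=config.gps_interval_min
        )
        a = spatial.night_areas(events, min_fixes=params.min_fixes, grid_size=params.kde_grid)
        manifest["stages"]["spatial"] = {
            "events": len(events),
            "nights": len(a),
        }
        return spatial.phase_area_table(a, cal)

    @stage("nests")
    def nest_out() -> tuple[pd.DataFrame, pd.DataFrame]:
        spells = nests.build_spells(study_data.nests, cal)
        summary = nests.nest_survival_summary(spells)
        manifest["stages"]["nests"] = {"spells": len(spells)}
        return spells, summary

    @stage("compare")
    def changes() -> tuple[pd.DataFrame, pd.DataFrame]:
        daily_inputs: dict[str, tuple[pd.DataFrame, str | None]] = {}
        if len(areas):
            daily_inputs["kde50"] = (
                areas.rename(columns={"night": "date", "area_ha": "value"}),
                None,
            )
        for label in list(classify.CLASSES) + [classify.OTHER]:
            if len(budgets):
                daily_inputs[f"budget_count:{label}"] = (
                    budgets.rename(columns={label: "value"})[
                        ["individual_id", "date", "value"]
                    ],
                    None,
                )
        if len(rhythm_tab):
            daily_inputs["DI"] = (
                rhythm_tab.rename(columns={"DI": "value"})[["individual_id", "date", "value"]],
                "DI",
            )
            daily_inputs["TSdusk"] = (
                rhythm_tab.rename(columns={"TSdusk_min": "value"})[
                    ["individual_id", "date", "value"]
                ],
                "TSdusk",
            )
            daily_inputs["ODBA"] = (
                rhythm_tab.rename(columns={"daily_odba": "value"})[
                    ["individual_id", "date", "value"]
                ],
                "ODBA",
            )
        if len(dfc_tab):
            daily_inputs["DFC"] = (
                dfc_tab.rename(columns={"dfc": "value"})[["individual_id", "date", "value"]],
                None,
            )
        ests: dict[str, ChangeEstimates] = {}
        tables = []
        for param, (daily, tname) in daily_inputs.items():
            try:
                est = estimate_changes(
                    daily, cal, parameter=tname, ci_method=params.ci_method
                )
            except (ValueError, KeyError):
                continue
            ests[param] = est
            t = est.table.copy()
            t.insert(0, "parameter", param)
            tables.append(t)
        changes_tab = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(
                columns=["parameter", "individual_id", "pred_change", "ci_lo", "ci_hi", "significant"]
            )
        )
        manifest["stages"]["compare"] = {"parameters": sorted(ests)}
        return changes_tab, summarize_changes(ests)

    spells_tab, nest_summary = nest_out
    changes_tab, change_summary = changes

    outputs = {
        "features.csv": feat,
        "predictions.csv": predictions,
        "budgets.csv": budgets,
        "rhythm.csv": rhythm_tab,
        "dfc.csv": dfc_tab,
        "areas.csv": areas,
        "spells.csv": spells_tab,
        "nest_summary.csv": nest_summary,
        "changes.csv": changes_tab,
        "change_summary.csv": change_summary,
    }
    checksums = {}
    for name, tab in outputs.items():
        path = outdir / name
        tab.to_csv(path, index=False)
        checksums[name] = _sha256(path)
    manifest["checksums"] = checksums
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
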