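"""End-to-end workflow: simulate -> measure -> analyse, with file outputs.

These functions back the command-line interface but are equally usable as a
library API. All randomness flows from the configured seed; outputs carry
no timestamps, so a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import RunConfig
from .errors import FemrotError
from .models import FemurModel
from .pipeline import measure_subject
from .stats import (
    ANGLE_NAMES,
    bland_altman,
    cohort_summary,
    compare_axes,
    icc_two_way,
    pivot_for_icc,
)
from .synthetic import ObserverModel, generate_cohort, simulate_observation

log = logging.getLogger("femrot")


def package_version() -> str:
    try:
        return version("femrot")
    except PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


def observer_ids(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def cmd_simulate(config: RunConfig, out_dir: str | Path) -> dict:
    """Generate a cohort; write per-subject model JSONs, truth CSV, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models, truth = generate_cohort(config.cohort_params())
    model_files = []
    for m in models:
        path = out / f"model_{m.subject_id}.json"
        fio.save_model(m, path)
        model_files.append(path.name)
    truth.to_csv(out / "truth.csv", index=False)
    manifest = {
        "seed": config.seed,
        "version": package_version(),
        "n_subjects": len(models),
        "subjects": [m.subject_id for m in models],
        "files": model_files + ["truth.csv"],
    }
    fio.write_json(manifest, out / "manifest.json")
    log.info("simulated %d femur models into %s", len(models), out)
    return manifest


def measure_models(
    models: list[FemurModel],
    config: RunConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Measure every subject under observers x sessions of landmark noise.

    Per-subject failures are logged and skipped; an all-subjects failure
    raises. Returns the long angles table.
    """
    obs_models = [ObserverModel(observer_id=o, landmark_sigma=config.sigma) for o in observer_ids(config.observers)]
    records: list[dict] = []
    n_failed = 0
    for model in models:
        try:
            subject_rows = []
            for obs in obs_models:
                for session in range(1, config.sessions + 1):
                    lms = simulate_observation(model, obs, rng)
                    dev = measure_subject(model, landmarks=lms, outlier_threshold_deg=config.outlier_threshold)
                    row = dev.as_dict()
                    row["observer_id"] = obs.observer_id
                    row["session"] = session
                    subject_rows.append(row)
        except FemrotError as exc:
            n_failed += 1
            log.warning("skipping subject %s: %s", model.subject_id, exc)
            continue
        records.extend(subject_rows)
    if not records:
        raise FemrotError(f"all {n_failed} subject(s) failed to measure")
    return pd.DataFrame(records, columns=fio.ANGLES_COLUMNS)


def cmd_measure(config: RunConfig, models_dir: str | Path, out_path: str | Path) -> pd.DataFrame:
    """Load model JSONs from a simulate run and write the angles CSV."""
    models_dir = Path(models_dir)
    paths = sorted(models_dir.glob("model_*.json"))
    if not paths:
        raise FemrotError(f"no model files found in {models_dir}")
    models = []
    for p in paths:
        try:
            models.append(fio.load_model(p))
        except (ValueError, KeyError) as exc:
            log.warning("skipping unreadable model file %s: %s", p.name, exc)
    if not models:
        raise FemrotError("no readable model files")
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from generation
    df = measure_models(models, config, rng)
    df.to_csv(out_path, index=False)
    log.info("wrote %d angle rows to %s", len(df), out_path)
    return df


def analyse_angles(angles: pd.DataFrame, config: RunConfig) -> dict:
    """Reliability + accuracy analysis of a long angles table.

    Intra-observer reliability compares the first observer's two sessions;
    inter-observer reliability compares the two observers' final session.
    Accuracy summaries and the three-axis comparison use the first
    observer's first session (one measurement per subject).
    """
    observers = sorted(angles["observer_id"].unique())
    sessions = sorted(angles["session"].unique())
    first_obs = observers[0]
    base = angles[(angles["observer_id"] == first_obs) & (angles["session"] == sessions[0])]
    groups = {name: base[f"{name}_deg"].to_numpy() for name in ANGLE_NAMES}

    summary = cohort_summary(groups, threshold_deg=config.outlier_threshold)
    comparison = compare_axes(groups)

    result: dict = {
        "n_subjects": int(base["subject_id"].nunique()),
        "angles": summary.set_index("angle").to_dict(orient="index"),
        "comparison": {k: v for k, v in comparison.items() if k != "pairwise"},
        "pairwise": comparison["pairwise"].to_dict(orient="records"),
        "icc_form": config.icc_form,
        "icc": {},
        "bland_altman": {},
        "bland_altman_points": {},
    }

    designs = {}
    if len(sessions) >= 2:
        designs["intra"] = ("session", (sessions[0], sessions[1]), {"observer_id": first_obs})
    if len(observers) >= 2:
        designs["inter"] = ("observer_id", (observers[0], observers[1]), {"session": sessions[-1]})

    for block, (key, levels, fixed) in designs.items():
        result["icc"][block] = {}
        result["bland_altman"][block] = {}
        result["bland_altman_points"][block] = {}
        for name in ANGLE_NAMES:
            pairs = pivot_for_icc(angles, name, key, levels, fixed)
            icc = icc_two_way(pairs, form=config.icc_form)
            ba = bland_altman(pairs)
            result["icc"][block][name] = icc.as_dict()
            result["bland_altman"][block][name] = ba.as_dict()
            result["bland_altman_points"][block][name] = np.column_stack(
                [pairs.mean(axis=1), pairs[:, 0] - pairs[:, 1]]
            )
    return result


def _reliability_table(angles: pd.DataFrame, result: dict, block: str, row_labels: dict) -> pd.DataFrame:
    """Study-style table: per-repeat mean +/- SD rows plus an ICC (CI) row."""
    rows = []
    for label, (key, value, fixed) in row_labels.items():
        sub = angles.copy()
        for fk, fv in fixed.items():
            sub = sub[sub[fk] == fv]
        sub = sub[sub[key] == value]
        row = {"item": label}
        for name in ANGLE_NAMES:
            v = sub[f"{name}_deg"].to_numpy()
            row[name] = f"{np.mean(v):.2f} ± {np.std(v, ddof=1):.2f}"
        rows.append(row)
    icc_row = {"item": "ICC(95%CI)"}
    for name in ANGLE_NAMES:
        d = result["icc"][block][name]
        icc_row[name] = f"{d['icc']:.3f}({d['ci_low']:.3f} ~ {d['ci_high']:.3f})"
    rows.append(icc_row)
    return pd.DataFrame(rows)


def cmd_stats(config: RunConfig, angles: pd.DataFrame, out_dir: str | Path) -> dict:
    """Run the full analysis and write report tables + summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = analyse_angles(angles, config)

    observers = sorted(angles["observer_id"].unique())
    sessions = sorted(angles["session"].unique())
    files = ["summary.json", "comparison.csv", "outliers.csv"]

    if "intra" in result["icc"]:
        first = observers[0]
        tab = _reliability_table(
            angles,
            result,
            "intra",
            {
                "First measurement": ("session", sessions[0], {"observer_id": first}),
                "Second measurement": ("session", sessions[1], {"observer_id": first}),
            },
        )
        tab.to_csv(out / "table_intra.csv", index=False)
        files.append("table_intra.csv")
    if "inter" in result["icc"]:
        tab = _reliability_table(
            angles,
            result,
            "inter",
            {
                f"Observer {observers[0]}": ("observer_id", observers[0], {"session": sessions[-1]}),
                f"Observer {observers[1]}": ("observer_id", observers[1], {"session": sessions[-1]}),
            },
        )
        tab.to_csv(out / "table_inter.csv", index=False)
        files.append("table_inter.csv")

    pd.DataFrame(result["pairwise"]).to_csv(out / "comparison.csv", index=False)
    outliers = pd.DataFrame(
        [
            {
                "angle": name,
                "outlier_count": result["angles"][name]["outlier_count"],
                "outlier_percent": result["angles"][name]["outlier_percent"],
                "n": result["angles"][name]["n"],
            }
            for name in ANGLE_NAMES
        ]
    )
    outliers.to_csv(out / "outliers.csv", index=False)

    for block, per_angle in result.pop("bland_altman_points").items():
        for name, pts in per_angle.items():
            path = out / f"bland_altman_{block}_{name}.tsv"
            pd.DataFrame(pts, columns=["mean", "diff"]).to_csv(path, sep="\t", index=False)
            files.append(path.name)

    summary = {"seed": config.seed, "version": package_version(), **result}
    fio.write_json(summary, out / "summary.json")
    fio.write_json({"seed": config.seed, "version": package_version(), "files": sorted(files)}, out / "stats_manifest.json")
    log.info("wrote analysis reports to %s", out)
    return summary


def cmd_run_all(config: RunConfig) -> dict:
    """simulate + measure + stats into ``config.out_dir``; returns the summary."""
    out = Path(config.out_dir)
    models_dir = out / "models"
    cmd_simulate(config, models_dir)
    angles = cmd_measure(config, models_dir, out / "angles.csv")
    return cmd_stats(config, angles, out / "stats")
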