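"""Chart data and figures: duration per patient, checkpoint user/nonuser
means, and per-setting means.

Every chart has a machine-readable CSV twin; the CSV is the source of truth
and the PNG is rendered from it. Builders operate on the analysis output
tables (adherence, activity profiles, patients) so a report can be produced
from a saved analysis directory without refitting.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "duration_chart_data",
    "checkpoint_chart_data",
    "setting_chart_data",
    "write_report",
]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing column(s) {missing}")


def duration_chart_data(adherence: pd.DataFrame) -> pd.DataFrame:
    """Per-patient total vs active days, sorted by total days (descending).

    The chart analogue: one bar pair per patient showing duration of use in
    relation to the active days within it.
    """
    _require_columns(adherence, ["patient_id", "total_days", "active_days"], "adherence")
    out = adherence[["patient_id", "total_days", "active_days"]].copy()
    out = out.sort_values(
        ["total_days", "active_days", "patient_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def checkpoint_chart_data(
    activity: pd.DataFrame, checkpoints: tuple[int, ...]
) -> pd.DataFrame:
    """Mean (SD) weekly steps at each checkpoint for users and for nonusers.

    Nonuser rows aggregate the carried-forward (LOCF) values, showing whether
    cohort-level increases are driven by dropout of low-activity patients.
    """
    _require_columns(activity, ["patient_id"], "activity_profiles")
    rows = []
    for cp in checkpoints:
        mean_col, status_col = f"day{cp}_mean", f"day{cp}_status"
        _require_columns(activity, [mean_col, status_col], "activity_profiles")
        for status, label in (("user", "user"), ("nonuser_locf", "nonuser")):
            vals = activity.loc[
                activity[status_col] == status, mean_col
            ].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "checkpoint_day": cp,
                    "group": label,
                    "n": len(vals),
                    "mean": round(float(vals.mean()), 4) if len(vals) else None,
                    "sd": (
                        round(float(vals.std(ddof=1)), 4)
                        if len(vals) > 1
                        else (0.0 if len(vals) == 1 else None)
                    ),
                }
            )
    return pd.DataFrame(rows)


def setting_chart_data(
    activity: pd.DataFrame, patients: pd.DataFrame
) -> pd.DataFrame:
    """Grand mean steps/day (mean, SD, n) per telerehabilitation setting."""
    _require_columns(activity, ["patient_id", "grand_mean"], "activity_profiles")
    _require_columns(patients, ["patient_id", "setting"], "patients")
    merged = activity.merge(patients[["patient_id", "setting"]], on="patient_id")
    if len(merged) != len(activity):
        raise ValueError("patients: some activity rows lack a setting")
    rows = []
    for setting in sorted(merged["setting"].unique()):
        vals = merged.loc[
            merged["setting"] == setting, "grand_mean"
        ].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "setting": setting,
                "n": len(vals),
                "mean": round(float(vals.mean()), 4) if len(vals) else None,
                "sd": (
                    round(float(vals.std(ddof=1)), 4)
                    if len(vals) > 1
                    else (0.0 if len(vals) == 1 else None)
                ),
            }
        )
    return pd.DataFrame(rows)


def _plot_duration(data: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(data["rank"], data["total_days"], color="0.7", label="total days")
    ax.bar(data["rank"], data["active_days"], color="0.1", label="active days")
    ax.set_xlabel("patient (sorted by total days)")
    ax.set_ylabel("days")
    ax.set_title("Duration of step-counter use per patient")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_checkpoints(data: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for group, marker in (("user", "o"), ("nonuser", "s")):
        sub = data[data["group"] == group].dropna(subset=["mean"])
        ax.errorbar(
            sub["checkpoint_day"], sub["mean"], yerr=sub["sd"].fillna(0.0),
            marker=marker, capsize=3, label=group,
        )
    ax.set_xlabel("study day")
    ax.set_ylabel("weekly mean steps/day")
    ax.set_title("Checkpoint weekly means: users vs nonusers (LOCF)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_settings(data: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    sub = data.dropna(subset=["mean"])
    ax.bar(
        sub["setting"], sub["mean"], yerr=sub["sd"].fillna(0.0),
        capsize=4, color="0.6",
    )
    ax.set_ylabel("grand mean steps/day")
    ax.set_title("Mean daily steps by telerehabilitation setting")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(analysis_dir: str | Path, out_dir: str | Path) -> None:
    """Build chart CSVs and PNGs from a saved analysis directory.

    Reads ``adherence.csv``, ``activity_profiles.csv`` and ``patients.csv``
    from ``analysis_dir``; writes ``duration_per_patient.csv``,
    ``checkpoint_means.csv``, ``setting_means.csv`` and matching ``.png``
    figures into ``out_dir``. Missing inputs or schema mismatches raise with
    the offending file/column named.
    """
    analysis_dir, out_dir = Path(analysis_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "adherence": analysis_dir / "adherence.csv",
        "activity": analysis_dir / "activity_profiles.csv",
        "patients": analysis_dir / "patients.csv",
    }
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing input {p} ({name})")
    adherence = pd.read_csv(paths["adherence"], dtype={"patient_id": str})
    activity = pd.read_csv(paths["activity"], dtype={"patient_id": str})
    patients = pd.read_csv(paths["patients"], dtype={"patient_id": str})

    checkpoints = tuple(
        sorted(
            int(c[len("day"):-len("_mean")])
            for c in activity.columns
            if c.startswith("day") and c.endswith("_mean")
        )
    )
    duration = duration_chart_data(adherence)
    checkpoint = checkpoint_chart_data(activity, checkpoints)
    setting = setting_chart_data(activity, patients)

    duration.to_csv(out_dir / "duration_per_patient.csv", index=False)
    checkpoint.to_csv(out_dir / "checkpoint_means.csv", index=False)
    setting.to_csv(out_dir / "setting_means.csv", index=False)
    _plot_duration(duration, out_dir / "duration_per_patient.png")
    _plot_checkpoints(checkpoint, out_dir / "checkpoint_means.png")
    _plot_settings(setting, out_dir / "setting_means.png")
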