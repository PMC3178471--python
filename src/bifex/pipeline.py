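"""End-to-end study orchestration: masks or cohort tables -> exponent tables.

``run_study`` reproduces the shape of the carotid-bifurcation analysis:
per-bifurcation records with radii, ICA tortuosity and junction exponent;
a radius-ratio summary table; cohort exponent estimates (nonlinear
regression and mean of individual roots) for all records and for the
low-tortuosity subset; and plot-data files for the fit-quality figure
(sum of daughter powers vs parent power).  Outputs are plain CSV/JSON and
byte-stable for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centerline import extract_bifurcation
from .exponent import (
    compare_sides,
    filter_low_tortuosity,
    fit_cohort_exponent,
    mean_individual_exponent,
    solve_exponent_records,
    summarize_ratios,
)
from .io import load_cohort, load_markers, load_mask
from .radius import measure_bifurcation

__all__ = ["RunConfig", "StudyReport", "run_study", "records_from_imaging"]

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Inputs and knobs for one study run.

    Provide either ``cohort_csv`` (radius triples, optionally with an
    ``ica_tortuosity`` column) or ``imaging_inputs`` as a list of
    ``(mask_path, markers_path)`` pairs to measure the triples from
    segmentations.
    """

    out_dir: str | Path
    cohort_csv: str | Path | None = None
    imaging_inputs: list[tuple[str, str]] = field(default_factory=list)
    method: str = "A"  # "A", "B" or "both"
    tortuosity_threshold: float = 0.1
    model_form: str = "parent_radius"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cohort_csv is None and not self.imaging_inputs:
            raise ValueError("config needs a cohort_csv or imaging_inputs")
        if self.tortuosity_threshold <= 0:
            raise ValueError("tortuosity_threshold must be > 0")
        if self.method not in ("A", "B", "both"):
            raise ValueError("method must be 'A', 'B' or 'both'")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw["imaging_inputs"] = [tuple(p) for p in raw.get("imaging_inputs", [])]
        return cls(**raw)


@dataclass
class StudyReport:
    records: pd.DataFrame
    ratio_summary: pd.DataFrame
    exponent_summary: pd.DataFrame
    paired_sides: dict | None
    log: dict
    out_dir: Path


def records_from_imaging(
    inputs: list[tuple[str, str]], methods: list[str]
) -> pd.DataFrame:
    """Measure radius triples (and ICA tortuosity) from mask/marker files.

    Subject and side are parsed from the mask filename when it follows
    ``<subject>_<side>*`` (e.g. ``s0001_left.nii.gz``); otherwise the file
    stem is the subject id and the side defaults to "left".
    """
    rows = []
    for mask_path, markers_path in inputs:
        mask = load_mask(mask_path)
        markers = load_markers(markers_path)
        bc = extract_bifurcation(mask, markers)
        stem = Path(mask_path).name.split(".")[0]
        parts = stem.split("_")
        subject = parts[0]
        side = parts[1] if len(parts) > 1 and parts[1] in ("left", "right") else "left"
        for method in methods:
            triple = measure_bifurcation(mask, bc, method=method)
            rows.append(
                {
                    "subject_id": subject,
                    "side": side,
                    "method": method,
                    "r_cca_mm": triple.r_cca,
                    "r_ica_mm": triple.r_ica,
                    "r_eca_mm": triple.r_eca,
                    "ica_tortuosity": bc.ica.tortuosity,
                }
            )
    return pd.DataFrame(rows)


def _exponent_rows(records: pd.DataFrame, method: str, subset: str,
                   model_form: str) -> list[dict]:
    rows = []
    fit = fit_cohort_exponent(records, model_form=model_form)
    ind = mean_individual_exponent(records)
    rows.append(
        {
            "method": method,
            "subset": subset,
            "estimator": f"regression_{model_form}",
            "n_hat": fit.n_hat,
            "ci95_low": fit.ci95[0],
            "ci95_high": fit.ci95[1],
            "n_obs": fit.n_obs,
        }
    )
    rows.append(
        {
            "method": method,
            "subset": subset,
            "estimator": "mean_individual",
            "n_hat": ind.mean,
            "ci95_low": np.nan,
            "ci95_high": np.nan,
            "n_obs": ind.n_ok,
        }
    )
    return rows


def run_study(config: RunConfig) -> StudyReport:
    """Run the full analysis and write its tables under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    methods = ["A", "B"] if config.method == "both" else [config.method]

    if config.cohort_csv is not None:
        records = load_cohort(config.cohort_csv)
        if "method" not in records.columns:
            records = records.assign(method=methods[0])
    else:
        records = records_from_imaging(config.imaging_inputs, methods)

    records = solve_exponent_records(records)
    n_no_root = int((records["solve_status"] != "ok").sum())

    ratio_rows, exp_rows, plot_frames = [], [], []
    for method in sorted(records["method"].unique()):
        sub = records[records["method"] == method]
        summ = summarize_ratios(sub)
        tbl = summ.stats.reset_index(names="quantity")
        tbl.insert(0, "method", method)
        ratio_rows.append(tbl)

        subsets = {"all": sub}
        if "ica_tortuosity" in sub.columns and sub["ica_tortuosity"].notna().all():
            subsets["low_tortuosity"] = filter_low_tortuosity(
                sub, config.tortuosity_threshold
            )
        for name, data in subsets.items():
            if len(data) >= 3:
                exp_rows.extend(_exponent_rows(data, method, name, config.model_form))

        if len(sub) < 3:
            continue  # too few records for a cohort fit or plot
        # fit-quality plot data: daughter power sum vs parent power at n_hat
        fit = fit_cohort_exponent(sub, model_form=config.model_form)
        for est, n_val in (("regression", fit.n_hat),
                           ("mean_individual", mean_individual_exponent(sub).mean)):
            plot_frames.append(
                pd.DataFrame(
                    {
                        "method": method,
                        "estimator": est,
                        "n": n_val,
                        "x_parent_power": sub["r_cca_mm"] ** n_val,
                        "y_daughter_power_sum": sub["r_ica_mm"] ** n_val
                        + sub["r_eca_mm"] ** n_val,
                    }
                )
            )

    ratio_summary = pd.concat(ratio_rows, ignore_index=True)
    exponent_summary = pd.DataFrame(exp_rows)
    plot_data = (pd.concat(plot_frames, ignore_index=True) if plot_frames
                 else pd.DataFrame())

    paired = None
    try:
        p = compare_sides(records[records["method"] == methods[0]])
        paired = {
            "ica_radius_t": p.ica_radius_t, "ica_radius_p": p.ica_radius_p,
            "exponent_t": p.exponent_t, "exponent_p": p.exponent_p,
            "df": p.df, "n_pairs": p.n_pairs,
            "n_excluded_subjects": p.n_excluded_subjects,
        }
    except (ValueError, KeyError):
        pass  # single-sided cohorts: paired comparison not applicable

    log = {
        "bifex_version": __version__,
        "seed": config.seed,
        "method": config.method,
        "model_form": config.model_form,
        "tortuosity_threshold": config.tortuosity_threshold,
        "n_records": int(len(records)),
        "n_no_root_excluded": n_no_root,
        "paired_sides": paired,
    }

    records.to_csv(out / "records.csv", index=False, float_format=FLOAT_FMT)
    ratio_summary.to_csv(out / "ratio_summary.csv", index=False, float_format=FLOAT_FMT)
    exponent_summary.to_csv(out / "exponent_summary.csv", index=False,
                            float_format=FLOAT_FMT)
    plot_data.to_csv(out / "fit_plot_data.csv", index=False, float_format=FLOAT_FMT)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return StudyReport(
        records=records, ratio_summary=ratio_summary,
        exponent_summary=exponent_summary, paired_sides=paired, log=log, out_dir=out,
    )
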