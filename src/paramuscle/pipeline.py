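"""End-to-end orchestration: manifest -> per-patient metrics -> cohort report.

``run_quantification`` walks a manifest CSV (one row per patient,
timepoint, rater pointing at an image and a mask file), runs the full
measurement chain per case — bias fit, correction, pooled Otsu threshold,
fat/muscle classification, CSA metrics — and emits a metrics table plus a
ΔRCSA table with the two raters averaged when both are present.

``run_statistics`` takes a cohort table and produces the study-style
report bundle: gated baseline comparisons, PRO and biomarker comparisons,
the multivariable ΔRCSA regression with tolerance/VIF and residual
diagnostics, and an ICC block when per-rater measurements are present.
Every number in a rendered report comes from the machine-readable JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import quant, stats
from .exceptions import DegenerateHistogramError
from .io import ENDPLATE, MUSCLE_LABELS, read_mask, read_slice, roi_pixel_area

logger = logging.getLogger("paramuscle")

MANIFEST_COLUMNS = ("patient_id", "timepoint", "rater", "image", "image_format", "mask")

#: outcome regression covariates, in reporting order
REGRESSION_COVARIATES = (
    "group", "age", "sex", "bmi", "level", "bmd",
    "asa", "spondylolisthesis", "diabetes", "smoking",
)

CATEGORICAL_BASELINE = ("sex", "diabetes", "smoking", "spondylolisthesis", "asa", "level")
CONTINUOUS_BASELINE = ("age", "bmi", "bmd")


@dataclass
class RunConfig:
    """Knobs of one pipeline run; flags mirror the CLI options."""

    manifest: str | Path | None = None
    output_dir: str | Path = "."
    bias_correction: bool = True
    n_bins: int = 256
    per_side_threshold: bool = False
    continuity_correction: bool = False
    degenerate_policy: str = "all_muscle"  # or "error"
    alpha: float = stats.ALPHA
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.degenerate_policy not in ("all_muscle", "error"):
            raise ValueError(f"unknown degenerate_policy {self.degenerate_policy!r}")


def _setup_run_logging(outdir: Path) -> logging.Handler:
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def quantify_case(sl, roi, config: RunConfig) -> dict:
    """One slice + one mask -> TCSA/FCSA/endplate CSA (mm²) and the threshold."""
    px_area = roi_pixel_area(sl)
    corrected = sl
    if config.bias_correction:
        bias = quant.fit_bias_field(sl, roi)
        corrected = quant.correct_bias(sl, bias)

    def _fcsa_for(labels) -> float:
        vals = corrected.pixels[roi.region(*labels)]
        try:
            thr = quant.otsu_threshold(vals, n_bins=config.n_bins)
        except DegenerateHistogramError:
            if config.degenerate_policy == "error":
                raise
            logger.warning(
                "degenerate ROI histogram for %s/%s: setting FCSA := TCSA",
                sl.patient_id, sl.timepoint,
            )
            return vals.size * px_area
        fat_map = quant.classify_fat_muscle(corrected, roi, thr, labels=labels)
        return quant.compute_fcsa(fat_map, px_area)

    tcsa = quant.compute_tcsa(roi, "bilateral", px_area)
    if config.per_side_threshold:
        fcsa = sum(_fcsa_for((lab,)) for lab in MUSCLE_LABELS)
    else:
        fcsa = _fcsa_for(MUSCLE_LABELS)
    ep = roi.pixel_count(ENDPLATE) * px_area
    return {"tcsa_mm2": tcsa, "fcsa_mm2": fcsa, "endplate_mm2": ep}


def run_quantification(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the per-patient chain over the manifest; write CSVs and a log.

    Returns ``(metrics, deltas)``.  Patients missing a timepoint for a
    rater are skipped with a logged reason.  The endplate CSA from the
    pre-op study is reused at follow-up when the follow-up mask carries no
    endplate label (ΔRCSA is unaffected either way: the normaliser cancels
    inside each fraction).
    """
    outdir = Path(config.output_dir)
    handler = _setup_run_logging(outdir)
    try:
        manifest = pd.read_csv(config.manifest) if config.manifest else pd.DataFrame(columns=MANIFEST_COLUMNS)
        missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns and len(manifest)]
        if missing:
            raise ValueError(f"manifest lacks required columns {missing}")

        metric_rows, delta_rows = [], []
        per_rater: dict[str, dict[str, quant.DeltaRCSA]] = {}
        for (pid, rater), cases in manifest.groupby(["patient_id", "rater"]) if len(manifest) else []:
            tps = dict(zip(cases["timepoint"], cases.to_dict("records")))
            if not {"pre", "followup"} <= set(tps):
                logger.warning("patient %s rater %s: missing timepoint(s) %s; skipped",
                               pid, rater, sorted({"pre", "followup"} - set(tps)))
                continue
            metrics = {}
            endplate_pre = None
            for tp in ("pre", "followup"):
                row = tps[tp]
                sl = read_slice(
                    row["image"], row["image_format"],
                    slice_index=int(row["slice_index"]) if "slice_index" in row and pd.notna(row.get("slice_index")) else None,
                    patient_id=str(pid), timepoint=tp,
                    level=row.get("level") if pd.notna(row.get("level", np.nan)) else None,
                )
                roi = read_mask(row["mask"], sl, rater_id=str(rater))
                areas = quantify_case(sl, roi, config)
                if tp == "pre":
                    endplate_pre = areas["endplate_mm2"]
                ep = areas["endplate_mm2"] if areas["endplate_mm2"] > 0 else endplate_pre
                if not ep or ep <= 0:
                    logger.warning("patient %s rater %s: no endplate label at any timepoint; skipped", pid, rater)
                    break
                metrics[tp] = quant.relative_metrics(
                    areas["tcsa_mm2"], areas["fcsa_mm2"], ep,
                    patient_id=str(pid), timepoint=tp, rater_id=str(rater),
                )
                metric_rows.append({
                    "patient_id": pid, "timepoint": tp, "rater": rater,
                    "level": row.get("level"),
                    "tcsa_mm2": metrics[tp].tcsa, "fcsa_mm2": metrics[tp].fcsa,
                    "endplate_mm2": metrics[tp].endplate_csa,
                    "rtcsa": metrics[tp].rtcsa, "rfcsa": metrics[tp].rfcsa,
                })
            if {"pre", "followup"} <= set(metrics):
                d = quant.delta_rcsa(metrics["pre"], metrics["followup"])
                per_rater.setdefault(str(pid), {})[str(rater)] = d
                delta_rows.append({"patient_id": pid, "rater": rater, "delta_rcsa": d.value,
                                   "pre_fraction": d.pre_fraction, "fu_fraction": d.fu_fraction})
                logger.info("patient %s rater %s: ΔRCSA = %+.4f", pid, rater, d.value)

        for pid, raters in per_rater.items():
            if len(raters) >= 2:
                r1, r2 = list(raters.values())[:2]
                avg = quant.average_raters(r1, r2)
                delta_rows.append({"patient_id": pid, "rater": "average", "delta_rcsa": avg.value,
                                   "pre_fraction": avg.pre_fraction, "fu_fraction": avg.fu_fraction})

        metrics_df = pd.DataFrame(metric_rows, columns=["patient_id", "timepoint", "rater", "level",
                                                        "tcsa_mm2", "fcsa_mm2", "endplate_mm2", "rtcsa", "rfcsa"])
        deltas_df = pd.DataFrame(delta_rows, columns=["patient_id", "rater", "delta_rcsa",
                                                      "pre_fraction", "fu_fraction"])
        if len(manifest) == 0:
            logger.warning("empty manifest: no patients to quantify")
        metrics_df.to_csv(outdir / "metrics.csv", index=False)
        deltas_df.to_csv(outdir / "delta_rcsa.csv", index=False)
        return metrics_df, deltas_df
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# statistics stage


def _encode_regression_design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["group"] = (df["group"] == "TLIF").astype(float)
    X["age"] = df["age"].astype(float)
    X["sex"] = (df["sex"] == "F").astype(float)
    X["bmi"] = df["bmi"].astype(float)
    X["level"] = (df["level"] == "L5S1").astype(float)
    X["bmd"] = df["bmd"].astype(float)
    X["asa"] = df["asa"].astype(float)
    X["spondylolisthesis"] = df["spondylolisthesis"].astype(float)
    X["diabetes"] = df["diabetes"].astype(float)
    X["smoking"] = df["smoking"].astype(float)
    return X


def _group_samples(df: pd.DataFrame, col: str):
    a = df.loc[df["group"] == "EndoLIF", col].dropna().to_numpy(float)
    b = df.loc[df["group"] == "TLIF", col].dropna().to_numpy(float)
    return a, b


def run_statistics(cohort: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Produce the full report bundle for one cohort table.

    Returns a nested dict (JSON-serialisable apart from the pandas frames
    under ``"residual_diagnostics"``); :func:`write_report` persists it.
    """
    config = config or RunConfig()
    if "group" not in cohort.columns or cohort["group"].isna().any():
        raise ValueError("cohort requires a non-missing 'group' column")
    report: dict = {"n": {g: int((cohort["group"] == g).sum()) for g in ("EndoLIF", "TLIF")}}

    baseline = {}
    for col in CATEGORICAL_BASELINE:
        if col not in cohort.columns:
            continue
        table = pd.crosstab(cohort[col], cohort["group"]).to_numpy()
        res = stats.compare_categorical(table, name=col,
                                        continuity_correction=config.continuity_correction)
        baseline[col] = res.to_dict()
    for col in CONTINUOUS_BASELINE:
        if col not in cohort.columns:
            continue
        a, b = _group_samples(cohort, col)
        baseline[col] = stats.compare_continuous(a, b, name=col).to_dict()
    report["baseline"] = baseline

    outcomes = {}
    for col in cohort.columns:
        if col.startswith(("vas_", "odi_", "ck_", "crp_", "esr_")):
            a, b = _group_samples(cohort, col)
            outcomes[col] = stats.compare_continuous(a, b, name=col).to_dict()
    if "avg_delta_rcsa" in cohort.columns:
        a, b = _group_samples(cohort, "avg_delta_rcsa")
        outcomes["avg_delta_rcsa"] = stats.compare_continuous(a, b, name="avg_delta_rcsa").to_dict()
    report["group_comparisons"] = outcomes

    if "avg_delta_rcsa" in cohort.columns and all(
        c in cohort.columns for c in ("age", "sex", "bmi", "level", "bmd", "asa",
                                      "spondylolisthesis", "diabetes", "smoking")
    ):
        sub = cohort.dropna(subset=["avg_delta_rcsa"])
        reg = stats.multivariable_ols(sub["avg_delta_rcsa"].to_numpy(float),
                                      _encode_regression_design(sub))
        report["regression"] = reg.to_dict()
        report["residual_diagnostics"] = reg.residual_diagnostics

    if {"delta_rcsa_rater1", "delta_rcsa_rater2"} <= set(cohort.columns):
        icc_block = {}
        for group in ("EndoLIF", "TLIF"):
            sel = cohort["group"] == group
            ratings = cohort.loc[sel, ["delta_rcsa_rater1", "delta_rcsa_rater2"]].to_numpy(float)
            if len(ratings) >= 5:
                r = stats.icc_a_k(ratings)
                icc_block[group] = {
                    "icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "f_value": r.f_value, "f_df": list(r.f_df), "f_p": r.f_p, "band": r.band,
                }
        report["icc"] = icc_block
    return report


def write_report(report: dict, output_dir: str | Path) -> Path:
    """Persist the bundle: stats.json plus residual-diagnostic CSV."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    diag = report.pop("residual_diagnostics", None)
    if diag is not None:
        diag.to_csv(outdir / "residual_diagnostics.csv", index=False)
    path = outdir / "stats.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    if diag is not None:
        report["residual_diagnostics"] = diag
    return path


def render_report(report: dict) -> str:
    """Human-readable text tables; every number also lives in the JSON."""
    lines = [f"Cohort: {report['n']}"]
    for section in ("baseline", "group_comparisons"):
        if section not in report:
            continue
        lines.append(f"\n== {section} ==")
        for name, res in report[section].items():
            flag = "*" if res["significant"] else ""
            lines.append(
                f"  {name:>20s}  {res['statistic_name']} = {res['statistic']:+.3f}  "
                f"p = {res['p_value']:.4f}{flag}"
            )
    if "regression" in report:
        lines.append("\n== multivariable regression of Average-ΔRCSA ==")
        for row in report["regression"]["coefficients"]:
            if row["name"] == "const":
                continue
            beta = row["effect"]["beta"]
            vif = row["diagnostics"].get("vif", float("nan"))
            flag = "*" if row["significant"] else ""
            lines.append(
                f"  {row['name']:>20s}  beta = {beta:+.3f}  "
                f"[{row['ci_low']:+.3f}, {row['ci_high']:+.3f}]  "
                f"p = {row['p_value']:.4f}{flag}  VIF = {vif:.3f}"
            )
    if "icc" in report:
        lines.append("\n== inter-rater reliability (ICC, absolute agreement, k=2) ==")
        for group, r in report["icc"].items():
            lines.append(
                f"  {group:>10s}  ICC = {r['icc']:.3f} [{r['ci_low']:.3f}, {r['ci_high']:.3f}]  "
                f"F = {r['f_value']:.1f}  band = {r['band']}"
            )
    return "\n".join(lines)
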