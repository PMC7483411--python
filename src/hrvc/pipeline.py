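"""Study orchestration: RR files -> feature table -> study output bundle.

``extract_features`` runs one recording through the full per-subject chain
(preprocess -> time domain -> frequency domain -> DFA -> MSE) and returns
one feature row; ``run_study`` maps it over a cohort and emits the study
tables: covariate comparison (table1), HRV comparison (table2),
univariable + stepwise multivariable logistic regression (table3), the
five adjustment models per retained HRV term (table4), and the
per-parameter ROC ranking, plus a machine-readable run manifest.

Failures are per subject, never global: a recording that cannot complete
a stage yields a row flagged with the failing stage and the study carries
on with the rest, mirroring real Holter quality-control attrition.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import (read_rr_file, filter_nn, select_segment,
                         InsufficientDataError)
from .timedomain import time_domain_metrics
from .freqdomain import SpectralConfig, frequency_domain_metrics
from .dfa import dfa
from .mse import mse_curve, mse_features
from . import diagnostics as dg

__all__ = ["RunConfig", "extract_features", "run_study", "HRV_PARAMS",
           "COVARIATE_COLS"]

#: The 14 HRV parameters of the feature table, in reporting order.
HRV_PARAMS = [
    "mean_rr", "sdrr", "pnn20", "pnn50",
    "vlf", "lf", "hf", "lf_hf_ratio",
    "dfa_alpha1", "dfa_alpha2",
    "mse_slope5", "mse_scale5", "mse_area1_5", "mse_area6_20",
]

COVARIATE_COLS = ["age", "male", "cad", "dm", "htn", "dyslipidemia",
                  "acei_arb", "beta_blocker", "ccb", "glucose_ac",
                  "creatinine"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one study run."""

    input_dir: str = "."
    covariates_csv: str = "subjects.csv"
    output_dir: str = "results"
    seed: int = 0
    # NN filter
    min_ms: float = 300.0
    max_ms: float = 2000.0
    max_rel_jump: float = 0.2
    # segment selection
    window_start: str = "09:00"
    window_end: str = "17:00"
    duration_h: float = 4.0
    step_min: float = 5.0
    # spectral
    resample_hz: float = 4.0
    window_s: float = 300.0
    overlap_frac: float = 0.5
    # DFA
    dfa_short: tuple = (4, 11)
    dfa_long: tuple = (11, 64)
    # MSE
    mse_m: int = 2
    mse_r_frac: float = 0.15
    mse_max_scale: int = 20
    # diagnostics
    p_stay: float = 0.05
    alpha_univariable: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dfa_short", "dfa_long"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dfa_short"] = list(d["dfa_short"])
        d["dfa_long"] = list(d["dfa_long"])
        return d


def extract_features(rr_path, cfg: RunConfig = None) -> dict:
    """One recording -> one feature row (14 HRV parameters + QC fields).

    On a stage failure the row carries ``failure_stage`` and
    ``failure_reason`` and all later fields stay missing.  If the
    recording cannot cover the configured clock window, segmentation
    falls back to the whole recording with ``qc_segment_fallback = 1``.
    """
    cfg = cfg or RunConfig()
    row = {"rr_path": str(rr_path), "failure_stage": "",
           "failure_reason": "", "qc_segment_fallback": 0}
    stage = "read"
    try:
        rr = read_rr_file(rr_path)
        stage = "segment"
        try:
            rr = select_segment(rr, cfg.window_start, cfg.window_end,
                                cfg.duration_h, cfg.step_min,
                                cfg.min_ms, cfg.max_ms, cfg.max_rel_jump)
        except InsufficientDataError:
            row["qc_segment_fallback"] = 1
        stage = "filter"
        nn = filter_nn(rr, cfg.min_ms, cfg.max_ms, cfg.max_rel_jump)
        row["qc_n_beats"] = len(rr)
        row["qc_n_accepted"] = len(nn)
        row["qc_frac_rejected"] = 1.0 - len(nn) / len(rr)
        stage = "timedomain"
        row.update(time_domain_metrics(nn).as_dict())
        stage = "freqdomain"
        scfg = SpectralConfig(resample_hz=cfg.resample_hz,
                              window_s=cfg.window_s,
                              overlap_frac=cfg.overlap_frac)
        row.update(frequency_domain_metrics(nn, scfg).as_dict())
        stage = "dfa"
        d = dfa(nn, short_range=cfg.dfa_short, long_range=cfg.dfa_long)
        row["dfa_alpha1"], row["dfa_alpha2"] = d.alpha1, d.alpha2
        stage = "mse"
        curve = mse_curve(nn, max_scale=cfg.mse_max_scale, m=cfg.mse_m,
                          r_frac=cfg.mse_r_frac)
        row.update(mse_features(curve.entropies))
        row["qc_mse_undefined_scales"] = int(np.isnan(curve.entropies).sum())
    except Exception as exc:
        row["failure_stage"] = stage
        row["failure_reason"] = f"{type(exc).__name__}: {exc}"
    return row


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _comparison_rows(cohort: pd.DataFrame, variables, method="auto") -> pd.DataFrame:
    rows = []
    for v in variables:
        try:
            c = dg.compare_groups(cohort, v, method=method)
        except (dg.DegenerateComparisonError, ValueError, KeyError) as exc:
            rows.append({"variable": v, "method": "failed", "p": np.nan,
                         "note": str(exc)})
            continue
        rows.append({
            "variable": v, "method": c.method,
            "hf_summary": c.summaries.get("HF", ""),
            "control_summary": c.summaries.get("control", ""),
            "statistic": c.statistic, "p": c.p, "note": "",
        })
    return pd.DataFrame(rows)


def _fmt_fit_row(fit, term) -> dict:
    if fit is None or fit.separation or term not in fit.table.index:
        return {"or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "flag": "separation" if fit and fit.separation
                else "failed"}
    r = fit.table.loc[term]
    return {"or": r["or_"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
            "p": r["p"], "flag": ""}


def run_study(cfg: RunConfig) -> dict:
    """Run the full study described by ``cfg``; returns the output paths.

    Writes under ``cfg.output_dir``: features.csv, failures.csv,
    table1.csv (covariates), table2.csv (HRV medians + Mann-Whitney p),
    table3.csv (univariable + stepwise multivariable logistic fits),
    table4.csv (five adjustment models per retained HRV term), roc.csv
    (AUC ranking), roc_curves.csv and manifest.json.  Output bytes are a
    pure function of the inputs, the config and the seed.
    """
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov = pd.read_csv(Path(cfg.covariates_csv))
    if "subject_id" not in cov.columns or "group" not in cov.columns:
        raise ValueError("covariates CSV needs subject_id and group columns")
    input_dir = Path(cfg.input_dir)

    rows = []
    for rec in cov.itertuples(index=False):
        path = input_dir / rec.rr_file
        if not path.exists():
            raise FileNotFoundError(
                f"subject {rec.subject_id}: RR file {path} does not exist")
        row = extract_features(path, cfg)
        row["subject_id"] = rec.subject_id
        rows.append(row)
    _log(f"[extract] {len(rows)} subjects in {time.time() - t0:.1f}s")

    feats = pd.DataFrame(rows).merge(cov, on="subject_id")
    failures = feats[feats["failure_stage"] != ""]
    ok = feats[feats["failure_stage"] == ""]
    for g in ("HF", "control"):
        n_ok = (ok["group"] == g).sum()
        if n_ok < 2:
            report = failures[["subject_id", "failure_stage",
                               "failure_reason"]].to_string(index=False)
            raise RuntimeError(
                f"group {g!r} has {n_ok} usable subjects (< 2); failures:\n"
                + report)

    lead = ["subject_id", "group"]
    feats = feats[lead + [c for c in feats.columns if c not in lead]]
    feats.to_csv(out / "features.csv", index=False)
    failures[["subject_id", "failure_stage", "failure_reason"]].to_csv(
        out / "failures.csv", index=False)

    covariate_cols = [c for c in COVARIATE_COLS if c in ok.columns]
    table1 = _comparison_rows(ok, covariate_cols)
    table1.to_csv(out / "table1.csv", index=False)

    table2 = _comparison_rows(ok, HRV_PARAMS, method="mann-whitney")
    table2.to_csv(out / "table2.csv", index=False)

    # --- logistic layer -----------------------------------------------------
    uni, significant = dg.univariable_screen(ok, HRV_PARAMS,
                                             alpha=cfg.alpha_univariable)
    step = dg.stepwise_select(ok, significant, p_stay=cfg.p_stay)
    retained = step.terms
    t3 = []
    for term in HRV_PARAMS:
        r = {"variable": term}
        r.update({f"uni_{k}": v for k, v in
                  _fmt_fit_row(uni.get(term), term).items()})
        if term in retained:
            r.update({f"multi_{k}": v for k, v in
                      _fmt_fit_row(step, term).items()})
        else:
            r.update({"multi_or": np.nan, "multi_ci_low": np.nan,
                      "multi_ci_high": np.nan, "multi_p": np.nan,
                      "multi_flag": ""})
        r["univariable_significant"] = term in significant
        r["stepwise_retained"] = term in retained
        t3.append(r)
    pd.DataFrame(t3).to_csv(out / "table3.csv", index=False)
    _log(f"[stepwise] retained: {retained}")

    t4 = []
    for term in retained:
        fits = dg.adjusted_models(ok, term)
        for model, fit in fits.items():
            r = {"variable": term, "model": model,
                 "n": fit.n_obs, "n_events": fit.n_events}
            r.update(_fmt_fit_row(fit, term))
            t4.append(r)
    pd.DataFrame(t4).to_csv(out / "table4.csv", index=False)

    roc_rows, curve_rows = [], []
    for term in HRV_PARAMS:
        res = dg.roc_auc(ok.dropna(subset=[term]), term)
        roc_rows.append({"variable": term, "auc_oriented": res.auc_oriented,
                         "auc_raw": res.auc, "orientation": res.orientation,
                         "n": int(ok[term].notna().sum()),
                         "degenerate": res.degenerate})
        for f, t in zip(res.fpr, res.tpr):
            curve_rows.append({"variable": term, "fpr": f, "tpr": t})
    roc = pd.DataFrame(roc_rows).sort_values(
        ["auc_oriented", "variable"], ascending=[False, True])
    roc.to_csv(out / "roc.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(out / "roc_curves.csv", index=False)

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": __version__,
        "n_subjects": int(len(feats)),
        "n_failed": int(len(failures)),
        "stepwise_retained": list(retained),
        "univariable_significant": list(significant),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _log(f"[study] complete in {time.time() - t0:.1f}s -> {out}")
    return {p: str(out / p) for p in
            ("features.csv", "failures.csv", "table1.csv", "table2.csv",
             "table3.csv", "table4.csv", "roc.csv", "roc_curves.csv",
             "manifest.json")}
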