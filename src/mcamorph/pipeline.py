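"""Cohort I/O, analysis orchestration, and report generation.

The pipeline consumes a per-bifurcation cohort CSV (one row per MCA
bifurcation, four group labels), computes every derived quantity per row, and
assembles a machine-readable report with the study's four result tables:

* table 1 — per-group summaries with five pairwise Mann–Whitney comparisons;
* table 2 — predicted optimal vs observed angles, paired Wilcoxon tests;
* table 3 — predicted−observed deviations, between-group comparisons;
* table 4 — univariate screen → selection rule → multivariate logistic model;
* ROC curves with Youden cut-offs for each final multivariate predictor.

Everything in the report is recomputable from the input table and the
configuration alone; reruns on identical inputs produce byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, GroupSpec
from .geometry import (
    DEFAULT_N_CAP,
    DEFAULT_TOL,
    junction_exponent,
    observed_branch_angles,
    radius_from_diameter,
)
from .hemodynamics import volume_flow_rate
from .optimality import optimal_angles
from .stats import (
    fit_logistic,
    mann_whitney_u,
    pearson_correlation_matrix,
    roc_analysis,
    select_model_variables,
    univariate_screen,
    wilcoxon_signed_rank,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "augment_cohort",
    "run_full_analysis",
    "write_report",
    "replicate_markers",
]

log = logging.getLogger(__name__)

GROUP_LABELS = ("An", "nonAn", "R", "L")

#: the five pairwise group contrasts reported in the summary table
PAIRWISE = (
    ("An", "nonAn"),
    ("An", "R"),
    ("An", "L"),
    ("nonAn", "R"),
    ("nonAn", "L"),
)

#: summary-table parameters in display order
TABLE1_PARAMS = (
    "r0", "r1", "r2", "junction_exponent", "tortuosity",
    "p0", "p1", "p2", "asymmetry_ratio", "area_ratio",
    "phi1_obs", "phi2_obs", "alpha_deg", "vm", "vfr", "pi",
)

#: candidate predictors for the case-control screen
DEFAULT_CANDIDATES = (
    "r0", "p0", "junction_exponent", "asymmetry_ratio", "area_ratio",
    "phi1_obs", "phi2_obs", "alpha_deg", "vm", "vfr", "pi",
)

MANDATORY_COLUMNS = (
    "subject_id", "group",
    "alpha_deg", "beta_deg", "gamma_deg", "vps", "ved", "vm",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Statistical thresholds and tolerances for one analysis run."""

    p_enter: float = 0.1
    r_max: float = 0.5
    n_cap: float = DEFAULT_N_CAP
    tol: float = DEFAULT_TOL
    case_group: str = "An"
    control_groups: tuple[str, ...] = ("R", "L")
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["control_groups"] = list(self.control_groups)
        d["candidates"] = list(self.candidates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kw = dict(d)
        if "control_groups" in kw:
            kw["control_groups"] = tuple(kw["control_groups"])
        if "candidates" in kw:
            kw["candidates"] = tuple(kw["candidates"])
        return cls(**kw)


@dataclass
class AnalysisReport:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4_univariate: pd.DataFrame
    table4_multivariate: pd.DataFrame
    roc_summary: pd.DataFrame
    roc_curves: pd.DataFrame
    selection_audit: list[dict]
    annotations: list[str]
    provenance: dict


# ---------------------------------------------------------------------------
# cohort I/O

def _row_errors(row: pd.Series) -> list[str]:
    errs = []
    for c in ("r0", "r1", "r2"):
        if not row[c] > 0:
            errs.append(f"{c} must be positive")
    for c in ("p0", "p1", "p2"):
        if c in row and pd.notna(row[c]) and not row[c] > 0:
            errs.append(f"{c} must be positive")
    for c in ("alpha_deg", "beta_deg", "gamma_deg"):
        if not 0 < row[c] <= 180:
            errs.append(f"{c} outside (0, 180]")
    if not (row["vps"] >= row["vm"] >= row["ved"] > 0):
        errs.append("velocities must satisfy vps >= vm >= ved > 0")
    return errs


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Load and validate a cohort CSV.

    Radii may be given directly (``r0, r1, r2``) or as best-fit diameters
    (``d0, d1, d2``); diameters are halved on load and, when both are
    present, radii win (a >1% mismatch is logged).  Branches are
    canonicalised so ``r1 >= r2``; rows violating the domain invariants are
    rejected with a line-numbered log entry and the rest of the file is kept.
    """
    path = Path(path)
    df = pd.read_csv(path)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    for i in range(3):
        if f"r{i}" not in df.columns and f"d{i}" not in df.columns:
            missing.append(f"r{i}|d{i}")
    if missing:
        raise ValueError(f"cohort CSV is missing mandatory columns: {missing}")

    bad_groups = sorted(set(df["group"].astype(str)) - set(GROUP_LABELS))
    if bad_groups:
        raise ValueError(f"unknown group labels: {bad_groups}")

    for i in range(3):
        r, d = f"r{i}", f"d{i}"
        if r not in df.columns:
            df[r] = df[d].map(lambda x: x / 2.0 if pd.notna(x) else np.nan)
        elif d in df.columns:
            both = df[r].notna() & df[d].notna()
            mismatch = both & ((df[r] - df[d] / 2.0).abs() > 0.01 * df[r].abs())
            for idx in df.index[mismatch]:
                log.warning(
                    "line %d: %s and %s/2 disagree by >1%%; keeping %s",
                    idx + 2, r, d, r,
                )
            df.loc[df[r].isna() & df[d].notna(), r] = df[d] / 2.0

    for c in ("p0", "p1", "p2", "tortuosity", "vfr"):
        if c not in df.columns:
            df[c] = np.nan
    if "side" not in df.columns:
        df["side"] = ""

    keep_rows = []
    for idx, row in df.iterrows():
        errs = _row_errors(row)
        if errs:
            log.warning("line %d rejected: %s", idx + 2, "; ".join(errs))
            continue
        keep_rows.append(idx)
    df = df.loc[keep_rows].reset_index(drop=True)

    swap = df["r2"] > df["r1"]
    if swap.any():
        for idx in df.index[swap]:
            log.warning("line %d: branches swapped to canonical r1 >= r2 order", idx + 2)
        for a, b in (("r1", "r2"), ("beta_deg", "gamma_deg"), ("p1", "p2")):
            df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()

    cols = ["subject_id", "group", "side", "r0", "r1", "r2", "p0", "p1", "p2",
            "alpha_deg", "beta_deg", "gamma_deg", "vps", "ved", "vm",
            "tortuosity", "vfr"]
    data = df[cols]
    prov = {"source": str(path), "n_rows": int(len(data))}
    return CohortTable(data=data, provenance=prov)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.data.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# per-row derivation

def augment_cohort(cohort: CohortTable, config: AnalysisConfig) -> pd.DataFrame:
    """Attach every per-row derived quantity to the cohort table."""
    df = cohort.data.copy()

    phi = [observed_branch_angles(b, g)
           for b, g in zip(df["beta_deg"], df["gamma_deg"])]
    df["phi1_obs"] = [p[0] for p in phi]
    df["phi2_obs"] = [p[1] for p in phi]
    df["asymmetry_ratio"] = (df["r2"] / df["r1"]) ** 2
    df["area_ratio"] = (df["r1"] ** 2 + df["r2"] ** 2) / df["r0"] ** 2

    n_vals, statuses = [], []
    for r0, r1, r2 in zip(df["r0"], df["r1"], df["r2"]):
        n, status = junction_exponent(r0, r1, r2, tol=config.tol, n_cap=config.n_cap)
        # capped exponents are sentinels, not measurements: treated as missing
        n_vals.append(n if status == "ok" else np.nan)
        statuses.append(status)
    df["junction_exponent"] = n_vals
    df["junction_status"] = statuses

    opt_rows = [optimal_angles(r0, r1, r2)
                for r0, r1, r2 in zip(df["r0"], df["r1"], df["r2"])]
    for name in ("phi1_s_deg", "phi2_s_deg", "total_s_deg",
                 "phi1_v_deg", "phi2_v_deg", "total_v_deg"):
        df[name] = [getattr(o, name) for o in opt_rows]
    df["valid_s"] = [o.valid_s for o in opt_rows]
    df["valid_v"] = [o.valid_v for o in opt_rows]

    df["d1_s"] = np.where(df["valid_s"], df["phi1_s_deg"] - df["phi1_obs"], np.nan)
    df["d2_s"] = np.where(df["valid_s"], df["phi2_s_deg"] - df["phi2_obs"], np.nan)
    df["dt_s"] = np.where(df["valid_s"], df["total_s_deg"] - df["alpha_deg"], np.nan)
    df["d1_v"] = np.where(df["valid_v"], df["phi1_v_deg"] - df["phi1_obs"], np.nan)
    df["d2_v"] = np.where(df["valid_v"], df["phi2_v_deg"] - df["phi2_obs"], np.nan)
    df["dt_v"] = np.where(df["valid_v"], df["total_v_deg"] - df["alpha_deg"], np.nan)

    df["pi"] = (df["vps"] - df["ved"]) / df["vm"]
    derived_vfr = [
        volume_flow_rate(vm, p0) if (pd.notna(p0) and p0 > 0 and vm > 0) else np.nan
        for vm, p0 in zip(df["vm"], df["p0"])
    ]
    # a stored volume-flow-rate column (marginal-mode cohorts) wins over the
    # vm*p0 product; measured cohorts normally derive it
    df["vfr"] = df["vfr"].where(df["vfr"].notna(), derived_vfr)
    return df


# ---------------------------------------------------------------------------
# report stages

def _mw_p(x: np.ndarray, y: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        return math.nan
    try:
        return mann_whitney_u(x, y)[1]
    except ValueError:
        return math.nan


def _build_table1(df: pd.DataFrame) -> pd.DataFrame:
    groups = {g: df[df["group"] == g] for g in GROUP_LABELS}
    rows = []
    for param in TABLE1_PARAMS:
        row: dict = {"parameter": param}
        for g, sub in groups.items():
            vals = sub[param].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"mean_{g}"] = vals.mean() if vals.size else math.nan
            row[f"sd_{g}"] = vals.std(ddof=1) if vals.size > 1 else math.nan
            row[f"n_{g}"] = int(vals.size)
        for a, b in PAIRWISE:
            row[f"p_{a}_vs_{b}"] = _mw_p(
                groups[a][param].to_numpy(dtype=float),
                groups[b][param].to_numpy(dtype=float),
            )
        rows.append(row)
    return pd.DataFrame(rows)


_CONTRASTS = (
    # (contrast name, predicted surface col, predicted volume col, observed col)
    ("phi1", "phi1_s_deg", "phi1_v_deg", "phi1_obs"),
    ("phi2", "phi2_s_deg", "phi2_v_deg", "phi2_obs"),
    ("total", "total_s_deg", "total_v_deg", "alpha_deg"),
)

_DEVIATIONS = (
    ("d1_s", "phi1", "surface"),
    ("d2_s", "phi2", "surface"),
    ("dt_s", "total", "surface"),
    ("d1_v", "phi1", "volume"),
    ("d2_v", "phi2", "volume"),
    ("dt_v", "total", "volume"),
)


def _build_table2(df: pd.DataFrame, annotations: list[str]) -> pd.DataFrame:
    rows = []
    for g in GROUP_LABELS:
        sub = df[df["group"] == g]
        for contrast, col_s, col_v, col_obs in _CONTRASTS:
            for family, col_pred in (("surface", col_s), ("volume", col_v)):
                pair = sub[[col_pred, col_obs]].dropna()
                pred = pair[col_pred].to_numpy()
                obs = pair[col_obs].to_numpy()
                if pred.size:
                    try:
                        p = wilcoxon_signed_rank(pred - obs)[1]
                    except ValueError:
                        p = math.nan
                        annotations.append(
                            f"table2 {g}/{contrast}/{family}: degenerate paired test"
                        )
                else:
                    p = math.nan
                    annotations.append(
                        f"table2 {g}/{contrast}/{family}: no feasible rows"
                    )
                rows.append({
                    "group": g,
                    "contrast": contrast,
                    "family": family,
                    "n_pairs": int(pred.size),
                    "predicted_mean": pred.mean() if pred.size else math.nan,
                    "predicted_sd": pred.std(ddof=1) if pred.size > 1 else math.nan,
                    "observed_mean": obs.mean() if obs.size else math.nan,
                    "observed_sd": obs.std(ddof=1) if obs.size > 1 else math.nan,
                    "p_paired": p,
                })
    return pd.DataFrame(rows)


def _build_table3(df: pd.DataFrame) -> pd.DataFrame:
    groups = {g: df[df["group"] == g] for g in GROUP_LABELS}
    rows = []
    for dev_col, contrast, family in _DEVIATIONS:
        row: dict = {"deviation": dev_col, "contrast": contrast, "family": family}
        for g, sub in groups.items():
            vals = sub[dev_col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"mean_{g}"] = vals.mean() if vals.size else math.nan
            row[f"sd_{g}"] = vals.std(ddof=1) if vals.size > 1 else math.nan
            row[f"n_{g}"] = int(vals.size)
        for a, b in PAIRWISE:
            row[f"p_{a}_vs_{b}"] = _mw_p(
                groups[a][dev_col].to_numpy(dtype=float),
                groups[b][dev_col].to_numpy(dtype=float),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_to_row(var: str, fit) -> dict:
    t = fit.terms.loc[var]
    return {
        "variable": var,
        "coef": float(t["coef"]),
        "se": float(t["se"]),
        "odds_ratio": float(t["odds_ratio"]),
        "ci_low": float(t["ci_low"]),
        "ci_high": float(t["ci_high"]),
        "p": float(t["p"]),
        "converged": bool(fit.converged),
        "separation": bool(fit.separation),
        "n_obs": int(fit.n_obs),
    }


def _build_table4_and_roc(
    df: pd.DataFrame, config: AnalysisConfig, annotations: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    use = df[df["group"].isin((config.case_group, *config.control_groups))].copy()
    use["is_case"] = (use["group"] == config.case_group).astype(int)
    outcome = f"{config.case_group} vs {'+'.join(config.control_groups)}"

    screen = univariate_screen(use, "is_case", config.candidates, outcome=outcome)
    uni = pd.DataFrame([_fit_to_row(v, screen[v]) for v in config.candidates])

    corr_r, _ = pearson_correlation_matrix(use, config.candidates)
    retained, audit = select_model_variables(
        screen, corr_r, p_enter=config.p_enter, r_max=config.r_max
    )

    if retained:
        complete = use[["is_case", *retained]].dropna()
        multi_fit = fit_logistic(complete["is_case"], complete[retained],
                                 outcome=outcome)
        multi = pd.DataFrame([_fit_to_row(v, multi_fit) for v in retained])
    else:
        multi = pd.DataFrame(
            columns=["variable", "coef", "se", "odds_ratio", "ci_low", "ci_high",
                     "p", "converged", "separation", "n_obs"]
        )
        annotations.append("table4: no variables retained for the multivariate model")

    roc_rows, curve_frames = [], []
    for var in retained:
        sub = use[["is_case", var]].dropna()
        cases = sub.loc[sub["is_case"] == 1, var].to_numpy()
        controls = sub.loc[sub["is_case"] == 0, var].to_numpy()
        if cases.size == 0 or controls.size == 0:
            annotations.append(f"roc {var}: empty class after missing-data removal")
            continue
        # protective markers (negative univariate slope) are sign-flipped so
        # that higher score always means case-like
        protective = float(screen[var].terms.loc[var, "coef"]) < 0
        sign = -1.0 if protective else 1.0
        res = roc_analysis(sign * cases, sign * controls)
        roc_rows.append({
            "variable": var,
            "auc": res.auc,
            "orientation": "lower_is_case" if protective else "higher_is_case",
            "cutoff": sign * res.cutoff,
            "sensitivity": res.sensitivity_at_cutoff,
            "specificity": res.specificity_at_cutoff,
            "youden_j": res.youden_j,
        })
        curve_frames.append(pd.DataFrame({
            "variable": var,
            "threshold": sign * res.thresholds,
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
        }))

    roc_summary = pd.DataFrame(roc_rows)
    roc_curves = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["variable", "threshold", "sensitivity", "specificity"])
    )
    return uni, multi, roc_summary, roc_curves, audit


def run_full_analysis(
    cohort: CohortTable, config: Optional[AnalysisConfig] = None
) -> AnalysisReport:
    """Full analysis of one cohort; deterministic for fixed input and config."""
    config = config or AnalysisConfig()
    counts = cohort.data["group"].value_counts()
    if (counts >= 3).sum() < 2:
        raise ValueError("need at least two groups with >= 3 rows each")

    annotations: list[str] = []
    df = augment_cohort(cohort, config)

    n_no_sol = int((df["junction_status"] == "no_solution").sum())
    n_capped = int((df["junction_status"] == "capped").sum())
    if n_no_sol or n_capped:
        annotations.append(
            f"junction exponent: {n_no_sol} rows without a positive root and "
            f"{n_capped} capped rows treated as missing"
        )
        log.warning(annotations[-1])
    n_inv_s = int((~df["valid_s"]).sum())
    n_inv_v = int((~df["valid_v"]).sum())
    if n_inv_s or n_inv_v:
        annotations.append(
            f"optimal angles: {n_inv_s} rows infeasible under the surface rules, "
            f"{n_inv_v} under the volume rules (excluded pairwise)"
        )

    table1 = _build_table1(df)
    table2 = _build_table2(df, annotations)
    table3 = _build_table3(df)
    uni, multi, roc_summary, roc_curves, audit = _build_table4_and_roc(
        df, config, annotations
    )

    csv_bytes = cohort.data.to_csv(index=False).encode()
    provenance = {
        "input_hash": hashlib.sha256(csv_bytes).hexdigest(),
        "config": config.to_dict(),
        "cohort": dict(cohort.provenance),
        "package_version": __version__,
    }
    return AnalysisReport(
        table1=table1,
        table2=table2,
        table3=table3,
        table4_univariate=uni,
        table4_multivariate=multi,
        roc_summary=roc_summary,
        roc_curves=roc_curves,
        selection_audit=audit,
        annotations=annotations,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# serialization

def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def report_payload(report: AnalysisReport) -> dict:
    """The full report as a JSON-serialisable dict (no timestamps)."""
    return {
        "table1": _jsonable(report.table1),
        "table2": _jsonable(report.table2),
        "table3": _jsonable(report.table3),
        "table4": {
            "univariate": _jsonable(report.table4_univariate),
            "multivariate": _jsonable(report.table4_multivariate),
        },
        "roc": {
            "summary": _jsonable(report.roc_summary),
            # curves live in roc.csv; the summary is what downstream readers use
        },
        "selection_audit": _jsonable(report.selection_audit),
        "annotations": list(report.annotations),
        "provenance": _jsonable(report.provenance),
    }


def write_report(
    report: AnalysisReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("json", "csv"),
) -> list[Path]:
    """Write report.json plus the four tables and ROC coordinates as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(json.dumps(report_payload(report), indent=2, sort_keys=True))
        written.append(p)
    if "csv" in formats:
        table4 = pd.concat(
            [
                report.table4_univariate.assign(model="univariate"),
                report.table4_multivariate.assign(model="multivariate"),
            ],
            ignore_index=True,
        )
        for name, frame in (
            ("table1", report.table1),
            ("table2", report.table2),
            ("table3", report.table3),
            ("table4", table4),
            ("roc", report.roc_curves),
        ):
            p = out_dir / f"{name}.csv"
            frame.to_csv(p, index=False)
            written.append(p)
    return written


# ---------------------------------------------------------------------------
# replicated marker calibration

def replicate_markers(
    specs: Sequence[GroupSpec],
    n_replicates: int,
    seed: int,
    markers: Sequence[str] = ("alpha", "vfr"),
    or_markers: Sequence[str] = ("alpha",),
    case_group: str = "An",
    control_groups: Sequence[str] = ("R", "L"),
) -> pd.DataFrame:
    """Replicated case-vs-control discrimination under the group specs.

    Each replicate draws the named marker for the case group and the pooled
    control groups from plain normal distributions with the specs' printed
    (mean, SD) — the calibration protocol works on the published marginal
    summaries directly — then computes the empirical AUC (cases score higher)
    and, for ``or_markers``, the univariate logistic odds ratio per raw unit.

    Returns one row per replicate with columns ``auc_<marker>`` and
    ``or_<marker>``.
    """
    by_label = {s.label: s for s in specs}
    case = by_label[case_group]
    controls = [by_label[g] for g in control_groups]
    rng = np.random.default_rng(seed)

    rows = []
    for _ in range(n_replicates):
        rec: dict = {}
        for marker in markers:
            m, s = case.params[marker]
            x_case = rng.normal(m, s, case.n)
            x_ctrl = np.concatenate(
                [rng.normal(*c.params[marker], c.n) for c in controls]
            )
            rec[f"auc_{marker}"] = roc_analysis(x_case, x_ctrl).auc
            if marker in or_markers:
                y = np.concatenate([np.ones(case.n), np.zeros(x_ctrl.size)])
                X = pd.DataFrame({marker: np.concatenate([x_case, x_ctrl])})
                fit = fit_logistic(y, X)
                rec[f"or_{marker}"] = float(fit.terms.loc[marker, "odds_ratio"])
        rows.append(rec)
    return pd.DataFrame(rows)
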