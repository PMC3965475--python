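"""File I/O, pipeline configuration, and the end-to-end pipeline.

All delimited files are comma-separated UTF-8 with mandatory headers,
decimal point "." and missing-value token "NA".
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    CohortTable,
    DATASET1_VARIABLES,
    DATASET2_VARIABLES,
    generate_cohort,
)
from .errors import ConfigError, ConvergenceError, UnfittableProfileError
from .evaluation import report_tables
from .indicators import indicator_matrix
from .kinetics import (
    FitConfig,
    KineticParameters,
    SizeGrid,
    fit_kinetic_parameters,
    steady_state_concentrations,
)
from .risk_model import (
    FeatureSpec,
    SelectionConfig,
    TrainedRiskModel,
    fit_fixed_model,
    full_selection_protocol,
)

logger = logging.getLogger("lipomet")

__all__ = [
    "PipelineConfig",
    "read_cohort",
    "read_profiles",
    "write_cohort_files",
    "fit_profiles",
    "compute_indicators",
    "run_pipeline",
    "BENCHMARK_MODELS",
]

MISSING_TOKEN = "NA"

#: The five benchmark variable lists (fixed, mirroring the published
#: final multivariate models).
BENCHMARK_MODELS: Dict[str, Tuple[str, ...]] = {
    "conventional_no_cholesterol": (
        "age", "sex", "cigarettes_per_day", "bp_medication", "sbp_nurse", "glucose",
    ),
    "conventional": (
        "age", "sex", "cigarettes_per_day", "bp_medication", "sbp_nurse", "glucose",
        "total_cholesterol", "hdl_cholesterol",
    ),
    "ldlc": (
        "age", "sex", "cigarettes_per_day", "bp_medication", "sbp_nurse", "glucose",
        "ldl_cholesterol_nmr",
    ),
    "ldlc_hdlc": (
        "age", "sex", "cigarettes_per_day", "bp_medication", "sbp_nurse", "glucose",
        "ldl_cholesterol_nmr", "hdl_cholesterol",
    ),
    "ldlc_hdlc_indicators": (
        "age", "sex", "cigarettes_per_day", "bp_medication", "sbp_nurse", "glucose",
        "ldl_cholesterol_nmr", "hdl_cholesterol", "vldl_e", "vldl_h",
    ),
}

#: The nested comparisons reported in the DeLong / reclassification tables.
BENCHMARK_COMPARISONS: Tuple[Tuple[str, str], ...] = (
    ("conventional_no_cholesterol", "conventional"),
    ("conventional_no_cholesterol", "ldlc"),
    ("conventional", "ldlc_hdlc"),
    ("conventional", "ldlc_hdlc_indicators"),
    ("ldlc", "ldlc_hdlc"),
    ("ldlc", "ldlc_hdlc_indicators"),
    ("ldlc_hdlc", "ldlc_hdlc_indicators"),
)


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False)
    if df.empty:
        raise ConfigError(f"empty table: {path}")
    return df


def read_cohort(
    path: str | Path,
    required_columns: Sequence[str] | None = None,
    outcome_column: str = "cvd10y",
) -> pd.DataFrame:
    """Read the risk-factor table, keeping complete cases only.

    Rows with any missing required field are excluded and counted in the
    log; duplicated subject ids are an error.
    """
    df = _read_csv(path)
    if required_columns is None:
        required_columns = [
            c for c in DATASET1_VARIABLES + DATASET2_VARIABLES if c in df.columns
        ]
    needed = ["subject_id", *required_columns, outcome_column]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(f"cohort file {path} lacks required column(s): {missing}")
    dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
    if dups:
        raise ConfigError(f"duplicated subject ids: {sorted(set(dups))}")
    complete = df[needed].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.warning(
            "excluded %d of %d subjects with incomplete records", n_excluded, len(df)
        )
    logger.info("cohort: %d subjects retained", int(complete.sum()))
    return df.loc[complete].reset_index(drop=True)


def read_profiles(path: str | Path, grid: SizeGrid) -> pd.DataFrame:
    """Read the subclass-profile table; subjects with any missing
    subclass are excluded with a logged warning."""
    df = _read_csv(path)
    needed = ["subject_id", *grid.subclass_names]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(f"profile file {path} lacks column(s): {missing}")
    complete = df[needed].notna().all(axis=1)
    if (~complete).any():
        logger.warning(
            "excluded %d profiles with missing subclasses", int((~complete).sum())
        )
    return df.loc[complete, needed].reset_index(drop=True)


def write_cohort_files(
    cohort: CohortTable,
    cohort_path: str | Path,
    profile_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write the risk-factor, profile, and (optionally) truth CSVs.  The
    risk-factor file holds observable variables only; generating
    parameters and true indicators go to the truth file."""
    observable = ["subject_id", *DATASET1_VARIABLES, *DATASET2_VARIABLES, "cvd10y"]
    cohort.data[observable].to_csv(cohort_path, index=False, na_rep=MISSING_TOKEN)
    cohort.profiles.to_csv(profile_path, index=False, na_rep=MISSING_TOKEN)
    if truth_path is not None:
        cohort.truth.to_csv(truth_path, index=False, na_rep=MISSING_TOKEN)


def fit_profiles(
    profiles: pd.DataFrame, grid: SizeGrid, config: FitConfig = FitConfig()
) -> pd.DataFrame:
    """Fit canonical kinetic parameters per subject.

    Returns one row per subject: the six canonical parameters, final
    objective, and a convergence flag.  Unfittable or non-convergent
    subjects are retained with converged=False and NA parameters /
    best-effort parameters respectively.
    """
    rows = []
    for _, rec in profiles.iterrows():
        obs = {s: float(rec[s]) for s in grid.subclass_names}
        row: Dict[str, object] = {"subject_id": rec["subject_id"]}
        try:
            params, diag = fit_kinetic_parameters(obs, grid, config)
            row.update(params.as_dict())
            row["objective"] = diag.objective
            row["converged"] = True
        except UnfittableProfileError as exc:
            logger.warning("subject %s unfittable: %s", rec["subject_id"], exc)
            row.update({k: np.nan for k in
                        ("f_prod_total", "prod_mu", "prod_sigma", "k_lpl",
                         "k_hl", "k_att", "k_upt")})
            row["objective"] = np.nan
            row["converged"] = False
        except ConvergenceError as exc:
            logger.warning("subject %s did not converge", rec["subject_id"])
            row.update(exc.parameters.as_dict())
            row["objective"] = exc.diagnostics.objective
            row["converged"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def compute_indicators(fitted: pd.DataFrame, grid: SizeGrid) -> pd.DataFrame:
    """Indicator matrix per subject from fitted canonical parameters.
    Subjects without converged fits get all-NA indicator rows."""
    rows = []
    for _, rec in fitted.iterrows():
        row: Dict[str, object] = {"subject_id": rec["subject_id"]}
        if bool(rec.get("converged", True)) and np.isfinite(rec["k_lpl"]):
            params = KineticParameters(
                f_prod_total=float(rec["f_prod_total"]),
                prod_mu=float(rec["prod_mu"]),
                prod_sigma=float(rec["prod_sigma"]),
                k_lpl=float(rec["k_lpl"]),
                k_hl=float(rec["k_hl"]),
                k_att=float(rec["k_att"]),
                k_upt=float(rec["k_upt"]),
            )
            row.update(indicator_matrix(params, grid=grid).as_row())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (YAML-serializable)."""

    out_dir: str = "lipomet_out"
    seed: int = 0
    simulate: bool = True
    n_subjects: int = 400
    noise_cv: float = 0.08
    cohort_path: Optional[str] = None
    profile_path: Optional[str] = None
    fit_n_starts: int = 10
    selection_delta: float = 0.005
    selection_test_fraction: float = 1.0 / 3.0
    n_folds: int = 10
    cutoffs: Tuple[float, float] = (0.06, 0.20)
    run_selection_protocol: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(raw["cutoffs"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cutoffs"] = list(self.cutoffs)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Simulate (optional) -> fit profiles -> compute indicators -> join
    -> selection protocol + benchmark models -> evaluation reports.

    Returns a dict with the cohort, fitted parameters, indicators, models
    and report tables; writes all files under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = SizeGrid.default()

    if config.simulate:
        cc = CohortConfig(
            n_subjects=config.n_subjects, seed=config.seed, noise_cv=config.noise_cv
        )
        cohort_table = generate_cohort(cc, grid)
        write_cohort_files(
            cohort_table,
            out / "cohort.csv",
            out / "profiles.csv",
            out / "truth.csv",
        )
        cohort_path = out / "cohort.csv"
        profile_path = out / "profiles.csv"
    else:
        if not config.cohort_path or not config.profile_path:
            raise ConfigError("cohort_path and profile_path required when simulate=false")
        cohort_path = Path(config.cohort_path)
        profile_path = Path(config.profile_path)
        for p in (cohort_path, profile_path):
            if not p.exists():
                raise FileNotFoundError(f"input file not found: {p}")

    logger.info("stage fit: %s", profile_path)
    profiles = read_profiles(profile_path, grid)
    fitted = fit_profiles(profiles, grid, FitConfig(n_starts=config.fit_n_starts,
                                                    seed=config.seed))
    fitted.to_csv(out / "fitted_parameters.csv", index=False, na_rep=MISSING_TOKEN)

    logger.info("stage indicators")
    indicators = compute_indicators(fitted, grid)
    indicators.to_csv(out / "indicators.csv", index=False, na_rep=MISSING_TOKEN)

    logger.info("stage join")
    cohort = read_cohort(cohort_path)
    joined = cohort.merge(
        indicators[["subject_id", "vldl_e", "vldl_h"]], on="subject_id", how="inner"
    )
    joined = joined.dropna(subset=["vldl_e", "vldl_h"]).reset_index(drop=True)

    sel_config = SelectionConfig(
        test_fraction=config.selection_test_fraction,
        delta=config.selection_delta,
        n_folds=config.n_folds,
        seed=config.seed,
    )

    models: Dict[str, np.ndarray] = {}
    trained: Dict[str, TrainedRiskModel] = {}
    for name, features in BENCHMARK_MODELS.items():
        logger.info("stage models: %s", name)
        tm = fit_fixed_model(joined, features, sel_config)
        trained[name] = tm
        models[name] = tm.cv_probabilities

    selected_model = None
    if config.run_selection_protocol:
        logger.info("stage selection protocol")
        selected_model = full_selection_protocol(joined, FeatureSpec(), sel_config)
        models["forward_selected"] = selected_model.cv_probabilities
        trained["forward_selected"] = selected_model

    logger.info("stage evaluation")
    y = joined["cvd10y"].to_numpy(int)
    tables = report_tables(
        models,
        y,
        baseline="conventional_no_cholesterol",
        comparisons=list(BENCHMARK_COMPARISONS),
        cutoffs=config.cutoffs,
        out_dir=out,
    )

    # prediction output for the headline model
    headline = trained.get("forward_selected", trained["ldlc_hdlc_indicators"])
    pred = pd.DataFrame(
        {
            "subject_id": joined["subject_id"],
            "probability": headline.cv_probabilities,
            "risk_class": np.array(["low", "medium", "high"])[
                headline.risk_class(cutoffs=config.cutoffs)
            ],
        }
    )
    pred.to_csv(out / "predictions.csv", index=False, na_rep=MISSING_TOKEN)
    _write_model_summary(trained, out / "models.yaml")
    return {
        "cohort": joined,
        "fitted": fitted,
        "indicators": indicators,
        "models": trained,
        "tables": tables,
    }


def _write_model_summary(trained: Dict[str, TrainedRiskModel], path: Path) -> None:
    doc = {}
    for name, tm in trained.items():
        doc[name] = {
            "features": list(tm.features),
            "svm_c": tm.svm_c,
            "gamma": tm.gamma,
            "platt": {"a": tm.platt.a, "b": tm.platt.b},
            "cv_auc": tm.cv_auc,
            "seed": tm.seed,
            "audit_trail": [
                {"stage": s, "feature": f, "auc": (None if np.isnan(a) else float(a))}
                for s, f, a in tm.audit_trail
            ],
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
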