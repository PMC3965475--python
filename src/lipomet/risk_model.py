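"""SVM risk score with Platt calibration and grouped forward selection.

The risk model is an L2-regularized soft-margin support vector machine
with a Gaussian kernel on standardized features.  Variables enter through
a three-stage grouped forward-selection protocol:

* stage 1 - age and sex are forced in, then classical (non-cholesterol)
  risk variables are added one at a time, each round keeping the
  candidate that maximizes test-split AUC, until six variables are
  included;
* stage 2 - two cholesterol markers are added the same way;
* stage 3 - metabolism indicators are added while (i) the AUC gain is at
  least ``delta`` and (ii) the candidate has r^2 < 0.25 with every
  variable already included (on the training split).

Selection uses a stratified train/test split; the final model's
predictions are produced by stratified k-fold cross-validation on the
complete dataset, with Platt-calibrated probabilities fitted per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .cohort import DATASET1_VARIABLES, DATASET2_VARIABLES
from .errors import ConfigError

__all__ = [
    "FeatureSpec",
    "SelectionConfig",
    "TrainedRiskModel",
    "PlattCalibrator",
    "train_svm",
    "platt_calibrate",
    "forward_select",
    "full_selection_protocol",
    "cross_validated_probabilities",
    "roc_auc_score_simple",
]


@dataclass(frozen=True)
class FeatureSpec:
    """The three predictor groups and the forced variables."""

    dataset1_names: Tuple[str, ...] = DATASET1_VARIABLES
    dataset2_names: Tuple[str, ...] = DATASET2_VARIABLES
    dataset3_names: Tuple[str, ...] = ("vldl_e", "vldl_h")
    forced_names: Tuple[str, ...] = ("age", "sex")

    def __post_init__(self):
        s1, s2, s3 = (
            set(self.dataset1_names),
            set(self.dataset2_names),
            set(self.dataset3_names),
        )
        if s1 & s2 or s1 & s3 or s2 & s3:
            raise ConfigError("the three datasets must be disjoint")
        if not set(self.forced_names) <= s1:
            raise ConfigError("forced names must belong to dataset 1")

    @property
    def all_names(self) -> Tuple[str, ...]:
        return self.dataset1_names + self.dataset2_names + self.dataset3_names


@dataclass(frozen=True)
class SelectionConfig:
    """Protocol settings: split, improvement threshold, folds, SVM grid."""

    test_fraction: float = 1.0 / 3.0  # stratified 2:1 train:test
    delta: float = 0.005  # minimum AUC gain in stage 3
    n_dataset1: int = 6
    n_dataset2: int = 2
    r2_screen: float = 0.25
    n_folds: int = 10
    seed: int = 0
    c_grid: Tuple[float, ...] = (0.5, 2.0, 8.0)
    #: RBF bandwidth grid, in multiples of 1/n_features (small values give
    #: a near-linear kernel, which the rare-event setting favours)
    gamma_grid: Tuple[float, ...] = (0.01, 0.03, 0.1, 0.3)
    svm_c: Optional[float] = None  # fixed C; None -> tuned per stage
    svm_gamma_mult: Optional[float] = None  # fixed gamma multiple; None -> tuned


def roc_auc_score_simple(y: np.ndarray, score: np.ndarray) -> float:
    """AUC by the rank statistic with ties counted 1/2 (midranks)."""
    y = np.asarray(y)
    score = np.asarray(score, float)
    pos = score[y == 1]
    neg = score[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = pd.Series(np.concatenate([pos, neg])).rank().to_numpy()
    return (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size
    )


# ---------------------------------------------------------------------------
# SVM


@dataclass
class _Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        sd = X.std(axis=0, ddof=0)
        return cls(mean=X.mean(axis=0), sd=np.where(sd > 0, sd, 1.0))

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    c: float = 2.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> SVC:
    """Fit the Gaussian-kernel soft-margin SVM on standardized features.

    Class weights are balanced to cope with the rare-event outcome.
    Deterministic given inputs (libsvm's solver is deterministic; the seed
    is stored for bookkeeping only).
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    bad = np.nonzero(~np.isfinite(X).all(axis=0))[0]
    if bad.size:
        raise ValueError(f"non-finite values in feature column(s) {bad.tolist()}")
    model = SVC(
        C=c, kernel="rbf", gamma=gamma, class_weight="balanced",
        random_state=seed,
    )
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# Platt calibration


@dataclass(frozen=True)
class PlattCalibrator:
    """Sigmoid map p = 1 / (1 + exp(a*f + b)) from decision values to
    probabilities (a < 0 when higher decision values mean higher risk)."""

    a: float
    b: float

    def __call__(self, decision: np.ndarray) -> np.ndarray:
        return expit(-(self.a * np.asarray(decision, float) + self.b))


def platt_calibrate(decision: np.ndarray, labels: np.ndarray) -> PlattCalibrator:
    """Fit the sigmoid by regularized maximum likelihood with Platt's
    target smoothing: positives get target (N+ + 1)/(N+ + 2), negatives
    1/(N- + 2).  Strictly monotone; raises on constant decision values or
    single-class labels.
    """
    f = np.asarray(decision, float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for calibration")
    if np.ptp(f) == 0:
        raise ValueError("decision values are constant; cannot calibrate")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab: np.ndarray) -> float:
        z = ab[0] * f + ab[1]
        # cross-entropy with p = sigmoid(-z), numerically stable:
        # -LL = sum t*z + log(1 + exp(-z))
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="BFGS")
    a, b = res.x
    if a == 0.0:
        raise ValueError("degenerate calibration (flat sigmoid)")
    return PlattCalibrator(a=float(a), b=float(b))


# ---------------------------------------------------------------------------
# forward selection


def _fit_score(
    df: pd.DataFrame,
    features: Sequence[str],
    y_col: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    c: float,
    seed: int,
    gamma_mult: float = 0.05,
) -> float:
    X = df.loc[:, list(features)].to_numpy(float)
    y = df[y_col].to_numpy(int)
    std = _Standardizer.fit(X[train_idx])
    gamma = gamma_mult / X.shape[1]
    model = train_svm(std(X[train_idx]), y[train_idx], c=c, gamma=gamma, seed=seed)
    return roc_auc_score_simple(y[test_idx], model.decision_function(std(X[test_idx])))


def forward_select(
    df: pd.DataFrame,
    candidates: Sequence[str],
    included: Sequence[str],
    y_col: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    delta: float = 0.0,
    current_auc: float | None = None,
    c: float = 2.0,
    seed: int = 0,
    gamma_mult: float = 0.05,
) -> Tuple[Optional[str], float]:
    """One forward-selection round: return (best candidate, its AUC), or
    (None, current_auc) when no candidate improves by at least ``delta``.
    Ties are broken by candidate name order."""
    overlap = set(candidates) & set(included)
    if overlap:
        raise ConfigError(f"candidates overlap included features: {sorted(overlap)}")
    if not candidates:
        return None, current_auc if current_auc is not None else float("nan")
    if current_auc is None:
        current_auc = (
            _fit_score(df, included, y_col, train_idx, test_idx, c, seed, gamma_mult)
            if included
            else 0.5
        )
    best_name, best_auc = None, -np.inf
    for name in sorted(candidates):
        auc = _fit_score(df, list(included) + [name], y_col, train_idx, test_idx,
                         c, seed, gamma_mult)
        if auc > best_auc:
            best_name, best_auc = name, auc
    if best_auc >= current_auc + delta and best_name is not None:
        return best_name, best_auc
    return None, current_auc


# ---------------------------------------------------------------------------
# full protocol


@dataclass
class TrainedRiskModel:
    """Result of the selection protocol.

    ``audit_trail`` records (stage, feature, test AUC after inclusion) for
    every accepted step; ``cv_probabilities`` are the Platt-calibrated
    cross-validated probabilities on the complete dataset.
    """

    features: List[str]
    svm_c: float
    gamma: str | float
    platt: PlattCalibrator
    audit_trail: List[Tuple[str, str, float]]
    cv_probabilities: np.ndarray
    cv_auc: float
    seed: int
    selection_test_auc: float

    def risk_class(self, probabilities: np.ndarray | None = None,
                   cutoffs: Tuple[float, float] = (0.06, 0.20)) -> np.ndarray:
        p = self.cv_probabilities if probabilities is None else probabilities
        return np.digitize(p, cutoffs)  # 0 low, 1 medium, 2 high


def cross_validated_probabilities(
    df: pd.DataFrame,
    features: Sequence[str],
    y_col: str = "cvd10y",
    n_folds: int = 10,
    c: float = 2.0,
    seed: int = 0,
    gamma_mult: float = 0.05,
) -> np.ndarray:
    """Platt-calibrated out-of-fold probabilities from stratified k-fold
    cross-validation (calibrator fitted on each fold's training part)."""
    X = df.loc[:, list(features)].to_numpy(float)
    y = df[y_col].to_numpy(int)
    gamma = gamma_mult / X.shape[1]
    probs = np.empty(len(df))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        std = _Standardizer.fit(X[train_idx])
        model = train_svm(std(X[train_idx]), y[train_idx], c=c, gamma=gamma, seed=seed)
        platt = platt_calibrate(model.decision_function(std(X[train_idx])), y[train_idx])
        probs[test_idx] = platt(model.decision_function(std(X[test_idx])))
    return probs


def _r2(x: np.ndarray, z: np.ndarray) -> float:
    sx, sz = x.std(), z.std()
    if sx == 0 or sz == 0:
        return 0.0
    r = np.corrcoef(x, z)[0, 1]
    return float(r * r)


def full_selection_protocol(
    cohort: pd.DataFrame,
    spec: FeatureSpec = FeatureSpec(),
    config: SelectionConfig = SelectionConfig(),
    y_col: str = "cvd10y",
) -> TrainedRiskModel:
    """Run the three-stage grouped forward-selection protocol and return
    the final cross-validated model.

    The cohort must be complete-case on all spec variables (rows with
    missing values in any used column raise)."""
    if len(spec.dataset1_names) < config.n_dataset1:
        raise ConfigError(
            f"need at least {config.n_dataset1} dataset-1 candidates, "
            f"got {len(spec.dataset1_names)}"
        )
    used = [c for c in spec.all_names if c in cohort.columns] + [y_col]
    missing_cols = set(spec.all_names) - set(cohort.columns)
    if missing_cols:
        raise ConfigError(f"cohort lacks columns: {sorted(missing_cols)}")
    if cohort[used].isna().any().any():
        raise ConfigError("cohort is not complete-case on the spec variables")

    df = cohort.reset_index(drop=True)
    y = df[y_col].to_numpy(int)
    idx = np.arange(len(df))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )

    included: List[str] = list(spec.forced_names)
    audit: List[Tuple[str, str, float]] = []

    def tune(features: List[str]) -> Tuple[float, float]:
        """Grid-search (C, gamma multiple) on the selection split for the
        current included set; fixed values in the config short-circuit."""
        if config.svm_c is not None and config.svm_gamma_mult is not None:
            c, g = float(config.svm_c), float(config.svm_gamma_mult)
            return c, g, _fit_score(df, features, y_col, train_idx, test_idx,
                                    c, config.seed, g)
        c_grid = config.c_grid if config.svm_c is None else (config.svm_c,)
        g_grid = (
            config.gamma_grid if config.svm_gamma_mult is None
            else (config.svm_gamma_mult,)
        )
        best = (-np.inf, None, None)
        for c in c_grid:
            for g in g_grid:
                auc = _fit_score(df, features, y_col, train_idx, test_idx,
                                 c, config.seed, g)
                if auc > best[0]:
                    best = (auc, float(c), float(g))
        return best[1], best[2], best[0]

    # hyperparameters are retuned at the start of each stage on the current
    # included set and held fixed within the stage (grid logged in audit)
    svm_c, gamma_mult, current = tune(included)
    audit.append(("tune_stage1", f"C={svm_c},gamma_mult={gamma_mult}", current))
    for name in included:
        audit.append(("stage1_forced", name, current))

    # stage 1: classical risk variables up to n_dataset1 (fixed count)
    candidates = [n for n in spec.dataset1_names if n not in included]
    while len(included) < config.n_dataset1 and candidates:
        name, auc = forward_select(
            df, candidates, included, y_col, train_idx, test_idx,
            delta=-np.inf, current_auc=current, c=svm_c, seed=config.seed,
            gamma_mult=gamma_mult,
        )
        included.append(name)
        candidates.remove(name)
        current = auc
        audit.append(("stage1", name, auc))

    # stage 2: cholesterol markers, fixed count
    svm_c, gamma_mult, current = tune(included)
    audit.append(("tune_stage2", f"C={svm_c},gamma_mult={gamma_mult}", current))
    candidates = list(spec.dataset2_names)
    for _ in range(config.n_dataset2):
        if not candidates:
            break
        name, auc = forward_select(
            df, candidates, included, y_col, train_idx, test_idx,
            delta=-np.inf, current_auc=current, c=svm_c, seed=config.seed,
            gamma_mult=gamma_mult,
        )
        included.append(name)
        candidates.remove(name)
        current = auc
        audit.append(("stage2", name, auc))

    # stage 3: metabolism indicators, delta-gated + r^2 screen
    svm_c, gamma_mult, current = tune(included)
    audit.append(("tune_stage3", f"C={svm_c},gamma_mult={gamma_mult}", current))
    candidates = list(spec.dataset3_names)
    while candidates:
        screened = [
            cand
            for cand in candidates
            if all(
                _r2(
                    df.loc[train_idx, cand].to_numpy(float),
                    df.loc[train_idx, inc].to_numpy(float),
                )
                < config.r2_screen
                for inc in included
            )
        ]
        if not screened:
            break
        name, auc = forward_select(
            df, screened, included, y_col, train_idx, test_idx,
            delta=config.delta, current_auc=current, c=svm_c, seed=config.seed,
            gamma_mult=gamma_mult,
        )
        if name is None:
            break
        included.append(name)
        candidates.remove(name)
        current = auc
        audit.append(("stage3", name, auc))

    # final model: cross-validated predictions on the complete dataset
    cv_probs = cross_validated_probabilities(
        df, included, y_col, n_folds=config.n_folds, c=svm_c, seed=config.seed,
        gamma_mult=gamma_mult,
    )
    cv_auc = roc_auc_score_simple(y, cv_probs)

    # full-data fit for the stored calibrator
    X = df.loc[:, included].to_numpy(float)
    std = _Standardizer.fit(X)
    final = train_svm(std(X), y, c=svm_c, gamma=gamma_mult / X.shape[1],
                      seed=config.seed)
    platt = platt_calibrate(final.decision_function(std(X)), y)

    return TrainedRiskModel(
        features=included,
        svm_c=svm_c,
        gamma=gamma_mult,
        platt=platt,
        audit_trail=audit,
        cv_probabilities=cv_probs,
        cv_auc=float(cv_auc),
        seed=config.seed,
        selection_test_auc=float(current),
    )


def fit_fixed_model(
    cohort: pd.DataFrame,
    features: Sequence[str],
    config: SelectionConfig = SelectionConfig(),
    y_col: str = "cvd10y",
) -> TrainedRiskModel:
    """Cross-validate a model with a fixed variable list (the benchmark
    models: conventional with/without cholesterol, LDLc, LDLc+HDLc, and
    the indicator-augmented model)."""
    df = cohort.reset_index(drop=True)
    if df[list(features)].isna().any().any():
        raise ConfigError("cohort is not complete-case on the model variables")
    y = df[y_col].to_numpy(int)
    svm_c = float(config.svm_c) if config.svm_c is not None else 2.0
    gamma_mult = (
        float(config.svm_gamma_mult) if config.svm_gamma_mult is not None else 0.05
    )
    cv_probs = cross_validated_probabilities(
        df, features, y_col, n_folds=config.n_folds, c=svm_c, seed=config.seed,
        gamma_mult=gamma_mult,
    )
    X = df.loc[:, list(features)].to_numpy(float)
    std = _Standardizer.fit(X)
    final = train_svm(std(X), y, c=svm_c, gamma=gamma_mult / X.shape[1],
                      seed=config.seed)
    platt = platt_calibrate(final.decision_function(std(X)), y)
    return TrainedRiskModel(
        features=list(features),
        svm_c=svm_c,
        gamma=gamma_mult,
        platt=platt,
        audit_trail=[("fixed", f, float("nan")) for f in features],
        cv_probabilities=cv_probs,
        cv_auc=float(roc_auc_score_simple(y, cv_probs)),
        seed=config.seed,
        selection_test_auc=float("nan"),
    )
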