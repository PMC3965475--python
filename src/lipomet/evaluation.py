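"""Discrimination and reclassification statistics for nested risk models.

Implements the comparison toolkit for cross-validated risk models:

* AUC with the DeLong structural-component standard error;
* the DeLong test for two correlated AUCs on the same subjects (plus the
  plain z-test from an externally supplied difference and SE, and an
  exact binomial sign test on discordant concordance pairs);
* Net Reclassification Improvement (NRI) over the low / medium / high
  risk classes cut at 6% and 20%, with event / non-event components and
  asymptotic z-tests;
* Integrated Discrimination Improvement (IDI), absolute and relative to
  model 1's discrimination slope;
* the intermediate-risk subgroup reclassification analysis; and
* report tables mirroring the published AUC / DeLong / reclassification /
  intermediate-risk table layouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest, norm

__all__ = [
    "RocResult",
    "NriResult",
    "IdiResult",
    "roc_auc",
    "delong_compare",
    "z_test_from_delta",
    "binomial_exact_compare",
    "nri",
    "idi",
    "intermediate_risk_reclassification",
    "report_tables",
    "percent_incremental_improvement",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS: Tuple[float, float] = (0.06, 0.20)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


# ---------------------------------------------------------------------------
# AUC and DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return pd.Series(x).rank().to_numpy()


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (per event) and V01 (per non-event)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


@dataclass(frozen=True)
class RocResult:
    """AUC with DeLong SE; ``improvement`` is AUC - 0.5 and
    ``percent_incremental`` the improvement relative to a named baseline
    (populated by :func:`report_tables`)."""

    auc: float
    se: float
    improvement: float
    percent_incremental: Optional[float] = None

    def __post_init__(self):
        assert abs(self.improvement - (self.auc - 0.5)) < 1e-12


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> RocResult:
    """AUC by pairwise concordance (ties count 1/2) with the DeLong
    structural-component variance."""
    y = _check_labels(labels)
    scores = np.asarray(probabilities, float)
    auc, v10, v01 = _delong_components(scores, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    return RocResult(auc=float(auc), se=float(np.sqrt(var)),
                     improvement=float(auc - 0.5))


def z_test_from_delta(delta: float, se: float) -> Tuple[float, float]:
    """Two-sided standard-normal test from an externally supplied
    (AUC difference, SE) pair."""
    z = delta / se
    return float(z), float(2.0 * norm.sf(abs(z)))


def delong_compare(
    probabilities_1: np.ndarray,
    probabilities_2: np.ndarray,
    labels: np.ndarray,
) -> Dict[str, float]:
    """DeLong comparison of two correlated AUCs measured on the same
    subjects.  Returns delta_auc (model 2 - model 1), its SE, z and the
    two-sided p-value."""
    p1 = np.asarray(probabilities_1, float)
    p2 = np.asarray(probabilities_2, float)
    if p1.shape != p2.shape:
        raise ValueError("both models must score the same subjects")
    y = _check_labels(labels)
    auc1, v10_1, v01_1 = _delong_components(p1, y)
    auc2, v10_2, v01_2 = _delong_components(p2, y)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = float(auc2 - auc1)
    if var <= 0:
        se, z, p = 0.0, 0.0, 1.0
        if delta != 0:
            raise ValueError("zero variance with nonzero AUC difference")
    else:
        se = float(np.sqrt(var))
        z, p = z_test_from_delta(delta, se)
    return {
        "auc1": float(auc1), "auc2": float(auc2), "delta_auc": delta,
        "se": se, "z": float(z), "p_value": float(p),
    }


def binomial_exact_compare(
    probabilities_1: np.ndarray,
    probabilities_2: np.ndarray,
    labels: np.ndarray,
) -> Dict[str, float]:
    """Exact binomial sign test on discordant concordance pairs: among
    event/non-event pairs ranked correctly by exactly one model, is the
    split compatible with 1/2?"""
    y = _check_labels(labels)
    p1 = np.asarray(probabilities_1, float)
    p2 = np.asarray(probabilities_2, float)
    pos = y == 1
    d1 = p1[pos][:, None] > p1[~pos][None, :]
    d2 = p2[pos][:, None] > p2[~pos][None, :]
    only2 = int(np.sum(d2 & ~d1))
    only1 = int(np.sum(d1 & ~d2))
    n_disc = only1 + only2
    if n_disc == 0:
        return {"n_discordant": 0, "wins_model2": 0, "p_value": 1.0}
    p = binomtest(only2, n_disc, 0.5).pvalue
    return {"n_discordant": n_disc, "wins_model2": only2, "p_value": float(p)}


# ---------------------------------------------------------------------------
# reclassification


def risk_classes(
    probabilities: np.ndarray, cutoffs: Tuple[float, float] = DEFAULT_CUTOFFS
) -> np.ndarray:
    """0 = low [0, c1), 1 = medium [c1, c2), 2 = high [c2, 1]."""
    c1, c2 = cutoffs
    if not (0 < c1 < c2 < 1):
        raise ValueError("cutoffs must be strictly increasing within (0,1)")
    return np.digitize(np.asarray(probabilities, float), [c1, c2])


@dataclass(frozen=True)
class NriResult:
    """NRI with event / non-event components.

    Components are net proportions (up-down for events, down-up for
    non-events); ``nri = event_component + nonevent_component`` exactly.
    ``n_events``/``n_nonevents`` of 0 marks an empty subgroup."""

    nri: float
    se: float
    p_value: float
    event_component: float
    event_p_value: float
    nonevent_component: float
    nonevent_p_value: float
    n_events: int
    n_nonevents: int

    @property
    def empty(self) -> bool:
        return self.n_events == 0 and self.n_nonevents == 0


def _component(up: int, down: int, n: int) -> Tuple[float, float, float]:
    """Net proportion, its SE, and two-sided p for one outcome group."""
    if n == 0:
        return 0.0, 0.0, 1.0
    p_up = up / n
    p_down = down / n
    comp = p_up - p_down
    var = (p_up + p_down) / n - comp**2 / n
    if var <= 0:
        return comp, 0.0, 1.0 if comp == 0 else 0.0
    se = math.sqrt(var)
    z = comp / se
    return comp, se, float(2.0 * norm.sf(abs(z)))


def nri(
    p1: np.ndarray,
    p2: np.ndarray,
    labels: np.ndarray,
    cutoffs: Tuple[float, float] = DEFAULT_CUTOFFS,
    allow_empty: bool = False,
) -> NriResult:
    """Net Reclassification Improvement over the risk classes cut at
    ``cutoffs``.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) -
    P(up|non-event)], with the asymptotic group-wise SEs and z-tests.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    y = np.asarray(labels).astype(int)
    if not allow_empty:
        _check_labels(y)
    cls1 = risk_classes(p1, cutoffs)
    cls2 = risk_classes(p2, cutoffs)
    move = np.sign(cls2 - cls1)
    ev = y == 1
    n_e = int(ev.sum())
    n_ne = int((~ev).sum())
    up_e = int(np.sum(move[ev] > 0))
    down_e = int(np.sum(move[ev] < 0))
    up_ne = int(np.sum(move[~ev] > 0))
    down_ne = int(np.sum(move[~ev] < 0))
    comp_e, se_e, p_e = _component(up_e, down_e, n_e)
    comp_ne, se_ne, p_ne = _component(down_ne, up_ne, n_ne)
    total = comp_e + comp_ne
    se = math.sqrt(se_e**2 + se_ne**2)
    if se > 0:
        p_val = float(2.0 * norm.sf(abs(total / se)))
    else:
        p_val = 1.0 if total == 0 else 0.0
    return NriResult(
        nri=total, se=se, p_value=p_val,
        event_component=comp_e, event_p_value=p_e,
        nonevent_component=comp_ne, nonevent_p_value=p_ne,
        n_events=n_e, n_nonevents=n_ne,
    )


@dataclass(frozen=True)
class IdiResult:
    """Integrated Discrimination Improvement.

    ``idi = delta_mean_events - delta_mean_nonevents``;
    ``relative_idi = idi / discrimination slope of model 1`` where the
    discrimination slope is mean p(events) - mean p(non-events)."""

    idi: float
    se: float
    p_value: float
    delta_mean_events: float
    delta_mean_nonevents: float
    relative_idi: float
    discrimination_slope_1: float
    discrimination_slope_2: float


def idi(p1: np.ndarray, p2: np.ndarray, labels: np.ndarray) -> IdiResult:
    """IDI with the asymptotic SE from the two groups' paired-difference
    variances."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    y = _check_labels(labels)
    ev = y == 1
    d = p2 - p1
    d_e = d[ev]
    d_ne = d[~ev]
    idi_val = float(d_e.mean() - d_ne.mean())
    var = (d_e.var(ddof=1) / d_e.size if d_e.size > 1 else 0.0) + (
        d_ne.var(ddof=1) / d_ne.size if d_ne.size > 1 else 0.0
    )
    se = float(np.sqrt(var))
    if se > 0:
        p_val = float(2.0 * norm.sf(abs(idi_val / se)))
    else:
        p_val = 1.0 if idi_val == 0 else 0.0
    slope1 = float(p1[ev].mean() - p1[~ev].mean())
    slope2 = float(p2[ev].mean() - p2[~ev].mean())
    rel = idi_val / slope1 if slope1 != 0 else float("nan")
    return IdiResult(
        idi=idi_val, se=se, p_value=p_val,
        delta_mean_events=float(d_e.mean()),
        delta_mean_nonevents=float(d_ne.mean()),
        relative_idi=float(rel),
        discrimination_slope_1=slope1,
        discrimination_slope_2=slope2,
    )


def intermediate_risk_reclassification(
    p1: np.ndarray,
    p2: np.ndarray,
    labels: np.ndarray,
    cutoffs: Tuple[float, float] = DEFAULT_CUTOFFS,
) -> NriResult:
    """NRI restricted to subjects at intermediate risk under model 1
    (calibrated probability in [c1, c2)).  An empty subgroup yields an
    explicit empty result rather than an exception."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    y = np.asarray(labels).astype(int)
    c1, c2 = cutoffs
    mask = (p1 >= c1) & (p1 < c2)
    if not mask.any():
        return NriResult(
            nri=0.0, se=0.0, p_value=1.0,
            event_component=0.0, event_p_value=1.0,
            nonevent_component=0.0, nonevent_p_value=1.0,
            n_events=0, n_nonevents=0,
        )
    return nri(p1[mask], p2[mask], y[mask], cutoffs, allow_empty=True)


# ---------------------------------------------------------------------------
# report tables


def percent_incremental_improvement(auc_model: float, auc_baseline: float) -> float:
    """Percent incremental AUC improvement from random relative to the
    baseline model: 100 * (AUC_m - AUC_baseline) / (AUC_m - 0.5)."""
    return 100.0 * (auc_model - auc_baseline) / (auc_model - 0.5)


def report_tables(
    models: Mapping[str, np.ndarray],
    labels: np.ndarray,
    baseline: str,
    comparisons: Sequence[Tuple[str, str]] | None = None,
    cutoffs: Tuple[float, float] = DEFAULT_CUTOFFS,
    out_dir: str | Path | None = None,
) -> Dict[str, pd.DataFrame]:
    """Build the four report tables from cross-validated probabilities.

    ``models`` maps model name -> probabilities; ``baseline`` names the
    no-cholesterol conventional model used as the reference for the
    percent-incremental column.  ``comparisons`` defaults to all ordered
    nested pairs in ``models`` order.  When ``out_dir`` is given the
    tables are written as table4_roc.csv .. table7_intermediate.csv.
    """
    if baseline not in models:
        raise ValueError(f"baseline model {baseline!r} missing from models")
    y = _check_labels(labels)
    names = list(models)
    base_auc = roc_auc(models[baseline], y).auc

    rows = []
    for name in names:
        r = roc_auc(models[name], y)
        rows.append(
            {
                "Model": name,
                "AUC": r.auc,
                "SE": r.se,
                "AUC improvement from random": r.improvement,
                "% incremental AUC improvement from random":
                    percent_incremental_improvement(r.auc, base_auc),
            }
        )
    table4 = pd.DataFrame(rows)

    if comparisons is None:
        comparisons = [
            (a, b) for i, a in enumerate(names) for b in names[i + 1:]
        ]
    rows = []
    for m1, m2 in comparisons:
        d = delong_compare(models[m1], models[m2], y)
        rows.append(
            {
                "Model 1": m1, "Model 2": m2,
                "Difference AUC ROC curve": d["delta_auc"],
                "Standard Error": d["se"], "P value": d["p_value"],
            }
        )
    table5 = pd.DataFrame(rows)

    rows_nri, rows_idi, rows_int = [], [], []
    for m1, m2 in comparisons:
        r = nri(models[m1], models[m2], y, cutoffs)
        rows_nri.append(
            {
                "Model 1": m1, "Model 2": m2, "NRI": r.nri,
                "Standard Error": r.se, "P value": r.p_value,
                "% of Events correctly reclassified":
                    100.0 * r.event_component,
                "Event P-value": r.event_p_value,
                "% of Non-events correctly reclassified":
                    100.0 * r.nonevent_component,
                "Nonevent P-value": r.nonevent_p_value,
            }
        )
        ri = idi(models[m1], models[m2], y)
        rows_idi.append(
            {
                "Model 1": m1, "Model 2": m2, "Absolute IDI": ri.idi,
                "Standard Error": ri.se, "P value": ri.p_value,
                "Probability change for events": ri.delta_mean_events,
                "Probability change for non-events": ri.delta_mean_nonevents,
                "Relative IDI": ri.relative_idi,
            }
        )
        sub = intermediate_risk_reclassification(models[m1], models[m2], y, cutoffs)
        rows_int.append(
            {
                "Model 1": m1, "Model 2": m2, "NRI": sub.nri,
                "Standard Error": sub.se, "P value": sub.p_value,
                "% of Events correctly reclassified":
                    100.0 * sub.event_component,
                "Event P-value": sub.event_p_value,
                "% of Non-events correctly reclassified":
                    100.0 * sub.nonevent_component,
                "Nonevent P-value": sub.nonevent_p_value,
                "n events": sub.n_events, "n non-events": sub.n_nonevents,
            }
        )
    tables = {
        "table4_roc": table4,
        "table5_delong": table5,
        "table6_reclassification": pd.concat(
            [pd.DataFrame(rows_nri), pd.DataFrame(rows_idi)], axis=1,
            keys=["NRI", "IDI"],
        ),
        "table7_intermediate": pd.DataFrame(rows_int),
    }
    # flatten the two-block reclassification table for CSV output
    t6 = pd.DataFrame(rows_nri).merge(
        pd.DataFrame(rows_idi), on=["Model 1", "Model 2"], suffixes=("", " (IDI)")
    )
    tables["table6_reclassification"] = t6
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tbl in tables.items():
            tbl.to_csv(out / f"{name}.csv", index=False)
    return tables
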