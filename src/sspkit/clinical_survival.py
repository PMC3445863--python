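"""Subtype-by-clinical-feature tables, IHC-style surrogate labels,
Kaplan-Meier estimation and the log-rank test."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CLINICAL_FEATURES,
    NA_TOKEN,
    SUBTYPES,
    ClinicalRecord,
    SubtypeCall,
    SurvivalRecord,
    ValidationError,
)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with .5 going up (not banker's)."""
    return int(math.floor(x + 0.5))


def clinical_by_subtype(
    calls: Sequence[SubtypeCall],
    clinical: Sequence[ClinicalRecord],
    features: Sequence[str] | None = None,
) -> dict[str, dict]:
    """One category x subtype count table per feature, with column proportions.

    Missing values are excluded from that feature's denominators and reported
    as a per-subtype count.
    """
    features = list(features) if features is not None else list(CLINICAL_FEATURES)
    unknown = [f for f in features if f not in CLINICAL_FEATURES]
    if unknown:
        raise ValidationError(f"unknown clinical feature(s): {unknown}")
    clin = {r.sample_id: r for r in clinical}
    missing = [c.sample_id for c in calls if c.sample_id not in clin]
    if missing:
        raise ValidationError(f"called samples without clinical records: {missing[:10]}")
    out: dict[str, dict] = {}
    for feature in features:
        levels = list(CLINICAL_FEATURES[feature])
        table = pd.DataFrame(0, index=levels, columns=list(SUBTYPES), dtype=int)
        na_counts = pd.Series(0, index=list(SUBTYPES), dtype=int)
        for call in calls:
            if call.label not in SUBTYPES:
                continue  # Unclassified calls carry no subtype column
            value = getattr(clin[call.sample_id], feature)
            if value == NA_TOKEN:
                na_counts[call.label] += 1
            else:
                table.loc[value, call.label] += 1
        denom = table.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = table / denom.replace(0, np.nan)
        out[feature] = {
            "counts": table,
            "proportions": props,
            "missing": na_counts,
        }
    return out


def marginal_summary(
    clinical: Sequence[ClinicalRecord],
    features: Sequence[str] | None = None,
) -> dict[str, dict]:
    """Per-feature category counts with integer percentages.

    Percentages are count / (non-missing total), rounded half-up; the missing
    count is reported separately and excluded from the denominator.
    """
    if not clinical:
        raise ValidationError("marginal_summary needs at least 1 record")
    features = list(features) if features is not None else list(CLINICAL_FEATURES)
    unknown = [f for f in features if f not in CLINICAL_FEATURES]
    if unknown:
        raise ValidationError(f"unknown clinical feature(s): {unknown}")
    out: dict[str, dict] = {}
    for feature in features:
        levels = list(CLINICAL_FEATURES[feature])
        counts = {lvl: 0 for lvl in levels}
        n_missing = 0
        for r in clinical:
            value = getattr(r, feature)
            if value == NA_TOKEN:
                n_missing += 1
            else:
                counts[value] += 1
        denom = sum(counts.values())
        percents = {
            lvl: (round_half_up(100.0 * c / denom) if denom else None)
            for lvl, c in counts.items()
        }
        out[feature] = {
            "counts": counts,
            "percent": percents,
            "n": denom,
            "missing": n_missing,
        }
    return out


def ihc_surrogate(record: ClinicalRecord) -> str:
    """Phenotype surrogate: ER+ -> luminal-like; ER-/HER2+ -> HER2-like;
    ER-/HER2- -> triple-negative-like; any missing input -> unknown."""
    if record.er == NA_TOKEN:
        return "unknown"
    if record.er == "positive":
        return "luminal-like"
    if record.her2 == NA_TOKEN:
        return "unknown"
    if record.her2 == "over-expressed":
        return "HER2-like"
    return "triple-negative-like"


@dataclass
class KMCurve:
    """Product-limit estimate: step times, survival values and risk sets."""

    times: np.ndarray  # distinct observed times, ascending
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # risk-set size just before each time
    events: np.ndarray  # events at each time

    def probability_at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "survival": self.survival.tolist(),
            "at_risk": self.at_risk.tolist(),
            "events": self.events.tolist(),
        }


def km_curve(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S starts at 1 and steps down only at event times; censoring shrinks the
    risk set without a step. Ties at one time collapse to a single step.
    """
    if not records:
        raise ValidationError("km_curve needs at least 1 record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times)
    out_t, out_s, out_n, out_d = [], [], [], []
    s = 1.0
    for t in uniq:
        at_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        out_t.append(float(t))
        out_s.append(s)
        out_n.append(at_risk)
        out_d.append(d)
    return KMCurve(np.array(out_t), np.array(out_s), np.array(out_n), np.array(out_d))


def logrank_test(
    groups: Sequence[Sequence[SurvivalRecord]],
) -> tuple[float, int, float]:
    """Multi-group log-rank test.

    Returns (chi-square statistic, df = G-1, upper-tail p-value). Ties are
    handled with the hypergeometric variance at tied event times; the
    statistic is the quadratic form of observed-minus-expected event counts
    against their estimated covariance (last group dropped).
    """
    if len(groups) < 2:
        raise ValidationError("logrank_test needs at least 2 groups")
    times, events, gidx = [], [], []
    for g, recs in enumerate(groups):
        for r in recs:
            times.append(r.time)
            events.append(r.event)
            gidx.append(g)
    times = np.array(times, dtype=float)
    events = np.array(events, dtype=int)
    gidx = np.array(gidx, dtype=int)
    if events.sum() == 0:
        raise ValidationError("logrank statistic undefined with zero events")
    G = len(groups)
    event_times = np.unique(times[events == 1])
    u = np.zeros(G)
    V = np.zeros((G, G))
    for t in event_times:
        at_risk = times >= t
        N = int(at_risk.sum())
        d = int(events[(times == t)].sum())
        if N <= 1:
            # no variance contribution possible; O == E when one subject left
            pass
        n_g = np.array([(at_risk & (gidx == g)).sum() for g in range(G)], dtype=float)
        o_g = np.array(
            [((times == t) & (events == 1) & (gidx == g)).sum() for g in range(G)],
            dtype=float,
        )
        e_g = n_g * d / N
        u += o_g - e_g
        if N > 1:
            factor = d * (N - d) / (N - 1)
            V += factor * (np.diag(n_g) * N - np.outer(n_g, n_g)) / N**2
    u_r, V_r = u[:-1], V[:-1, :-1]
    try:
        stat = float(u_r @ np.linalg.solve(V_r, u_r))
    except np.linalg.LinAlgError:
        stat = float(u_r @ np.linalg.pinv(V_r) @ u_r)
    stat = max(stat, 0.0)
    df = G - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def filter_survival(
    calls: Sequence[SubtypeCall],
    survival: Sequence[SurvivalRecord],
    clinical: Sequence[ClinicalRecord] | None = None,
    clinical_filter: Mapping[str, str] | None = None,
    labels: Sequence[str] | None = None,
) -> dict[str, list[SurvivalRecord]]:
    """Group survival records by call label, optionally filtered on clinical
    values (e.g. ``{"er": "negative"}``) and restricted to given labels.

    Subgroup analyses are just this filter in front of km_curve/logrank_test.
    """
    surv = {r.sample_id: r for r in survival}
    clin = {r.sample_id: r for r in clinical} if clinical is not None else {}
    if clinical_filter and clinical is None:
        raise ValidationError("clinical_filter requires clinical records")
    groups: dict[str, list[SurvivalRecord]] = {}
    for call in calls:
        if call.sample_id not in surv:
            continue
        if labels is not None and call.label not in labels:
            continue
        if clinical_filter:
            rec = clin.get(call.sample_id)
            if rec is None:
                continue
            if any(getattr(rec, k) != v for k, v in clinical_filter.items()):
                continue
        groups.setdefault(call.label, []).append(surv[call.sample_id])
    return groups
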