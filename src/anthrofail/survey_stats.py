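"""Survey-weighted prevalence estimation and the score-vs-conventional audit.

Prevalences from complex household surveys (DHS/NFHS-style) are estimated
with sampling weights; 95% confidence intervals use a Taylor-linearized
design-based variance when stratum and primary-sampling-unit (PSU)
identifiers are available, and otherwise fall back to a normal approximation
on the effective sample size ``n_eff = (Σw)² / Σw²`` (Kish).

The module also cross-tabulates the composite score's Failure/No-failure
call against the conventional definition of anthropometric failure (any of
HAZ < −2, WAZ < −2, WHZ < −2, WHZ > +2) and reports sensitivity and
specificity, unweighted by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .ciaf_models import Model, conventional_indicators, group_codes, tabulate_groups, UNCLASSIFIED, assign_group

__all__ = [
    "WeightedEstimate",
    "ConfusionSummary",
    "weighted_proportion",
    "confusion_vs_conventional",
    "indicator_prevalence",
    "group_prevalence",
]


@dataclass(frozen=True)
class WeightedEstimate:
    """Weighted frequency, proportion (%) and 95% CI for one category."""

    category: str
    weighted_freq: float
    proportion_pct: float
    ci_lo_pct: float
    ci_hi_pct: float
    weighted_total: float
    n_unweighted: int


@dataclass(frozen=True)
class ConfusionSummary:
    """2×2 agreement between the score's call and conventional failure."""

    tp: float
    fp: float
    fn: float
    tn: float
    sensitivity_pct: float
    specificity_pct: float

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def _design_variance(member: np.ndarray, weights: np.ndarray, strata, psu, p: float) -> float:
    """Taylor-linearized variance of a weighted proportion under with-
    replacement sampling of PSUs within strata (the standard svy/Stata
    first-order approximation)."""
    wtot = weights.sum()
    # Linearized scores for the ratio estimator p = Σw·y / Σw.
    z = weights * (member.astype(float) - p) / wtot
    strata = np.asarray(strata, dtype=object)
    psu = np.asarray(psu, dtype=object)
    var = 0.0
    for h in np.unique(strata):
        in_h = strata == h
        clusters = np.unique(psu[in_h])
        n_h = len(clusters)
        if n_h < 2:
            continue  # single-PSU stratum contributes no estimable variance
        totals = np.array([z[in_h & (psu == c)].sum() for c in clusters])
        var += n_h / (n_h - 1) * ((totals - totals.mean()) ** 2).sum()
    return var


def weighted_proportion(
    member: Sequence[bool],
    weights: Sequence[float],
    strata: Sequence | None = None,
    psu: Sequence | None = None,
    category: str = "",
    alpha: float = 0.05,
) -> WeightedEstimate:
    """Weighted proportion of members with a 95% (by default) CI.

    ``member`` flags category membership per record.  With ``strata`` and
    ``psu`` both given, the CI uses the design-based Taylor variance;
    otherwise a normal approximation on the Kish effective sample size.

    Raises
    ------
    ValueError
        If weights are negative or sum to zero.
    """
    member = np.asarray(member, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    if member.shape != weights.shape:
        raise ValueError("member and weights must be aligned")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    wtot = weights.sum()
    if wtot <= 0:
        raise ValueError("weights sum to zero: no population to estimate")
    wfreq = weights[member].sum()
    p = wfreq / wtot
    if strata is not None and psu is not None:
        se = np.sqrt(_design_variance(member, weights, strata, psu, p))
    else:
        n_eff = wtot**2 / (weights**2).sum()
        se = np.sqrt(p * (1 - p) / n_eff)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, p - zcrit * se)
    hi = min(1.0, p + zcrit * se)
    return WeightedEstimate(
        category=category,
        weighted_freq=wfreq,
        proportion_pct=100 * p,
        ci_lo_pct=100 * lo,
        ci_hi_pct=100 * hi,
        weighted_total=wtot,
        n_unweighted=int(member.size),
    )


def _conventional_failure(haz, waz, whz) -> np.ndarray:
    haz, waz, whz = (np.asarray(a, dtype=float) for a in (haz, waz, whz))
    return (haz < -2) | (waz < -2) | (whz < -2) | (whz > 2)


def confusion_vs_conventional(
    records: Sequence,
    scores: Sequence[float],
    cutoff: float,
    weights: Sequence[float] | None = None,
) -> ConfusionSummary:
    """Cross-tabulate the score's Failure call (score ≥ cutoff) against
    conventional anthropometric failure (any indicator failing).

    Counts are unweighted unless ``weights`` is given, matching how such
    audits are usually reported.  Sensitivity = tp/(tp+fn), specificity =
    tn/(tn+fp), as percentages (0 when the denominator is empty).
    """
    haz = np.array([r.haz for r in records], dtype=float)
    waz = np.array([r.waz for r in records], dtype=float)
    whz = np.array([r.whz for r in records], dtype=float)
    scores = np.asarray(scores, dtype=float)
    ref = _conventional_failure(haz, waz, whz)
    test = scores >= cutoff
    w = np.ones_like(scores) if weights is None else np.asarray(weights, dtype=float)
    tp = float(w[ref & test].sum())
    fp = float(w[~ref & test].sum())
    fn = float(w[ref & ~test].sum())
    tn = float(w[~ref & ~test].sum())
    sens = 100 * tp / (tp + fn) if tp + fn > 0 else 0.0
    spec = 100 * tn / (tn + fp) if tn + fp > 0 else 0.0
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn, sensitivity_pct=sens, specificity_pct=spec)


def _gated_out(scores, score_gate) -> np.ndarray:
    if score_gate is None:
        return np.zeros(len(scores), dtype=bool)
    return np.asarray(scores, dtype=float) < score_gate


def indicator_prevalence(
    records: Sequence,
    weights: Sequence[float] | None = None,
    strata: Sequence | None = None,
    psu: Sequence | None = None,
    score_gate: float | None = None,
    scores: Sequence[float] | None = None,
) -> dict[str, WeightedEstimate]:
    """Marginal weighted prevalence of stunting, wasting, underweight and
    overweight (a child counts toward every indicator it meets).

    With ``score_gate``, children whose composite score falls below the gate
    count toward no indicator (they are deemed "No failure" by the score),
    so gated prevalence is never above ungated prevalence.
    """
    records = list(records)
    haz = np.array([r.haz for r in records], dtype=float)
    waz = np.array([r.waz for r in records], dtype=float)
    whz = np.array([r.whz for r in records], dtype=float)
    if weights is None:
        weights = np.array([r.survey_weight for r in records], dtype=float)
    if score_gate is not None and scores is None:
        raise ValueError("score gating requested but scores not provided")
    gated_out = _gated_out(scores if scores is not None else [], score_gate) \
        if score_gate is not None else np.zeros(len(records), dtype=bool)
    members = {
        "stunting": haz < -2,
        "wasting": whz < -2,
        "underweight": waz < -2,
        "overweight": whz > 2,
    }
    return {
        name: weighted_proportion(
            member & ~gated_out, weights, strata=strata, psu=psu, category=name
        )
        for name, member in members.items()
    }


def group_prevalence(
    records: Sequence,
    model: Model | str = Model.PROPOSED,
    weights: Sequence[float] | None = None,
    strata: Sequence | None = None,
    psu: Sequence | None = None,
    score_gate: float | None = None,
    scores: Sequence[float] | None = None,
) -> dict[str, WeightedEstimate]:
    """Weighted prevalence of each mutually exclusive CIAF group (plus
    Unclassified), in table order; proportions sum to 100%.

    With ``score_gate``, a child scoring below the gate is counted in
    "No failure" (group A) regardless of indicators.
    """
    records = list(records)
    model = Model(model)
    if weights is None:
        weights = np.array([r.survey_weight for r in records], dtype=float)
    if score_gate is not None and scores is None:
        raise ValueError("score gating requested but scores not provided")
    gated_out = _gated_out(scores if scores is not None else [], score_gate) \
        if score_gate is not None else np.zeros(len(records), dtype=bool)
    codes = np.array(
        [
            "A" if gated_out[i]
            else assign_group(conventional_indicators(r.haz, r.waz, r.whz), model).code
            for i, r in enumerate(records)
        ],
        dtype=object,
    )
    out: dict[str, WeightedEstimate] = {}
    for code in group_codes(model) + (UNCLASSIFIED,):
        out[code] = weighted_proportion(
            codes == code, weights, strata=strata, psu=psu, category=code
        )
    return out
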