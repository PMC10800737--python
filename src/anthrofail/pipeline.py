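"""End-to-end orchestration: exclusions → score → calibrate → classify → tables.

:func:`run_full_pipeline` wires the modules into the full analysis flow a
survey dataset goes through: plausibility screening, composite scoring,
empirical cut-off calibration, gated and ungated CIAF classification,
weighted prevalence tables, and the score-vs-conventional confusion audit.
The report it returns serializes to byte-stable JSON (sorted keys, floats at
6 significant digits) so repeated runs on identical input diff clean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import ciaf_models, survey_stats
from .ciaf_models import Model, UNCLASSIFIED, group_codes
from .records import (
    ChildRecord,
    PlausibilityLimits,
    apply_exclusion_pipeline,
    read_records_csv,
)
from .scoring import (
    DEFAULT_HAZ_THRESHOLD,
    ScoreParams,
    calibrate_cutoff,
    score_records,
)

__all__ = ["RunConfig", "run_full_pipeline", "render_report_json"]

logger = logging.getLogger("anthrofail")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    n: int = 15
    haz_threshold: float = DEFAULT_HAZ_THRESHOLD
    model: Model | str = Model.PROPOSED
    gate: bool = True
    limits: PlausibilityLimits = field(default_factory=PlausibilityLimits)
    use_design: bool = True  # use stratum/PSU for CIs when present


def _estimates_table(estimates: dict) -> dict:
    return {
        key: {
            "weighted_freq": est.weighted_freq,
            "proportion_pct": est.proportion_pct,
            "ci_lo_pct": est.ci_lo_pct,
            "ci_hi_pct": est.ci_hi_pct,
        }
        for key, est in estimates.items()
    }


def run_full_pipeline(
    records: Sequence[ChildRecord],
    config: RunConfig | None = None,
) -> dict:
    """Run the complete analysis on raw records and return a report dict.

    Steps: exclusion pipeline → composite scoring at power ``n`` →
    cut-off calibration (lowest score among HAZ < threshold) → ungated and
    score-gated group tabulations and weighted prevalences → indicator
    prevalences → confusion audit.  Deterministic given records and config.

    Raises
    ------
    CalibrationError
        If no retained record has HAZ below the calibration threshold.
    """
    if config is None:
        config = RunConfig()
    model = Model(config.model)
    retained, report = apply_exclusion_pipeline(records, config.limits)
    logger.info("exclusions: %s", report.as_dict())
    params = ScoreParams(n=config.n)
    scores = score_records(retained, params)
    calib = calibrate_cutoff(
        zip(scores, (r.haz for r in retained)),
        haz_threshold=config.haz_threshold,
        n=config.n,
    )
    logger.info(
        "calibrated cutoff %.6f (n=%d, %d qualifying records)",
        calib.cutoff, config.n, calib.qualifying_count,
    )
    weights = np.array([r.survey_weight for r in retained], dtype=float)
    strata = [r.stratum for r in retained]
    psu = [r.psu for r in retained]
    have_design = config.use_design and all(s is not None for s in strata) and all(
        p is not None for p in psu
    )
    kw = dict(weights=weights, strata=strata if have_design else None,
              psu=psu if have_design else None)

    counts_ungated = ciaf_models.tabulate_groups(retained, model)
    counts_gated = ciaf_models.tabulate_groups(
        retained, model, score_gate=calib.cutoff, scores=scores
    )
    prev_ungated = survey_stats.group_prevalence(retained, model, **kw)
    prev_gated = survey_stats.group_prevalence(
        retained, model, score_gate=calib.cutoff, scores=scores, **kw
    )
    ind_ungated = survey_stats.indicator_prevalence(retained, **kw)
    ind_gated = survey_stats.indicator_prevalence(
        retained, score_gate=calib.cutoff, scores=scores, **kw
    )
    confusion = survey_stats.confusion_vs_conventional(retained, scores, calib.cutoff)

    all_codes = group_codes(model) + (UNCLASSIFIED,)
    return {
        "config": {
            "n": config.n,
            "haz_threshold": config.haz_threshold,
            "model": model.value,
            "gate": bool(config.gate),
            "design_based_ci": bool(have_design),
        },
        "exclusions": report.as_dict(),
        "calibration": {
            "cutoff": calib.cutoff,
            "haz_threshold": calib.haz_threshold,
            "qualifying_count": calib.qualifying_count,
        },
        "group_counts": {
            "ungated": {c: int(counts_ungated.get(c, 0)) for c in all_codes},
            "gated": {c: int(counts_gated.get(c, 0)) for c in all_codes},
        },
        "group_prevalence": {
            "ungated": _estimates_table(prev_ungated),
            "gated": _estimates_table(prev_gated),
        },
        "indicator_prevalence": {
            "ungated": _estimates_table(ind_ungated),
            "gated": _estimates_table(ind_gated),
        },
        "confusion": {
            "tp": confusion.tp,
            "fp": confusion.fp,
            "fn": confusion.fn,
            "tn": confusion.tn,
            "sensitivity_pct": confusion.sensitivity_pct,
            "specificity_pct": confusion.specificity_pct,
        },
    }


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def render_report_json(report: dict) -> str:
    """Serialize a report with sorted keys and floats at 6 significant
    digits, so identical runs produce byte-identical JSON."""
    return json.dumps(_round_floats(report), sort_keys=True, indent=2)
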