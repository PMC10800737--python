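"""The composite anthropometric-failure score and its cut-off calibration.

The score combines the three WHO z-scores into a single 0–100 scalar in which
higher values mean more severe anthropometric failure.  Raw z-scores cannot
simply be averaged: positive and negative deviations cancel, and a high WHZ
(overweight) is itself a failure.  The construction therefore

1. subtracts HAZ and WAZ from a constant so that deficits *raise* the score,
2. folds WHZ by absolute value so that wasting and overweight both raise it,
3. raises each z-score to an odd-behaving power ``n`` (sign-preserving, via
   ``sign(z)·|z|^n``) so that extreme deviations dominate moderate ones, and
4. rescales so the score spans exactly [0, 100] over the WHO plausibility box
   HAZ ∈ [−6, +6], WAZ ∈ [−6, +5], WHZ ∈ [−5, +5].

For power ``n`` the score is::

    score = 100 / (3·6^n + 2·5^n)
            · [ (6^n + 5^n) − sp(HAZ, n) − sp(WAZ, n) + |WHZ|^n ]

with ``sp(z, n) = sign(z)·|z|^n``.  This single form is algebraically equal to
the two-branch formulation (adding the WHZ term when WHZ < 0, subtracting it
when WHZ > 0); the branches coincide at WHZ = 0.  At ``n = 1`` the bracket is
the familiar ``11 − (HAZ + WAZ ± WHZ)`` with maximum 28 at (−6, −6, −5).

The failure cut-off is calibrated empirically on a scored population: it is
the lowest score among children with HAZ below a threshold (default −2.10 SD,
deliberately below the conventional −2 SD stunting line so that children near
the line, who may simply be in a slow phase of saltatory linear growth, are
not committed to "failure" by HAZ alone).  Scores at or above the cut-off are
classified Failure.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import PlausibilityLimits

__all__ = [
    "ScoreParams",
    "CutoffCalibration",
    "CalibrationError",
    "Classification",
    "signed_power",
    "composite_score",
    "score_records",
    "max_unscaled_sum",
    "max_unscaled_score",
    "calibrate_cutoff",
    "classify_by_score",
]

DEFAULT_HAZ_THRESHOLD = -2.10


@dataclass(frozen=True)
class ScoreParams:
    """Power and range constants of the composite score.

    The range constants are the WHO plausibility limits: the positive maxima
    of HAZ and WAZ (+6, +5) set the zero point of the score, and the largest
    absolute values (6, 6, 5) set its maximum.  ``n`` defaults to 15, which
    weights severe deviations heavily; ``n = 1`` gives the plain z-score sum
    with constants a = 11 and unscaled maximum 28.
    """

    n: int = 15
    z_max_pos_haz: int = 6
    z_max_pos_waz: int = 5
    z_abs_max_haz: int = 6
    z_abs_max_waz: int = 6
    z_abs_max_whz: int = 5

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"power n must be a positive integer, got {self.n!r}")

    @property
    def offset(self) -> int:
        """Bracket offset ``6^n + 5^n`` (11 at n = 1): makes the score 0 at
        the most favourable point (HAZ = +6, WAZ = +5, WHZ = 0)."""
        return self.z_max_pos_haz**self.n + self.z_max_pos_waz**self.n

    @property
    def denom(self) -> int:
        """Normalizing constant ``3·6^n + 2·5^n`` (28 at n = 1): the bracket's
        value at the worst point (HAZ = −6, WAZ = −6, WHZ = −5)."""
        return (
            self.z_abs_max_haz**self.n
            + self.z_abs_max_waz**self.n
            + self.z_max_pos_haz**self.n
            + self.z_abs_max_whz**self.n
            + self.z_max_pos_waz**self.n
        )


def signed_power(z, n: int):
    """Sign-preserving power ``sign(z)·|z|^n``; 0 at z = 0.

    Equivalent to the quotient ``z^(2n−1) / |z^(n−1)|`` wherever that is
    defined (the quotient is 0/0 at z = 0 for n > 1; its limit is 0), but
    computed directly to avoid overflow at large n (6^29 ≈ 3.7e22 loses
    precision in double arithmetic).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.abs(z) ** n
    return float(out) if out.ndim == 0 else out


def composite_score(haz, waz, whz, params: ScoreParams | None = None):
    """Composite failure score in [0, 100]; higher = more severe failure.

    Accepts scalars or numpy arrays.  Inputs must lie inside the plausibility
    box (HAZ ∈ [−6, +6], WAZ ∈ [−6, +5], WHZ ∈ [−5, +5] by default); callers
    are expected to run the exclusion pipeline first.

    Raises
    ------
    ValueError
        If any input lies outside the plausibility box.
    """
    if params is None:
        params = ScoreParams()
    haz = np.asarray(haz, dtype=float)
    waz = np.asarray(waz, dtype=float)
    whz = np.asarray(whz, dtype=float)
    if np.any((haz < -params.z_abs_max_haz) | (haz > params.z_max_pos_haz)):
        raise ValueError("HAZ outside plausibility range")
    if np.any((waz < -params.z_abs_max_waz) | (waz > params.z_max_pos_waz)):
        raise ValueError("WAZ outside plausibility range")
    if np.any(np.abs(whz) > params.z_abs_max_whz):
        raise ValueError("WHZ outside plausibility range")
    n = params.n
    bracket = (
        params.offset
        - np.sign(haz) * np.abs(haz) ** n
        - np.sign(waz) * np.abs(waz) ** n
        + np.abs(whz) ** n
    )
    # 100·bracket/denom (not (100/denom)·bracket): for integral inputs up to
    # n ≈ 17 every intermediate is exactly representable, so the extremes land
    # on exactly 0.0 and 100.0.
    out = 100.0 * bracket / params.denom
    return float(out) if out.ndim == 0 else out


def score_records(records: Sequence, params: ScoreParams | None = None) -> np.ndarray:
    """Score a sequence of records carrying ``haz``/``waz``/``whz``."""
    haz = np.array([r.haz for r in records], dtype=float)
    waz = np.array([r.waz for r in records], dtype=float)
    whz = np.array([r.whz for r in records], dtype=float)
    return composite_score(haz, waz, whz, params)


def _branch_sum(haz: float, waz: float, whz: float) -> float:
    """Branch-appropriate raw z-score sum: HAZ+WAZ+WHZ when WHZ ≤ 0,
    HAZ+WAZ−WHZ when WHZ ≥ 0 (branches agree at WHZ = 0)."""
    return haz + waz + whz if whz < 0 else haz + waz - whz


def _box_candidates(limits: PlausibilityLimits, grid_step: float | None):
    """Candidate points for brute-force optimization over the plausibility
    box.  The branch sum is linear on each WHZ half-box, so its extrema lie on
    the corners of the two half-boxes (WHZ ∈ {lo, 0, hi}); a dense grid is
    supported as an independent cross-check."""
    if grid_step is None:
        haz_pts = (limits.haz_lo, limits.haz_hi)
        waz_pts = (limits.waz_lo, limits.waz_hi)
        whz_pts = (limits.whz_lo, 0.0, limits.whz_hi)
    else:
        haz_pts = np.arange(limits.haz_lo, limits.haz_hi + grid_step / 2, grid_step)
        waz_pts = np.arange(limits.waz_lo, limits.waz_hi + grid_step / 2, grid_step)
        whz_pts = np.arange(limits.whz_lo, limits.whz_hi + grid_step / 2, grid_step)
    return itertools.product(haz_pts, waz_pts, whz_pts)


def max_unscaled_sum(
    limits: PlausibilityLimits | None = None, grid_step: float | None = None
) -> float:
    """Maximum of the branch-appropriate raw z-score sum over the plausibility
    box, by brute force (corner enumeration, or a dense grid if ``grid_step``
    is given).

    Over the default WHO box this is 11, attained at HAZ = +6, WAZ = +5,
    WHZ = 0; it is the constant the n = 1 score subtracts the sum from so
    that the score's minimum is 0.
    """
    if limits is None:
        limits = PlausibilityLimits()
    return max(_branch_sum(h, w, z) for h, w, z in _box_candidates(limits, grid_step))


def max_unscaled_score(
    limits: PlausibilityLimits | None = None,
    grid_step: float | None = None,
    a: float | None = None,
) -> tuple[float, tuple[float, float, float]]:
    """Maximum of the unscaled n = 1 score ``a − (branch sum)`` over the
    plausibility box, with its maximizing point.

    The constant ``a`` defaults to the branch-sum maximum over the *full WHO
    box* (11): it is part of the score's construction and does not shrink
    when the search box is restricted.  Over the default box the maximum is
    28 at (HAZ, WAZ, WHZ) = (−6, −6, −5): the 100/28 rescaling pins the
    score's top at 100.
    """
    if limits is None:
        limits = PlausibilityLimits()
    if a is None:
        a = max_unscaled_sum(PlausibilityLimits(), grid_step)
    best_val, best_pt = -math.inf, None
    for h, w, z in _box_candidates(limits, grid_step):
        val = a - _branch_sum(h, w, z)
        if val > best_val:
            best_val, best_pt = val, (h, w, z)
    return best_val, best_pt


class CalibrationError(ValueError):
    """Raised when no record qualifies for cut-off calibration."""


@dataclass(frozen=True)
class CutoffCalibration:
    """Result of the empirical cut-off rule.

    ``cutoff`` is the minimum score among records with HAZ strictly below
    ``haz_threshold``; ``qualifying_count`` is how many records that is.
    """

    cutoff: float
    haz_threshold: float
    n_used: int
    qualifying_count: int


def calibrate_cutoff(
    scored_records: Iterable[tuple[float, float]],
    haz_threshold: float = DEFAULT_HAZ_THRESHOLD,
    n: int = 15,
) -> CutoffCalibration:
    """Calibrate the failure cut-off: the lowest score among records whose
    HAZ falls strictly below ``haz_threshold``.

    Parameters
    ----------
    scored_records
        Iterable of ``(score, haz)`` pairs.
    haz_threshold
        HAZ qualifying line in SD units (default −2.10).
    n
        The score power used, recorded for provenance.

    Raises
    ------
    CalibrationError
        If no record has HAZ below the threshold.
    """
    qualifying = [score for score, haz in scored_records if haz < haz_threshold]
    if not qualifying:
        raise CalibrationError(
            f"no record with HAZ < {haz_threshold}: cannot calibrate cut-off"
        )
    # Exact float ordering; scores are deterministic so ties reproduce.
    return CutoffCalibration(
        cutoff=min(qualifying),
        haz_threshold=haz_threshold,
        n_used=n,
        qualifying_count=len(qualifying),
    )


class Classification(enum.Enum):
    FAILURE = "Failure"
    NO_FAILURE = "NoFailure"


def classify_by_score(score: float, cutoff: float) -> Classification:
    """Failure iff ``score >= cutoff``.

    Ties go to Failure: the record that defines the cut-off has HAZ below the
    calibration threshold and must itself classify as Failure for the rule to
    be coherent.
    """
    return Classification.FAILURE if score >= cutoff else Classification.NO_FAILURE
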