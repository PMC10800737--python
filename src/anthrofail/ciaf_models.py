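"""CIAF taxonomies: conventional indicators and mutually exclusive groups.

The Composite Index of Anthropometric Failure (CIAF) partitions children into
mutually exclusive categories of anthropometric failure instead of reporting
the overlapping marginal prevalences of stunting, wasting, underweight and
overweight.  Three successive taxonomies are implemented:

* **Svedberg** (as operationalized with the extra "Underweight only" group):
  seven groups A–F and Y defined on wasting/stunting/underweight only.
* **Kuiti**: adds "Stunting and overweight" (G) and "Overweight only" (H).
  Two operationalizations are provided — strict row-matching against the
  published table, and a *legacy-sequential* mode that first labels by the
  Svedberg table and then reassigns any overweight child to G or H.  The
  legacy mode reproduces the discrepancy that motivates the ten-group model:
  a child who is stunted, underweight *and* overweight leaves "Stunting and
  underweight" (E) and lands in "Stunting and overweight" (G).
* **Proposed**: ten groups — the Kuiti nine plus group I, "Stunting,
  underweight, and overweight", restoring a clean partition.

Indicator conventions (WHO): stunted HAZ < −2, wasted WHZ < −2, underweight
WAZ < −2, overweight WHZ > +2, all strict.  Indicator combinations matching
no published row (e.g. wasting + stunting without underweight) are surfaced
as ``Unclassified``, never silently folded into another group.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Model",
    "IndicatorSet",
    "GroupLabel",
    "UNCLASSIFIED",
    "GROUP_NAMES",
    "conventional_indicators",
    "assign_group",
    "assign_group_legacy_kuiti",
    "tabulate_groups",
    "cross_model_audit",
    "group_codes",
]


class Model(str, enum.Enum):
    """CIAF taxonomy variants."""

    SVEDBERG = "svedberg"
    KUITI = "kuiti"
    KUITI_LEGACY = "kuiti-legacy"
    PROPOSED = "proposed"


@dataclass(frozen=True)
class IndicatorSet:
    """The four conventional anthropometric-failure indicators.

    ``wasted`` (WHZ < −2) and ``overweight`` (WHZ > +2) partition disjoint
    ranges of WHZ and can never both hold.
    """

    stunted: bool
    wasted: bool
    underweight: bool
    overweight: bool

    def __post_init__(self) -> None:
        if self.wasted and self.overweight:
            raise ValueError("wasted and overweight are mutually exclusive (both derive from WHZ)")

    @property
    def any_failure(self) -> bool:
        return self.stunted or self.wasted or self.underweight or self.overweight


UNCLASSIFIED = "Unclassified"

#: Human-readable group names (proposed model; earlier models use subsets).
GROUP_NAMES = {
    "A": "No failure",
    "B": "Wasting only",
    "C": "Wasting and underweight",
    "D": "Stunting, wasting and underweight",
    "E": "Stunting and underweight",
    "F": "Stunting only",
    "Y": "Underweight only",
    "G": "Stunting and overweight",
    "H": "Overweight only",
    "I": "Stunting, underweight, and overweight",
    UNCLASSIFIED: "Unclassified",
}

# Row tables keyed on (wasted, stunted, underweight[, overweight]); the
# Svedberg table ignores overweight entirely.
_SVEDBERG_ROWS = {
    (False, False, False): "A",
    (True, False, False): "B",
    (True, False, True): "C",
    (True, True, True): "D",
    (False, True, True): "E",
    (False, True, False): "F",
    (False, False, True): "Y",
}

_KUITI_ROWS = {
    (False, False, False, False): "A",
    (True, False, False, False): "B",
    (True, False, True, False): "C",
    (True, True, True, False): "D",
    (False, True, True, False): "E",
    (False, True, False, False): "F",
    (False, False, True, False): "Y",
    (False, True, False, True): "G",
    (False, False, False, True): "H",
}

_PROPOSED_ROWS = dict(_KUITI_ROWS)
_PROPOSED_ROWS[(False, True, True, True)] = "I"


def group_codes(model: Model | str) -> tuple[str, ...]:
    """Valid group codes for a model, in table order (without Unclassified)."""
    model = Model(model)
    if model is Model.SVEDBERG:
        return ("A", "B", "C", "D", "E", "F", "Y")
    if model in (Model.KUITI, Model.KUITI_LEGACY):
        return ("A", "B", "C", "D", "E", "F", "Y", "G", "H")
    return ("A", "B", "C", "D", "E", "F", "Y", "G", "H", "I")


@dataclass(frozen=True)
class GroupLabel:
    """One taxonomy's label for one child."""

    model: Model
    code: str

    def __post_init__(self) -> None:
        if self.code != UNCLASSIFIED and self.code not in group_codes(self.model):
            raise ValueError(f"code {self.code!r} invalid for model {self.model.value}")

    @property
    def name(self) -> str:
        return GROUP_NAMES[self.code]


def conventional_indicators(haz: float, waz: float, whz: float) -> IndicatorSet:
    """Derive the four indicators from a z-score triple.

    Inequalities are strict: a child at exactly −2 (or +2) SD does not fail
    that indicator.
    """
    return IndicatorSet(
        stunted=haz < -2,
        wasted=whz < -2,
        underweight=waz < -2,
        overweight=whz > 2,
    )


def assign_group(ind: IndicatorSet, model: Model | str) -> GroupLabel:
    """Label an indicator combination under a taxonomy by exact row-matching.

    Combinations matching no published row yield ``Unclassified``.  The
    proposed table, for instance, has no row for wasting + stunting without
    underweight, nor for underweight + overweight without stunting; whether
    such combinations are biologically possible is an open question, so they
    are reported as-is rather than coerced.
    """
    model = Model(model)
    if model is Model.SVEDBERG:
        code = _SVEDBERG_ROWS.get((ind.wasted, ind.stunted, ind.underweight), UNCLASSIFIED)
    elif model is Model.KUITI:
        code = _KUITI_ROWS.get(
            (ind.wasted, ind.stunted, ind.underweight, ind.overweight), UNCLASSIFIED
        )
    elif model is Model.KUITI_LEGACY:
        return assign_group_legacy_kuiti(ind)
    else:
        code = _PROPOSED_ROWS.get(
            (ind.wasted, ind.stunted, ind.underweight, ind.overweight), UNCLASSIFIED
        )
    return GroupLabel(model=model, code=code)


def assign_group_legacy_kuiti(ind: IndicatorSet) -> GroupLabel:
    """Sequential (legacy) Kuiti labelling.

    First label by the Svedberg table (which ignores overweight), then
    reassign any overweight child: to G if stunted, to H if it has no other
    failure.  A stunted + underweight + overweight child therefore lands in
    G, which is exactly the migration out of E that the ten-group model's
    group I makes explicit.
    """
    base = _SVEDBERG_ROWS.get((ind.wasted, ind.stunted, ind.underweight), UNCLASSIFIED)
    if ind.overweight:
        if ind.stunted:
            return GroupLabel(Model.KUITI_LEGACY, "G")
        if not ind.any_failure or base == "A":
            return GroupLabel(Model.KUITI_LEGACY, "H")
    return GroupLabel(Model.KUITI_LEGACY, base)


def tabulate_groups(
    records: Iterable,
    model: Model | str,
    score_gate: float | None = None,
    scores: Sequence[float] | None = None,
) -> Counter:
    """Unweighted group frequencies under a taxonomy.

    With ``score_gate`` set, a child whose composite score falls below the
    gate (the calibrated cut-off) is counted as "No failure" (group A)
    regardless of its indicators; ``scores`` must then be supplied, aligned
    with ``records``.  Weighted analogues live in :mod:`anthrofail.survey_stats`.
    """
    model = Model(model)
    records = list(records)
    if score_gate is not None:
        if scores is None:
            raise ValueError("score gating requested but scores not provided")
        scores = list(scores)
        if len(scores) != len(records):
            raise ValueError("scores and records must be aligned")
    table: Counter = Counter()
    for i, record in enumerate(records):
        if score_gate is not None and scores[i] < score_gate:
            table["A"] += 1
            continue
        ind = conventional_indicators(record.haz, record.waz, record.whz)
        table[assign_group(ind, model).code] += 1
    return table


def cross_model_audit(records: Iterable) -> dict:
    """Tabulate all taxonomies on one population and check the counting
    identities that link them.

    The ten-group model explains the discrepancy between Svedberg and
    sequential-Kuiti labelling:

    * Svedberg E = proposed E + proposed I (Svedberg cannot see overweight,
      so S+U+O children sit in its "Stunting and underweight");
    * legacy-Kuiti G = proposed G + proposed I (sequential reassignment sends
      S+U+O children to "Stunting and overweight");
    * legacy-Kuiti E = proposed E.

    Returns the per-model tables, the identity checks, and totals.
    """
    records = list(records)
    tables = {
        model.value: tabulate_groups(records, model)
        for model in (Model.SVEDBERG, Model.KUITI_LEGACY, Model.PROPOSED)
    }
    sv, kl, pr = tables["svedberg"], tables["kuiti-legacy"], tables["proposed"]
    identities = {
        "svedberg_E_eq_proposed_E_plus_I": sv["E"] == pr["E"] + pr["I"],
        "legacy_kuiti_G_eq_proposed_G_plus_I": kl["G"] == pr["G"] + pr["I"],
        "legacy_kuiti_E_eq_proposed_E": kl["E"] == pr["E"],
    }
    totals = {name: sum(tab.values()) for name, tab in tables.items()}
    return {
        "tables": {name: dict(tab) for name, tab in tables.items()},
        "identities": identities,
        "totals": totals,
        "n_records": len(records),
        "all_identities_hold": all(identities.values()),
    }
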