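"""Seeded generator of DHS-like under-five child populations.

Real child-recode microdata (e.g. the NFHS-5 file the score was demonstrated
on) is registered-access, so every pipeline stage here is exercised on
synthetic populations instead.  The generator draws (HAZ, WHZ) from a
correlated bivariate normal and builds WAZ structurally::

    WAZ = b_h·HAZ + b_w·WHZ + ε,   ε ~ N(0, σ²)

reflecting that weight-for-age was introduced as a single indicator folding
together linear deficit (stunting) and ponderal deficit (wasting); with the
default loadings 0.55/0.55 and noise SD 0.35 the marginal WAZ variance stays
near 1 and biologically coherent rare combinations (very low HAZ and WAZ
with high WHZ) occur the way field data shows them.  Triples falling outside
the WHO plausibility box are resampled (rejection, not clipping, so the
limits carry no boundary atoms).

Records in specific CIAF groups can be *planted*: their z-scores are drawn
uniformly from group-consistent boxes (for group I — stunting, underweight
and overweight together — the box is the empirical range reported for that
group: HAZ −6.00..−3.82, WAZ −4.03..−2.01, WHZ +2.01..+4.82), so planted
counts are recovered exactly by deterministic classification.

A messy variant injects missing anthropometry and out-of-box z-scores at
given rates and returns the injected counts, for verifying the exclusion
pipeline's bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ciaf_models import Model, assign_group, conventional_indicators
from .records import ChildRecord, PlausibilityLimits

__all__ = [
    "SyntheticConfig",
    "InjectionSummary",
    "PLANT_RANGES",
    "generate_population",
    "generate_messy_population",
]

#: Group-consistent uniform sampling boxes (haz, waz, whz) per proposed-model
#: code.  Group I uses the published empirical ranges; the others keep a
#: 0.01 SD margin from the ±2 thresholds so classification is unambiguous.
PLANT_RANGES: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "A": ((-1.99, 3.0), (-1.99, 3.0), (-1.99, 1.99)),
    "B": ((-1.99, 3.0), (-1.99, 3.0), (-4.0, -2.01)),
    "C": ((-1.99, 2.0), (-4.0, -2.01), (-4.0, -2.01)),
    "D": ((-5.0, -2.01), (-5.0, -2.01), (-4.0, -2.01)),
    "E": ((-5.0, -2.01), (-5.0, -2.01), (-1.99, 1.99)),
    "F": ((-5.0, -2.01), (-1.99, 2.0), (-1.99, 1.99)),
    "Y": ((-1.99, 2.0), (-4.0, -2.01), (-1.99, 1.99)),
    "G": ((-5.0, -2.01), (-1.99, 2.0), (2.01, 4.5)),
    "H": ((-1.99, 2.0), (-1.99, 2.0), (2.01, 4.5)),
    "I": ((-6.0, -3.82), (-4.03, -2.01), (2.01, 4.82)),
}


@dataclass
class SyntheticConfig:
    """Population model parameters.

    Defaults loosely mimic the Indian under-five z-score distribution
    (negative mean HAZ and WHZ, weak HAZ–WHZ correlation, marginal
    prevalences of stunting/wasting in the tens of percent); they are
    configuration, not constants.
    """

    n_children: int = 10_000
    seed: int = 0
    mean_haz: float = -1.2
    mean_whz: float = -0.8
    sd_haz: float = 1.6
    sd_whz: float = 1.3
    corr_haz_whz: float = 0.1
    waz_loading_haz: float = 0.55
    waz_loading_whz: float = 0.55
    waz_noise_sd: float = 0.35
    weight_distribution: str = "lognormal"  # "constant" or "lognormal"
    weight_mu: float = 0.0
    weight_sigma: float = 0.5
    planted_records: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if not -1 < self.corr_haz_whz < 1:
            raise ValueError("corr_haz_whz must lie in (-1, 1)")
        if self.sd_haz <= 0 or self.sd_whz <= 0 or self.waz_noise_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if self.weight_distribution not in ("constant", "lognormal"):
            raise ValueError("weight_distribution must be 'constant' or 'lognormal'")
        for code, count in self.planted_records:
            if code not in PLANT_RANGES:
                raise ValueError(f"unknown plant group code {code!r}")
            if count < 0:
                raise ValueError("planted counts must be >= 0")


@dataclass(frozen=True)
class InjectionSummary:
    """Bookkeeping for :func:`generate_messy_population`."""

    n_missing_anthropometry: int
    n_outlier_haz: int
    n_outlier_waz: int
    n_outlier_whz: int

    @property
    def n_outliers(self) -> int:
        return self.n_outlier_haz + self.n_outlier_waz + self.n_outlier_whz


def _draw_triples(config: SyntheticConfig, n: int, rng: np.random.Generator,
                  limits: PlausibilityLimits) -> np.ndarray:
    """Rejection-sample n (haz, waz, whz) triples inside the plausibility box."""
    cov = np.array(
        [
            [config.sd_haz**2, config.corr_haz_whz * config.sd_haz * config.sd_whz],
            [config.corr_haz_whz * config.sd_haz * config.sd_whz, config.sd_whz**2],
        ]
    )
    mean = np.array([config.mean_haz, config.mean_whz])
    out = np.empty((0, 3))
    attempts = 0
    while len(out) < n:
        batch = max(n - len(out), 1000)
        hw = rng.multivariate_normal(mean, cov, size=batch)
        haz, whz = hw[:, 0], hw[:, 1]
        waz = (
            config.waz_loading_haz * haz
            + config.waz_loading_whz * whz
            + rng.normal(0.0, config.waz_noise_sd, size=batch)
        )
        ok = (
            (haz >= limits.haz_lo) & (haz <= limits.haz_hi)
            & (waz >= limits.waz_lo) & (waz <= limits.waz_hi)
            & (whz >= limits.whz_lo) & (whz <= limits.whz_hi)
        )
        out = np.vstack([out, np.column_stack([haz, waz, whz])[ok]])
        attempts += batch
        if attempts >= 10_000 and len(out) < 0.01 * attempts:
            raise ValueError(
                "rejection rate above 99%: population parameters are degenerate "
                "relative to the plausibility box"
            )
    return out[:n]


def _make_record(i: int, haz: float, waz: float, whz: float, config: SyntheticConfig,
                 rng: np.random.Generator) -> ChildRecord:
    age = float(rng.uniform(0, 59))
    sex = "male" if rng.random() < 0.5 else "female"
    if config.weight_distribution == "constant":
        w = 1.0
    else:
        w = float(rng.lognormal(config.weight_mu, config.weight_sigma))
    # Cosmetic raw anthropometry consistent in direction with the z-scores;
    # the analysis itself never recomputes z-scores from these.
    height = max(45.0, 65.0 + 0.55 * age + 2.0 * haz)
    weight = max(2.0, 7.0 + 0.16 * age + 1.0 * waz)
    return ChildRecord(
        id=f"c{i:07d}",
        haz=round(float(haz), 6),
        waz=round(float(waz), 6),
        whz=round(float(whz), 6),
        age_months=round(age, 2),
        sex=sex,
        height_cm=round(height, 1),
        weight_kg=round(weight, 2),
        survey_weight=round(w, 6),
        stratum=f"s{rng.integers(1, 11):02d}",
        psu=f"p{rng.integers(1, 201):04d}",
    )


def generate_population(config: SyntheticConfig | None = None) -> list[ChildRecord]:
    """Generate a seeded synthetic child population.

    Returns ``config.n_children`` base records plus any planted records,
    in deterministic order (same seed, same config → identical records).
    Every record lies inside the WHO plausibility box and carries
    height/weight, so the exclusion pipeline retains all of them.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    limits = PlausibilityLimits()
    triples = _draw_triples(config, config.n_children, rng, limits)
    records = [
        _make_record(i, h, w, z, config, rng) for i, (h, w, z) in enumerate(triples)
    ]
    i = len(records)
    for code, count in config.planted_records:
        h_rng, w_rng, z_rng = PLANT_RANGES[code]
        for _ in range(count):
            h = float(rng.uniform(*h_rng))
            w = float(rng.uniform(*w_rng))
            z = float(rng.uniform(*z_rng))
            records.append(_make_record(i, h, w, z, config, rng))
            i += 1
    return records


def generate_messy_population(
    config: SyntheticConfig | None = None,
    missing_rate: float = 0.0,
    outlier_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[list[ChildRecord], InjectionSummary]:
    """Generate a population and corrupt disjoint subsets of it.

    ``missing_rate`` of records lose height and weight (excluded at the
    pipeline's first stage); ``outlier_rate`` of the remaining records get
    one z-score pushed strictly outside the plausibility box (cycling
    through HAZ, WAZ, WHZ).  The subsets are disjoint, so the returned
    :class:`InjectionSummary` matches the exclusion report reason-for-reason.
    """
    if not (0 <= missing_rate <= 1 and 0 <= outlier_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    records = generate_population(config)
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = len(records)
    n_missing = int(round(missing_rate * n))
    n_outlier = min(int(round(outlier_rate * n)), n - n_missing)
    chosen = rng.choice(n, size=n_missing + n_outlier, replace=False)
    missing_idx, outlier_idx = chosen[:n_missing], chosen[n_missing:]
    for i in missing_idx:
        records[i].height_cm = None
        records[i].weight_kg = None
    counts = {"haz": 0, "waz": 0, "whz": 0}
    for k, i in enumerate(outlier_idx):
        which = ("haz", "waz", "whz")[k % 3]
        lo_hi = {"haz": (-6, 6), "waz": (-6, 5), "whz": (-5, 5)}[which]
        value = lo_hi[1] + float(rng.uniform(0.5, 3.0))
        if rng.random() < 0.5:
            value = lo_hi[0] - float(rng.uniform(0.5, 3.0))
        setattr(records[i], which, value)
        counts[which] += 1
    summary = InjectionSummary(
        n_missing_anthropometry=int(n_missing),
        n_outlier_haz=counts["haz"],
        n_outlier_waz=counts["waz"],
        n_outlier_whz=counts["whz"],
    )
    return records, summary
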