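"""Soil-water partitioning from column-leaching data.

A leaching test applies a known amount of antibiotic to a small soil column
(5 g dry weight), elutes with 10 mL artificial rainwater, and quantifies the
analyte recovered in the soil and water fractions.  The partition
coefficient is

    Kd = (amount_soil / soil_mass) / (amount_water / eluate_volume)

in L/kg, i.e. sorbed content (ng/g) over solution concentration (ng/mL).
Nondetects are substituted by the limit of detection, which makes a
water-censored Kd a lower bound and a soil-censored Kd an upper bound.
Any log10 Kd above 2 is flagged as a rough estimate: at that partitioning
the water fraction approaches the detection limit and the ratio becomes
extrapolative.  Koc normalises Kd to the organic-carbon fraction,
Koc = 100 * Kd / %OC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LeachObservation",
    "PartitionResult",
    "BothBelowDetectionError",
    "compute_kd",
    "kd_to_koc",
    "som_to_oc",
    "range_ratio",
    "combine_replicates",
    "read_leach_csv",
    "partition_table",
]

#: Conventional loss-on-ignition organic matter to organic carbon divisor.
VAN_BEMMELEN_FACTOR = 1.724

#: log10 Kd above which the estimate is considered rough (Kd > 100 L/kg).
ROUGH_LOG10_KD = 2.0

#: Acceptable recovered/applied mass-balance window before a quality warning.
MASS_BALANCE_WINDOW = (0.5, 1.2)


class BothBelowDetectionError(ValueError):
    """Raised when neither fraction is above its detection limit."""


@dataclass(frozen=True)
class LeachObservation:
    """One replicate of the column-leaching test for a soil x compound."""

    soil_id: str
    compound: str
    amount_soil: float  # ng recovered in the soil fraction
    amount_water: float  # ng recovered in the eluate
    soil_mass: float = 5.0  # g dry weight
    eluate_volume: float = 10.0  # mL
    lod_soil: float = 1.0  # ng
    lod_water: float = 1.0  # ng
    replicate: int = 1
    applied: float | None = 400.0  # ng, for mass-balance checking

    def __post_init__(self) -> None:
        if self.soil_mass <= 0 or self.eluate_volume <= 0:
            raise ValueError("soil mass and eluate volume must be positive")
        if self.amount_soil < 0 or self.amount_water < 0:
            raise ValueError("recovered amounts must be non-negative")
        if self.lod_soil <= 0 or self.lod_water <= 0:
            raise ValueError("detection limits must be positive")


@dataclass
class PartitionResult:
    soil_id: str
    compound: str
    kd: float  # L/kg
    log10_kd: float
    censored: str  # "none" | "soil_lod" | "water_lod"
    rough_estimate: bool
    koc: float = math.nan  # L/kg OC, set by kd_to_koc when OC is known
    log10_koc: float = math.nan
    replicate: int = 1


def compute_kd(obs: LeachObservation) -> PartitionResult:
    """Partition coefficient of one leaching observation, with censoring.

    A fraction below its detection limit enters the ratio at the LOD; if
    both fractions are nondetect no Kd exists and
    :class:`BothBelowDetectionError` is raised.
    """
    soil_nd = obs.amount_soil < obs.lod_soil
    water_nd = obs.amount_water < obs.lod_water
    if soil_nd and water_nd:
        raise BothBelowDetectionError(
            f"{obs.soil_id}/{obs.compound} replicate {obs.replicate}: both "
            "fractions below detection; Kd undefined"
        )
    amount_soil = obs.lod_soil if soil_nd else obs.amount_soil
    amount_water = obs.lod_water if water_nd else obs.amount_water
    censored = "soil_lod" if soil_nd else ("water_lod" if water_nd else "none")

    if obs.applied is not None:
        recovery = (obs.amount_soil + obs.amount_water) / obs.applied
        lo, hi = MASS_BALANCE_WINDOW
        if not lo <= recovery <= hi:
            warnings.warn(
                f"{obs.soil_id}/{obs.compound} replicate {obs.replicate}: "
                f"mass balance {recovery:.2f} outside [{lo}, {hi}]",
                stacklevel=2,
            )

    kd = (amount_soil / obs.soil_mass) / (amount_water / obs.eluate_volume)
    log10_kd = math.log10(kd)
    return PartitionResult(
        soil_id=obs.soil_id, compound=obs.compound, kd=kd,
        log10_kd=log10_kd, censored=censored,
        rough_estimate=log10_kd > ROUGH_LOG10_KD, replicate=obs.replicate,
    )


def som_to_oc(som_percent: float, factor: float = VAN_BEMMELEN_FACTOR) -> float:
    """Convert loss-on-ignition organic matter (%) to organic carbon (%)."""
    if som_percent < 0:
        raise ValueError("SOM percentage must be non-negative")
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    return som_percent / factor


def kd_to_koc(kd: float, oc_percent: float) -> tuple[float, float]:
    """Organic-carbon-normalised coefficient: Koc = 100 * Kd / %OC.

    Returns ``(koc, log10_koc)``.
    """
    if oc_percent <= 0:
        raise ValueError("organic carbon percentage must be positive")
    if kd <= 0:
        raise ValueError("Kd must be positive")
    koc = 100.0 * kd / oc_percent
    return koc, math.log10(koc)


def range_ratio(values) -> float:
    """max/min of a set of positive values (the spread statistic reported
    per compound); round to reproduce the integer table form."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("range ratio needs at least 2 values")
    if np.any(arr <= 0):
        raise ValueError("range ratio defined for positive values only")
    return float(arr.max() / arr.min())


def combine_replicates(results: list[PartitionResult],
                       how: str = "geometric") -> PartitionResult:
    """Pool replicate Kd values for one soil x compound.

    Default is the geometric mean (the data are analysed on the log scale);
    ``how='arithmetic'`` averages on the linear scale instead.  Censoring
    flags are propagated: any censored replicate marks the pooled value.
    """
    if not results:
        raise ValueError("no replicates to combine")
    first = results[0]
    if any(r.soil_id != first.soil_id or r.compound != first.compound
           for r in results):
        raise ValueError("replicates must share soil_id and compound")
    kds = np.array([r.kd for r in results])
    if how == "geometric":
        kd = float(stats.gmean(kds))
    elif how == "arithmetic":
        kd = float(kds.mean())
    else:
        raise ValueError(f"unknown pooling method {how!r}")
    censored_flags = {r.censored for r in results} - {"none"}
    censored = censored_flags.pop() if len(censored_flags) == 1 else (
        "mixed" if censored_flags else "none"
    )
    log10_kd = math.log10(kd)
    return PartitionResult(
        soil_id=first.soil_id, compound=first.compound, kd=kd,
        log10_kd=log10_kd, censored=censored,
        rough_estimate=log10_kd > ROUGH_LOG10_KD, replicate=0,
    )


def read_leach_csv(path) -> list[LeachObservation]:
    """Read leaching observations from CSV.

    Columns: ``soil_id, compound, replicate, amount_soil_ng,
    amount_water_ng, soil_mass_g, eluate_volume_ml, lod_soil_ng,
    lod_water_ng`` and optionally ``applied_ng``.
    """
    frame = pd.read_csv(path)
    obs = []
    for row in frame.itertuples(index=False):
        obs.append(
            LeachObservation(
                soil_id=str(row.soil_id), compound=str(row.compound),
                replicate=int(getattr(row, "replicate", 1)),
                amount_soil=float(row.amount_soil_ng),
                amount_water=float(row.amount_water_ng),
                soil_mass=float(row.soil_mass_g),
                eluate_volume=float(row.eluate_volume_ml),
                lod_soil=float(row.lod_soil_ng),
                lod_water=float(row.lod_water_ng),
                applied=float(getattr(row, "applied_ng", 400.0)),
            )
        )
    return obs


def partition_table(
    observations: list[LeachObservation],
    oc_percent: dict[str, float] | None = None,
    pooling: str = "geometric",
) -> tuple[pd.DataFrame, list[str]]:
    """Compute pooled Kd (and Koc where OC is known) per soil x compound.

    ``oc_percent`` maps soil_id to organic carbon content in percent.
    Returns the results table and a log of observations without a Kd.
    """
    log: list[str] = []
    grouped: dict[tuple[str, str], list[PartitionResult]] = {}
    for obs in observations:
        try:
            res = compute_kd(obs)
        except BothBelowDetectionError as exc:
            log.append(str(exc))
            continue
        grouped.setdefault((obs.soil_id, obs.compound), []).append(res)

    rows = []
    for (soil_id, compound), results in sorted(grouped.items()):
        pooled = combine_replicates(results, how=pooling)
        row = {
            "soil_id": soil_id, "compound": compound,
            "n_replicates": len(results), "kd_l_per_kg": pooled.kd,
            "log10_kd": pooled.log10_kd, "censored": pooled.censored,
            "rough_estimate": pooled.rough_estimate,
            "koc_l_per_kg_oc": math.nan, "log10_koc": math.nan,
        }
        if oc_percent is not None and soil_id in oc_percent:
            koc, log10_koc = kd_to_koc(pooled.kd, oc_percent[soil_id])
            row["koc_l_per_kg_oc"] = koc
            row["log10_koc"] = log10_koc
        rows.append(row)
    return pd.DataFrame(rows), log
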