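"""Per-replicate myosin efficiency indices, replicate QC and aggregation.

The efficiency index of one replicate is the blank-subtracted initial
decay rate of its relative fluorescence, normalised by the effective
myosin concentration in the well:

    index = (atp_rate - blank_rate) / concentration      [1/s per mg/mL]

A larger index means a steeper fluorescence decay, more heat released per
unit myosin, and therefore *lower* mechanochemical efficiency.  Each
preparation is measured in sextuplicate; replicates are QC'd in two
steps — negative indices (null reactions) first, then a single-pass
one-standard-deviation band on the remainder — and surviving replicates
aggregate preparation -> animal -> group, with group dispersion computed
over animal means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import RateEstimate

__all__ = [
    "EfficiencyRecord",
    "PreparationSummary",
    "AnimalSummary",
    "GroupSummary",
    "PipelineError",
    "INCLUDED",
    "EXCLUDED_NEGATIVE",
    "EXCLUDED_OUTSIDE_SD",
    "pair_blanks",
    "efficiency_index",
    "qc_filter",
    "select_optimal_dilution",
    "aggregate",
]

INCLUDED = "included"
EXCLUDED_NEGATIVE = "excluded_negative"
EXCLUDED_OUTSIDE_SD = "excluded_outside_sd"


class PipelineError(ValueError):
    pass


@dataclass
class EfficiencyRecord:
    """One ATP replicate's blank-subtracted, normalised rate with QC status."""

    preparation_id: str
    replicate_index: int
    atp_rate: float
    blank_rate: float
    concentration_mg_per_ml: float
    efficiency_index: float
    qc_status: str = INCLUDED
    animal_id: str = ""
    group: str = ""
    stratum: str = ""
    well_id: str = ""

    @property
    def net_rate(self) -> float:
        return self.atp_rate - self.blank_rate

    @property
    def included(self) -> bool:
        return self.qc_status == INCLUDED


@dataclass(frozen=True)
class PreparationSummary:
    preparation_id: str
    animal_id: str
    group: str
    stratum: str
    n_included: int
    mean_index: float
    sd_index: float
    failed: bool = False


@dataclass(frozen=True)
class AnimalSummary:
    animal_id: str
    group: str
    stratum: str
    n_preparations: int
    mean_index: float


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD over *animal* means (n = animals), per stratum."""

    group: str
    stratum: str
    n_animals: int
    mean_index: float
    sd_index: float


def pair_blanks(
    layout: pd.DataFrame,
    rates: Sequence[RateEstimate],
) -> dict[str, tuple[list[tuple[int, str, float]], float]]:
    """Pair every ATP replicate with its preparation's mean blank rate.

    Returns ``{preparation_id: ([(replicate_index, well_id, atp_rate),
    ...], blank_rate)}``.  The blank rate is the mean over the
    preparation's blank wells (no per-well pairing is defined by the
    assay); a preparation with ATP wells but no blank rate is an error.
    """
    by_well = {r.well_id: r for r in rates}
    layout_idx = layout.set_index("well_id")
    preps: dict[str, tuple[list[tuple[int, str, float]], float]] = {}
    for prep, grp in layout_idx.groupby("preparation_id"):
        atp_rows = grp[grp["condition"] == "ATP"]
        blank_rows = grp[grp["condition"] == "BLANK"]
        atp_wells = [w for w in atp_rows.index if w in by_well]
        blank_rates = [by_well[w].initial_decay_rate
                       for w in blank_rows.index if w in by_well]
        if not atp_wells:
            continue
        if not blank_rates:
            raise PipelineError(
                f"preparation {prep}: ATP wells present but no blank rate")
        blank_rate = float(np.mean(blank_rates))
        pairs = [
            (int(atp_rows.loc[w, "replicate_index"]), w,
             by_well[w].initial_decay_rate)
            for w in atp_wells
        ]
        pairs.sort()
        preps[str(prep)] = (pairs, blank_rate)
    return preps


def efficiency_index(
    atp_rate: float, blank_rate: float, concentration: float
) -> float:
    """Blank-subtracted rate per unit effective myosin concentration.

    May be negative (a null reaction); negatives are handled by QC, not
    here.  Halving the concentration doubles the index for fixed rates.
    """
    if concentration <= 0:
        raise PipelineError(
            f"concentration must be positive, got {concentration}")
    return (atp_rate - blank_rate) / concentration


def qc_filter(
    indices: Sequence[float], sd_multiplier: float = 1.0
) -> list[str]:
    """Classify each replicate index as included or excluded with reason.

    Step 1: indices < 0 (null reactions) are excluded first — they would
    corrupt the dispersion estimate.  Step 2: on the remainder, compute
    the mean m and sample SD s (n-1 denominator) once; any value with
    |x - m| > sd_multiplier * s is excluded.  The band test is strict and
    single-pass (never iterated); if s = 0 every remaining value is kept.
    Returns one status per input value, in order.  If nothing survives the
    caller must flag the preparation as failed rather than drop it.
    """
    if len(indices) < 2:
        raise PipelineError("QC needs at least 2 replicate indices")
    statuses = [INCLUDED] * len(indices)
    positive: list[tuple[int, float]] = []
    for i, x in enumerate(indices):
        if x < 0:
            statuses[i] = EXCLUDED_NEGATIVE
        else:
            positive.append((i, x))
    if not positive:
        return statuses
    values = np.array([x for _, x in positive])
    if len(values) >= 2:
        m = values.mean()
        s = float(np.std(values, ddof=1))
        if s > 0:
            for i, x in positive:
                if abs(x - m) > sd_multiplier * s:
                    statuses[i] = EXCLUDED_OUTSIDE_SD
    return statuses


def select_optimal_dilution(
    series: Sequence[tuple[float, float]], tolerance: float = 0.05
) -> float:
    """Pick the optimal assay concentration from a dilution series.

    ``series`` is (concentration, net_rate) pairs.  Among concentrations
    whose net rate is within ``tolerance`` of the fastest observed rate,
    the lowest concentration wins — the least myosin that still reacts at
    full speed.
    """
    if not series:
        raise PipelineError("empty dilution series")
    concs = [c for c, _ in series]
    if len(set(concs)) != len(concs):
        raise PipelineError("dilution series concentrations must be distinct")
    max_rate = max(rate for _, rate in series)
    eligible = [c for c, rate in series if rate >= (1.0 - tolerance) * max_rate]
    return min(eligible)


def aggregate(
    records: Iterable[EfficiencyRecord],
    strata: Mapping[str, str] | None = None,
) -> tuple[list[PreparationSummary], list[AnimalSummary], list[GroupSummary]]:
    """Roll replicate records up to preparation, animal and group level.

    Excluded replicates never enter any aggregate.  A preparation whose
    replicates were all excluded is reported as failed (NaN mean), and an
    animal left with no surviving preparation is flagged the same way.
    Group mean and SD are computed over animal means (n = animals), the
    dispersion convention used for small-animal studies, never over
    pooled replicates.
    """
    records = list(records)
    prep_summaries: list[PreparationSummary] = []
    by_prep: dict[str, list[EfficiencyRecord]] = {}
    for rec in records:
        by_prep.setdefault(rec.preparation_id, []).append(rec)

    for prep, recs in by_prep.items():
        stratum = strata.get(prep, recs[0].stratum) if strata else recs[0].stratum
        included = [r.efficiency_index for r in recs if r.included]
        failed = len(included) == 0
        mean = float(np.mean(included)) if included else math.nan
        sd = float(np.std(included, ddof=1)) if len(included) > 1 else 0.0
        prep_summaries.append(PreparationSummary(
            preparation_id=prep,
            animal_id=recs[0].animal_id,
            group=recs[0].group,
            stratum=stratum,
            n_included=len(included),
            mean_index=mean,
            sd_index=sd if included else math.nan,
            failed=failed,
        ))

    animal_summaries: list[AnimalSummary] = []
    by_animal: dict[tuple[str, str], list[PreparationSummary]] = {}
    for ps in prep_summaries:
        if ps.failed or ps.stratum == "":
            continue
        by_animal.setdefault((ps.animal_id, ps.stratum), []).append(ps)
    for (animal, stratum), preps in sorted(by_animal.items()):
        animal_summaries.append(AnimalSummary(
            animal_id=animal,
            group=preps[0].group,
            stratum=stratum,
            n_preparations=len(preps),
            mean_index=float(np.mean([p.mean_index for p in preps])),
        ))

    group_summaries: list[GroupSummary] = []
    by_group: dict[tuple[str, str], list[AnimalSummary]] = {}
    for asum in animal_summaries:
        by_group.setdefault((asum.group, asum.stratum), []).append(asum)
    for (group, stratum), animals in sorted(by_group.items()):
        means = np.array([a.mean_index for a in animals])
        group_summaries.append(GroupSummary(
            group=group,
            stratum=stratum,
            n_animals=len(animals),
            mean_index=float(means.mean()),
            sd_index=float(np.std(means, ddof=1)) if len(means) > 1 else 0.0,
        ))
    return prep_summaries, animal_summaries, group_summaries
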