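"""Model/Results surface for a complete thermometry study.

:class:`ThermometryAssay` bundles the raw inputs of one study — kinetic
traces, plate layout, sample metadata, A280 absorbance sets and optional
MyHC densitometry — with a :class:`~qdtherm.config.RunConfig`.  Its
:meth:`~ThermometryAssay.fit` runs the full analysis and returns a
:class:`ThermometryResults` carrying per-replicate efficiency indices
with QC status, preparation/animal/group aggregates, the isoform strata
and the between-group comparison, with a printable ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .config import RunConfig
from .isoforms import (HIGH_IIA, MAIN, IsoformComposition, isoform_fractions,
                       stratify)
from .kinetics import FluorescenceTrace, RateEstimate, initial_rate_of
from .pipeline import (AnimalSummary, EfficiencyRecord, GroupSummary,
                       PipelineError, PreparationSummary, aggregate,
                       efficiency_index, pair_blanks, qc_filter)
from .protein import (AbsorbanceSet, ProteinQuantResult,
                      effective_concentration, quantify_a280)
from .stats import GroupComparison, t_test_values

__all__ = ["ThermometryAssay", "ThermometryResults"]


@dataclass
class ThermometryResults:
    """Fitted study: estimates, QC verdicts, aggregates and the group test."""

    config: RunConfig
    rates: list[RateEstimate]
    protein: list[ProteinQuantResult]
    records: list[EfficiencyRecord]
    preparations: list[PreparationSummary]
    animals: list[AnimalSummary]
    group_summaries: list[GroupSummary]
    comparison: GroupComparison | None
    compositions: dict[str, IsoformComposition]
    strata: dict[str, str]
    warnings: list[str] = field(default_factory=list)

    # -- convenience views -------------------------------------------------

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "preparation_id": r.preparation_id,
            "animal_id": r.animal_id,
            "group": r.group,
            "stratum": r.stratum,
            "replicate_index": r.replicate_index,
            "atp_rate_per_s": r.atp_rate,
            "blank_rate_per_s": r.blank_rate,
            "net_rate_per_s": r.net_rate,
            "concentration_mg_per_ml": r.concentration_mg_per_ml,
            "efficiency_index": r.efficiency_index,
            "qc_status": r.qc_status,
        } for r in self.records])

    def animal_means(self, group: str, stratum: str = MAIN) -> np.ndarray:
        return np.array([a.mean_index for a in self.animals
                         if a.group == group and a.stratum == stratum])

    def group_summary(self, group: str, stratum: str = MAIN) -> GroupSummary | None:
        for gs in self.group_summaries:
            if gs.group == group and gs.stratum == stratum:
                return gs
        return None

    # -- output ------------------------------------------------------------

    def to_tsv(self, dest) -> None:
        qio.write_results(self, dest)

    def summary(self) -> str:
        """Human-readable report of the fitted study."""
        lines = [
            "Quantum-dot thermometry: myosin efficiency index",
            "=" * 60,
            f"polynomial degree {self.config.poly_degree}, window "
            f"[0, {self.config.window_end_s:g}] s, QC band "
            f"{self.config.sd_multiplier:g} SD",
            f"replicates: {len(self.records)} "
            f"({sum(r.included for r in self.records)} included, "
            f"{sum(r.qc_status == 'excluded_negative' for r in self.records)}"
            f" negative, "
            f"{sum(r.qc_status == 'excluded_outside_sd' for r in self.records)}"
            f" outside SD band)",
            "-" * 60,
            f"{'group':<8}{'stratum':<10}{'n animals':>10}"
            f"{'mean index':>14}{'SD':>10}",
        ]
        for gs in self.group_summaries:
            lines.append(
                f"{gs.group:<8}{gs.stratum:<10}{gs.n_animals:>10d}"
                f"{gs.mean_index:>14.4g}{gs.sd_index:>10.3g}")
        lines.append("-" * 60)
        if self.comparison is not None:
            c = self.comparison
            kind = "Welch" if c.welch else "Student (pooled)"
            lines.append(
                f"{kind} unpaired t-test, main stratum: "
                f"t = {c.t_statistic:.3f}, df = {c.degrees_of_freedom:g}, "
                f"two-sided p = {c.p_two_sided:.4g}")
            lines.append(
                "larger index = steeper fluorescence decay = more heat "
                "= lower myosin efficiency")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot_traces(self, traces: list[FluorescenceTrace], ax=None):
        from .plotting import plot_relative_traces
        return plot_relative_traces(traces, self, ax=ax)

    def plot_indices(self, ax=None):
        from .plotting import plot_index_distribution
        return plot_index_distribution(self, ax=ax)


class ThermometryAssay:
    """One study's raw inputs plus configuration; ``fit()`` analyses it."""

    def __init__(
        self,
        traces: list[FluorescenceTrace],
        layout: pd.DataFrame,
        metadata: pd.DataFrame,
        absorbance: list[AbsorbanceSet],
        densitometry: pd.DataFrame | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.traces = traces
        self.layout = layout
        self.metadata = metadata
        self.absorbance = absorbance
        self.densitometry = densitometry
        self.config = config or RunConfig()
        self._validate_cross_references()

    def _validate_cross_references(self) -> None:
        layout_preps = set(self.layout["preparation_id"].astype(str))
        meta_preps = set(self.metadata["preparation_id"].astype(str))
        dangling = layout_preps - meta_preps
        if dangling:
            raise qio.ValidationError(
                f"layout preparations missing from metadata: {sorted(dangling)}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_csv_dir(cls, path: str | Path,
                     config: RunConfig | None = None) -> "ThermometryAssay":
        """Load ``kinetics.csv``, ``layout.csv``, ``metadata.csv``,
        ``a280.csv`` and (optionally) ``densitometry.csv`` from a directory."""
        p = Path(path)
        layout = qio.read_layout(p / "layout.csv")
        metadata = qio.read_metadata(p / "metadata.csv")
        traces = qio.read_kinetic_table(p / "kinetics.csv", layout)
        absorbance = qio.read_a280_table(p / "a280.csv")
        densi_path = p / "densitometry.csv"
        densitometry = (qio.read_densitometry_table(densi_path)
                        if densi_path.exists() else None)
        return cls(traces, layout, metadata, absorbance, densitometry, config)

    @classmethod
    def from_synthetic(cls, dataset,
                       config: RunConfig | None = None) -> "ThermometryAssay":
        """Build directly from an in-memory synthetic dataset."""
        from .io import read_a280_table
        layout = qio.read_layout(_as_buffer(dataset.layout))
        metadata = qio.read_metadata(_as_buffer(dataset.metadata))
        times = dataset.kinetics["time_s"].to_numpy(dtype=float)
        times = times - times[0]
        layout_idx = layout.set_index("well_id")
        traces = [
            FluorescenceTrace(
                well_id=col,
                times=times.copy(),
                intensities=dataset.kinetics[col].to_numpy(dtype=float),
                condition=str(layout_idx.loc[col, "condition"]),
                preparation_id=str(layout_idx.loc[col, "preparation_id"]),
            )
            for col in dataset.kinetics.columns if col != "time_s"
        ]
        absorbance = read_a280_table(_as_buffer(dataset.a280))
        densitometry = qio.read_densitometry_table(
            _as_buffer(dataset.densitometry))
        return cls(traces, layout, metadata, absorbance, densitometry, config)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> ThermometryResults:
        cfg = self.config
        warnings: list[str] = []

        rates = [initial_rate_of(tr, cfg) for tr in self.traces]

        protein = quantify_a280(self.absorbance, cfg)
        conc_by_sample = {p.sample_id: p for p in protein if p.role == "sample"}
        if any(not p.qc_pass for p in protein):
            warnings.append("A280 batch flagged by internal-control QC")

        meta = self.metadata.set_index("preparation_id")
        pairs = pair_blanks(self.layout, rates)

        records: list[EfficiencyRecord] = []
        for prep, (atp_pairs, blank_rate) in pairs.items():
            if prep not in conc_by_sample:
                raise PipelineError(
                    f"preparation {prep}: no A280 sample measurement")
            conc = effective_concentration(
                conc_by_sample[prep], float(meta.loc[prep, "dilution_factor"]))
            if conc <= 0:
                raise PipelineError(
                    f"preparation {prep}: non-positive effective concentration")
            animal = str(meta.loc[prep, "animal_id"])
            group = str(meta.loc[prep, "group"])
            indices = [efficiency_index(atp, blank_rate, conc)
                       for _, _, atp in atp_pairs]
            statuses = qc_filter(indices, cfg.sd_multiplier)
            for (rep, well, atp), idx, status in zip(atp_pairs, indices,
                                                     statuses):
                records.append(EfficiencyRecord(
                    preparation_id=prep, replicate_index=rep,
                    atp_rate=atp, blank_rate=blank_rate,
                    concentration_mg_per_ml=conc, efficiency_index=idx,
                    qc_status=status, animal_id=animal, group=group,
                    well_id=well))

        # isoform strata
        prep_ids = sorted(pairs)
        compositions: dict[str, IsoformComposition] = {}
        if self.densitometry is not None and len(self.densitometry):
            wide = self.densitometry.pivot_table(
                index="preparation_id", columns="band", values="volume",
                aggfunc="first").fillna(0.0)
            for prep, row in wide.iterrows():
                compositions[str(prep)] = isoform_fractions(
                    str(prep), float(row.get("MyHC_I", 0.0)),
                    float(row.get("MyHC_IIa", 0.0)))
            strata, strat_warnings = stratify(
                compositions, prep_ids, cfg.iia_stratify_threshold,
                cfg.missing_composition_policy)
            warnings.extend(strat_warnings)
        else:
            strata = {prep: MAIN for prep in prep_ids}

        for rec in records:
            rec.stratum = strata.get(rec.preparation_id, "")

        preparations, animals, group_summaries = aggregate(records, strata)
        for ps in preparations:
            if ps.failed:
                warnings.append(
                    f"preparation {ps.preparation_id}: all replicates excluded")

        comparison = self._compare_groups(animals, warnings)

        return ThermometryResults(
            config=cfg, rates=rates, protein=protein, records=records,
            preparations=preparations, animals=animals,
            group_summaries=group_summaries, comparison=comparison,
            compositions=compositions, strata=strata, warnings=warnings)

    def _compare_groups(self, animals: list[AnimalSummary],
                        warnings: list[str]) -> GroupComparison | None:
        """Main-stratum CON vs EXP test over per-animal means."""
        excluded_animals: set[str] = set()
        if self.config.exclude_whole_animal_high_iia:
            excluded_animals = {a.animal_id for a in animals
                                if a.stratum == HIGH_IIA}
        values = {"CON": [], "EXP": []}
        for a in animals:
            if a.stratum == MAIN and a.animal_id not in excluded_animals:
                values[a.group].append(a.mean_index)
        if len(values["CON"]) < 2 or len(values["EXP"]) < 2:
            warnings.append(
                "fewer than 2 animals per group in the main stratum; "
                "no group comparison")
            return None
        return t_test_values(values["CON"], values["EXP"],
                             group_a="CON", group_b="EXP")


def _as_buffer(df: pd.DataFrame):
    import io as _stdio
    buf = _stdio.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf
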