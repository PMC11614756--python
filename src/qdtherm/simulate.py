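"""Synthetic thermometry studies with recorded ground truth.

Every stage of the pipeline can be exercised without lab data: the
generator draws a full study — kinetic plate table, plate layout, sample
metadata, A280 readings, MyHC densitometry — from a hierarchical model
whose defaults mirror the study conditions (5 CON vs 5 EXP animals,
sextuplicate wells with paired 0 mM ATP blanks, readings every 5 s for
2 min, group efficiency indices 0.47 +/- 0.25 vs 1.47 +/- 0.44 over
animal means).

Relative fluorescence follows the negative hyperbola F(t) = 1/(1 + rho t),
whose t = 0 derivative is exactly -rho, so the true initial decay rate of
every well is analytic and independent of any estimator.  Additive
Gaussian noise is two-regime: small before 20 s (the reproducible early
window) and larger after.  Index variance is partitioned between animals
and replicates so that the dispersion of animal means matches the
configured group SD: with animal fraction f of the variance,
sigma_animal = sqrt(f) * sigma_group and the within-preparation replicate
SD is sqrt(n_rep * (1 - f)) * sigma_group.

Ground truth (true rates, concentrations, per-animal indices, isoform
fractions, planted anomalies) is returned beside the tables so recovery
and QC precision/recall are computable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "AnomalySpec",
    "GroundTruth",
    "SyntheticDataset",
    "SimulationError",
    "generate_study",
    "inject_qc_anomalies",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the study's own conditions."""

    n_animals_per_group: int = 5
    preps_per_animal: int = 1
    replicates: int = 6
    group_index_means: tuple[float, float] = (0.47, 1.47)   # (CON, EXP)
    group_index_sds: tuple[float, float] = (0.25, 0.44)     # over animal means
    animal_sd_fraction: float = 0.8   # fraction of index VARIANCE between animals
    blank_rate_mean: float = 2e-4     # 1/s, non-enzymatic drift
    concentration_mean_mg_per_ml: float = 2.0   # A280 stock concentration
    concentration_cv: float = 0.10
    dilution_factor: float = 1000.0   # stock -> in-well effective concentration
    noise_sd_early: float = 0.002     # relative-intensity units, t <= boundary
    noise_sd_late: float = 0.010      # t > boundary
    noise_boundary_s: float = 20.0
    n_timepoints: int = 25
    interval_s: float = 5.0
    iia_fraction_main: float = 0.03
    iia_fraction_high: float = 0.25
    n_high_iia_animals: int = 0       # EXP animals given a high-IIa composition
    a280_blank_au: float = 0.05
    a280_reading_sd: float = 0.01
    raw_scale_range: tuple[float, float] = (2e4, 6e4)  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1 or self.preps_per_animal < 1:
            raise SimulationError("need >= 1 animal and >= 1 prep per animal")
        if self.replicates < 2:
            raise SimulationError("need >= 2 replicates for QC")
        if self.noise_sd_late < self.noise_sd_early:
            raise SimulationError("late-window noise must be >= early noise")
        if min(self.group_index_sds) < 0 or min(self.noise_sd_early,
                                                self.noise_sd_late) < 0:
            raise SimulationError("standard deviations must be >= 0")
        if min(self.group_index_means) < 0:
            raise SimulationError("group index means imply negative rates")
        if self.blank_rate_mean < 0:
            raise SimulationError("blank rate must be >= 0")
        if self.concentration_mean_mg_per_ml <= 0 or self.dilution_factor <= 0:
            raise SimulationError("concentrations must be positive")
        if not 0.0 < self.animal_sd_fraction <= 1.0:
            raise SimulationError("animal_sd_fraction must be in (0, 1]")
        if self.n_high_iia_animals > self.n_animals_per_group:
            raise SimulationError("more high-IIa animals than EXP animals")

    @property
    def effective_concentration(self) -> float:
        return self.concentration_mean_mg_per_ml / self.dilution_factor

    def within_prep_sd(self, group_sd: float) -> float:
        """Replicate-level index SD making animal-mean dispersion = group SD."""
        f = self.animal_sd_fraction
        return group_sd * np.sqrt(self.replicates * (1.0 - f))

    def animal_sd(self, group_sd: float) -> float:
        return group_sd * np.sqrt(self.animal_sd_fraction)


@dataclass(frozen=True)
class AnomalySpec:
    """Planted QC anomalies per preparation (recorded in the truth ledger)."""

    n_negative: int = 0
    n_outlier: int = 0
    outlier_scale: float = 10.0     # outlier index = scale x group mean
    negative_magnitude: float = 0.5  # negative index = -magnitude x group mean


@dataclass
class GroundTruth:
    """True quantities behind a synthetic study.

    ``replicates``: one row per ATP well (true rates, concentration,
    index, planted anomaly tag).  ``animals``: latent per-animal index.
    ``preparations``: stock concentration, blank rate, IIa fraction.
    """

    replicates: pd.DataFrame
    animals: pd.DataFrame
    preparations: pd.DataFrame


@dataclass
class SyntheticDataset:
    """A complete in-memory study in the pipeline's table schemas."""

    config: SyntheticConfig
    kinetics: pd.DataFrame       # wide: time_s + one column per well
    layout: pd.DataFrame
    metadata: pd.DataFrame
    a280: pd.DataFrame           # long
    densitometry: pd.DataFrame
    truth: GroundTruth

    def scale_intensities(self, k: float) -> "SyntheticDataset":
        """Return a copy with all raw fluorescence multiplied by k > 0."""
        if k <= 0:
            raise SimulationError("scale factor must be positive")
        kin = self.kinetics.copy()
        for col in kin.columns:
            if col != "time_s":
                kin[col] = kin[col] * k
        return replace(self, kinetics=kin)

    def write(self, out_dir: str | Path) -> None:
        """Write the five CSV tables (deterministic formatting)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kwargs = dict(index=False, float_format="%.17g")
        self.kinetics.to_csv(out / "kinetics.csv", **kwargs)
        self.layout.to_csv(out / "layout.csv", **kwargs)
        self.metadata.to_csv(out / "metadata.csv", **kwargs)
        self.a280.to_csv(out / "a280.csv", **kwargs)
        self.densitometry.to_csv(out / "densitometry.csv", **kwargs)


def _hyperbola(t: np.ndarray, rho: float) -> np.ndarray:
    denom = 1.0 + rho * t
    if np.any(denom <= 0.05):
        raise SimulationError(
            f"decay rate {rho} implies non-physical fluorescence over the window")
    return 1.0 / denom


def _well_trace(rng: np.random.Generator, t: np.ndarray, rho: float,
                cfg: SyntheticConfig) -> np.ndarray:
    scale = rng.uniform(*cfg.raw_scale_range)
    sd = np.where(t <= cfg.noise_boundary_s, cfg.noise_sd_early,
                  cfg.noise_sd_late)
    rel = _hyperbola(t, rho) + rng.normal(0.0, 1.0, len(t)) * sd
    return np.maximum(rel, 1e-6) * scale


def generate_study(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw one complete synthetic study, reproducible from its seed."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_timepoints, dtype=float) * cfg.interval_s

    kinetics: dict[str, np.ndarray] = {"time_s": t}
    layout_rows, meta_rows, a280_rows, densi_rows = [], [], [], []
    rep_rows, animal_rows, prep_rows = [], [], []

    groups = ("CON", "EXP")
    for gi, group in enumerate(groups):
        mu = cfg.group_index_means[gi]
        sg = cfg.group_index_sds[gi]
        sa, sw = cfg.animal_sd(sg), cfg.within_prep_sd(sg)
        for ai in range(cfg.n_animals_per_group):
            animal_id = f"{group}{ai + 1:02d}"
            high_iia = group == "EXP" and ai < cfg.n_high_iia_animals
            animal_index = rng.normal(mu, sa)
            animal_rows.append({
                "animal_id": animal_id, "group": group,
                "true_index": animal_index, "high_iia": high_iia,
            })
            for pi in range(cfg.preps_per_animal):
                prep_id = f"{animal_id}P{pi + 1}"
                stock = max(rng.normal(cfg.concentration_mean_mg_per_ml,
                                       cfg.concentration_cv
                                       * cfg.concentration_mean_mg_per_ml),
                            0.1 * cfg.concentration_mean_mg_per_ml)
                conc_eff = stock / cfg.dilution_factor
                rho_blank = max(rng.normal(cfg.blank_rate_mean,
                                           0.1 * cfg.blank_rate_mean), 0.0) \
                    if cfg.blank_rate_mean > 0 else 0.0
                if high_iia:
                    frac_iia = float(np.clip(
                        rng.normal(cfg.iia_fraction_high, 0.10), 0.12, 0.45))
                else:
                    frac_iia = float(np.clip(
                        rng.normal(cfg.iia_fraction_main, 0.01), 0.0, 0.05))
                prep_rows.append({
                    "preparation_id": prep_id, "animal_id": animal_id,
                    "group": group, "true_stock_mg_per_ml": stock,
                    "true_blank_rate": rho_blank, "fraction_IIa": frac_iia,
                })
                meta_rows.append({
                    "preparation_id": prep_id, "animal_id": animal_id,
                    "group": group, "dilution_factor": cfg.dilution_factor,
                })

                rep_indices = rng.normal(animal_index, sw, cfg.replicates)
                for r in range(1, cfg.replicates + 1):
                    idx = rep_indices[r - 1]
                    rho_atp = rho_blank + idx * conc_eff
                    well = f"{prep_id}-ATP{r}"
                    kinetics[well] = _well_trace(rng, t, rho_atp, cfg)
                    layout_rows.append({
                        "well_id": well, "preparation_id": prep_id,
                        "condition": "ATP", "replicate_index": r,
                    })
                    rep_rows.append({
                        "preparation_id": prep_id, "replicate_index": r,
                        "well_id": well, "true_rho_atp": rho_atp,
                        "true_rho_blank": rho_blank,
                        "true_concentration_mg_per_ml": conc_eff,
                        "true_index": idx, "planted": "",
                    })
                for r in range(1, cfg.replicates + 1):
                    well = f"{prep_id}-BLANK{r}"
                    kinetics[well] = _well_trace(rng, t, rho_blank, cfg)
                    layout_rows.append({
                        "well_id": well, "preparation_id": prep_id,
                        "condition": "BLANK", "replicate_index": r,
                    })

                # A280: 3 repeats of stock reading above the buffer blank
                for rep in range(1, 4):
                    a280_rows.append({
                        "sample_id": prep_id, "role": "sample",
                        "nominal_mg_per_ml": "",
                        "a280_reading": stock + cfg.a280_blank_au
                        + rng.normal(0.0, cfg.a280_reading_sd),
                        "repeat_index": rep,
                    })
                total_volume = rng.uniform(800.0, 1200.0)
                densi_rows.append({
                    "preparation_id": prep_id, "band": "MyHC_I",
                    "volume": total_volume * (1.0 - frac_iia),
                })
                densi_rows.append({
                    "preparation_id": prep_id, "band": "MyHC_IIa",
                    "volume": total_volume * frac_iia,
                })

    # shared batch controls: one buffer blank, BSA internal controls 1-4 mg/mL
    for rep in range(1, 4):
        a280_rows.append({
            "sample_id": "buffer_blank", "role": "blank",
            "nominal_mg_per_ml": "",
            "a280_reading": cfg.a280_blank_au
            + rng.normal(0.0, cfg.a280_reading_sd / 5.0),
            "repeat_index": rep,
        })
    for nominal in (1.0, 2.0, 3.0, 4.0):
        for rep in range(1, 4):
            a280_rows.append({
                "sample_id": f"bsa_{nominal:g}", "role": "bsa_control",
                "nominal_mg_per_ml": nominal,
                "a280_reading": nominal + cfg.a280_blank_au
                + rng.normal(0.0, cfg.a280_reading_sd),
                "repeat_index": rep,
            })

    truth = GroundTruth(
        replicates=pd.DataFrame(rep_rows),
        animals=pd.DataFrame(animal_rows),
        preparations=pd.DataFrame(prep_rows),
    )
    return SyntheticDataset(
        config=cfg,
        kinetics=pd.DataFrame(kinetics),
        layout=pd.DataFrame(layout_rows),
        metadata=pd.DataFrame(meta_rows),
        a280=pd.DataFrame(a280_rows),
        densitometry=pd.DataFrame(densi_rows),
        truth=truth,
    )


def inject_qc_anomalies(
    dataset: SyntheticDataset,
    spec: AnomalySpec,
    seed: int | None = None,
) -> SyntheticDataset:
    """Plant negative-rate replicates and extreme outliers in every prep.

    The last ``n_negative`` replicate wells of each preparation are
    regenerated as null reactions (net rate below the blank), and the
    ``n_outlier`` wells before them as extreme fast reactions.  Planted
    wells are tagged in ``truth.replicates['planted']`` so the QC filter's
    recall is measurable.  At least two untouched replicates must remain.
    """
    cfg = dataset.config
    n_planted = spec.n_negative + spec.n_outlier
    if n_planted == 0:
        return dataset
    if n_planted > cfg.replicates - 2:
        raise SimulationError(
            f"cannot plant {n_planted} anomalies in {cfg.replicates} replicates "
            f"(need >= 2 untouched)")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    t = dataset.kinetics["time_s"].to_numpy()

    kin = dataset.kinetics.copy()
    reps = dataset.truth.replicates.copy().set_index(
        ["preparation_id", "replicate_index"])
    preps = dataset.truth.preparations.set_index("preparation_id")
    group_mean = dict(zip(("CON", "EXP"), cfg.group_index_means))

    for prep_id, prow in preps.iterrows():
        mu = group_mean[prow["group"]]
        targets = list(range(cfg.replicates, cfg.replicates - n_planted, -1))
        neg_targets = targets[: spec.n_negative]
        out_targets = targets[spec.n_negative:]
        for r in neg_targets + out_targets:
            key = (prep_id, r)
            conc = reps.loc[key, "true_concentration_mg_per_ml"]
            rho_blank = reps.loc[key, "true_rho_blank"]
            if r in neg_targets:
                idx = -spec.negative_magnitude * mu
                tag = "negative"
            else:
                idx = spec.outlier_scale * mu
                tag = "outlier"
            rho = rho_blank + idx * conc
            well = reps.loc[key, "well_id"]
            kin[well] = _well_trace(rng, t, rho, cfg)
            reps.loc[key, ["true_rho_atp", "true_index", "planted"]] = \
                [rho, idx, tag]

    truth = GroundTruth(
        replicates=reps.reset_index(),
        animals=dataset.truth.animals.copy(),
        preparations=dataset.truth.preparations.copy(),
    )
    return replace(dataset, kinetics=kin, truth=truth)
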