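"""A280 protein quantification with blank and BSA internal-control QC.

Total extracted protein is quantified by absorbance at 280 nm without a
standard curve: concentration = (mean reading - blank mean) x factor.  A
blank set (extraction buffer only) and optional BSA internal controls at
known concentrations travel with every batch; a control whose recovered
concentration strays from nominal flags the whole batch.  The extracted
myosin is assumed proportional to total extracted protein, so this total
concentration is the value the pipeline normalises rates by — never a
myosin-specific amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

import numpy as np

from .config import RunConfig

__all__ = [
    "AbsorbanceSet",
    "ProteinQuantResult",
    "ProteinQuantError",
    "quantify_a280",
    "effective_concentration",
]

ROLES = ("sample", "blank", "bsa_control")


class ProteinQuantError(ValueError):
    pass


@dataclass(frozen=True)
class AbsorbanceSet:
    """Repeated A280 readings for one sample, blank, or BSA control."""

    sample_id: str
    role: str
    readings: tuple[float, ...]
    nominal_mg_per_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ProteinQuantError(
                f"{self.sample_id}: role must be one of {ROLES}, got {self.role!r}")
        if len(self.readings) < 3:
            raise ProteinQuantError(
                f"{self.sample_id}: at least 3 repeated readings required, "
                f"got {len(self.readings)}")
        if not all(np.isfinite(self.readings)):
            raise ProteinQuantError(f"{self.sample_id}: non-finite reading")
        if self.role == "bsa_control" and self.nominal_mg_per_ml <= 0:
            raise ProteinQuantError(
                f"{self.sample_id}: BSA control needs a positive nominal concentration")


@dataclass
class ProteinQuantResult:
    """Blank-corrected concentration for one sample with its QC verdict."""

    sample_id: str
    role: str
    concentration_mg_per_ml: float
    reading_cv: float
    blank_mean: float
    qc_pass: bool
    qc_notes: list[str] = field(default_factory=list)
    recovery: float | None = None  # BSA controls only: measured / nominal


def quantify_a280(
    samples: list[AbsorbanceSet],
    config: RunConfig | None = None,
) -> list[ProteinQuantResult]:
    """Convert a batch of absorbance sets to concentrations.

    Exactly one blank set must be present; its mean reading is subtracted
    from every other set before applying the conversion factor.  Negative
    blank-corrected means clamp to zero with a note.  BSA controls are
    checked for recovery within ``config.bsa_recovery_tolerance``; one
    failing control marks every result in the batch ``qc_pass = False``
    (results are still returned, flagged, never silently dropped).
    """
    config = config or RunConfig()
    blanks = [s for s in samples if s.role == "blank"]
    if len(blanks) != 1:
        raise ProteinQuantError(
            f"exactly one blank set required, found {len(blanks)}")
    blank_mean = fmean(blanks[0].readings)

    results: list[ProteinQuantResult] = []
    batch_notes: list[str] = []
    for s in samples:
        if s.role == "blank":
            continue
        mean = fmean(s.readings)
        sd = float(np.std(s.readings, ddof=1))
        cv = 0.0 if mean == 0 else abs(sd / mean)
        corrected = mean - blank_mean
        notes: list[str] = []
        if corrected < 0:
            notes.append("negative_blank_corrected_mean_clamped_to_zero")
            corrected = 0.0
        conc = corrected * config.a280_factor_mg_per_ml_per_AU
        if cv > config.cv_warn_threshold:
            notes.append(f"reading_cv_{cv:.3f}_exceeds_{config.cv_warn_threshold}")
        res = ProteinQuantResult(
            sample_id=s.sample_id,
            role=s.role,
            concentration_mg_per_ml=conc,
            reading_cv=cv,
            blank_mean=blank_mean,
            qc_pass=True,
            qc_notes=notes,
        )
        if s.role == "bsa_control":
            res.recovery = conc / s.nominal_mg_per_ml
            if abs(res.recovery - 1.0) > config.bsa_recovery_tolerance:
                res.qc_pass = False
                res.qc_notes.append(
                    f"bsa_recovery_{res.recovery:.3f}_outside_tolerance")
                batch_notes.append(
                    f"bsa_control_{s.sample_id}_failed_recovery")
        results.append(res)

    if batch_notes:
        for res in results:
            res.qc_pass = False
            for note in batch_notes:
                if note not in res.qc_notes:
                    res.qc_notes.append(note)
    return results


def effective_concentration(
    result: ProteinQuantResult, dilution_factor: float
) -> float:
    """Concentration actually present in the assay well.

    ``dilution_factor`` f >= 1 means the stock was diluted f-fold between
    the A280 measurement and the reaction well; this diluted value is what
    rates are normalised by.
    """
    if dilution_factor <= 0:
        raise ProteinQuantError(
            f"dilution_factor must be positive, got {dilution_factor}")
    return result.concentration_mg_per_ml / dilution_factor
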