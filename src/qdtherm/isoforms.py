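"""Myosin heavy chain isoform composition and stratification.

Soleus preparations are dominated by the slow type I MyHC isoform, with a
small type IIa fraction; fast isoforms hydrolyse ATP with less heat per
unit myosin, so preparations with an unusually high IIa content are
analysed as a separate stratum rather than diluting the main group
comparison.  Band volumes come from gel densitometry; only the two
resolved bands (I, IIa) enter the model, so the two fractions sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "IsoformComposition",
    "IsoformError",
    "isoform_fractions",
    "stratify",
    "MAIN",
    "HIGH_IIA",
]

MAIN = "main"
HIGH_IIA = "high_IIa"


class IsoformError(ValueError):
    pass


@dataclass(frozen=True)
class IsoformComposition:
    preparation_id: str
    fraction_I: float
    fraction_IIa: float

    def __post_init__(self) -> None:
        for name, frac in (("fraction_I", self.fraction_I),
                           ("fraction_IIa", self.fraction_IIa)):
            if not 0.0 <= frac <= 1.0:
                raise IsoformError(
                    f"{self.preparation_id}: {name}={frac} outside [0, 1]")
        if abs(self.fraction_I + self.fraction_IIa - 1.0) > 1e-9:
            raise IsoformError(
                f"{self.preparation_id}: fractions must sum to 1")


def isoform_fractions(
    preparation_id: str, volume_I: float, volume_IIa: float
) -> IsoformComposition:
    """Relative isoform content from densitometric band volumes."""
    if volume_I < 0 or volume_IIa < 0:
        raise IsoformError(f"{preparation_id}: band volumes must be >= 0")
    total = volume_I + volume_IIa
    if total == 0:
        raise IsoformError(f"{preparation_id}: all band volumes are zero")
    return IsoformComposition(
        preparation_id=preparation_id,
        fraction_I=volume_I / total,
        fraction_IIa=volume_IIa / total,
    )


def stratify(
    compositions: Mapping[str, IsoformComposition],
    preparation_ids: list[str],
    threshold: float,
    missing_policy: str = "exclude",
) -> tuple[dict[str, str], list[str]]:
    """Assign each preparation to the main or high-IIa stratum.

    A preparation is ``high_IIa`` iff its IIa fraction strictly exceeds
    ``threshold`` (a composition exactly at the threshold stays main).
    Returns ``(strata, warnings)``; a preparation without densitometry is
    dropped with a warning under the default policy, or assumed main
    under ``missing_policy="main"``.
    """
    if not 0.0 < threshold < 1.0:
        raise IsoformError(f"threshold must be in (0, 1), got {threshold}")
    strata: dict[str, str] = {}
    warnings: list[str] = []
    for prep in preparation_ids:
        comp = compositions.get(prep)
        if comp is None:
            if missing_policy == "main":
                strata[prep] = MAIN
                warnings.append(f"{prep}: no composition; assumed main stratum")
            else:
                warnings.append(f"{prep}: no composition; excluded from strata")
            continue
        strata[prep] = HIGH_IIA if comp.fraction_IIa > threshold else MAIN
    return strata, warnings
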