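"""Reading and writing the assay's tabular formats.

All inputs are comma-separated UTF-8 with a header row: a *wide* kinetics
table (column ``time_s`` plus one column per well), and *long* tables for
the plate layout, sample metadata, A280 absorbance readings and MyHC
densitometry volumes.  Results go out as a TSV with one row per replicate
(QC flag and exclusion reason included) followed by summary blocks.

Validation is total: any malformed input raises :class:`ValidationError`
naming the offending row or field; a partially-parsed dataset is never
returned.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import FluorescenceTrace
from .protein import AbsorbanceSet

__all__ = [
    "ValidationError",
    "read_layout",
    "read_metadata",
    "read_kinetic_table",
    "read_a280_table",
    "read_densitometry_table",
    "write_results",
    "read_results",
]

CONDITIONS = ("ATP", "BLANK")
GROUPS = ("CON", "EXP")
LAYOUT_COLUMNS = ["well_id", "preparation_id", "condition", "replicate_index"]
METADATA_COLUMNS = ["preparation_id", "animal_id", "group", "dilution_factor"]
A280_COLUMNS = ["sample_id", "role", "nominal_mg_per_ml", "a280_reading",
                "repeat_index"]
DENSITOMETRY_COLUMNS = ["preparation_id", "band", "volume"]
BANDS = ("MyHC_I", "MyHC_IIa")


class ValidationError(ValueError):
    """A malformed input table; the message names the offending row/field."""


def _read_csv(source, required: list[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(source, float_precision="round_trip")
    except Exception as exc:  # surface the parser's complaint with context
        raise ValidationError(f"{what}: could not parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# layout / metadata


def read_layout(source) -> pd.DataFrame:
    """Read and validate the plate layout (well -> preparation/condition).

    Enforces: unique well ids, conditions in {ATP, BLANK}, integer
    replicate indices >= 1 unique within (preparation, condition), and at
    least one blank well for every preparation that has ATP wells.
    """
    df = _read_csv(source, LAYOUT_COLUMNS, "layout")
    df = df[LAYOUT_COLUMNS].copy()
    df["well_id"] = df["well_id"].astype(str)
    df["preparation_id"] = df["preparation_id"].astype(str)

    dupes = df["well_id"][df["well_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"layout: duplicate well_id {list(dupes)}")
    bad = df.loc[~df["condition"].isin(CONDITIONS), "well_id"]
    if len(bad):
        raise ValidationError(
            f"layout: condition must be ATP or BLANK (wells {list(bad)})")
    try:
        df["replicate_index"] = df["replicate_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"layout: non-integer replicate_index ({exc})")
    if (df["replicate_index"] < 1).any():
        bad = df.loc[df["replicate_index"] < 1, "well_id"]
        raise ValidationError(f"layout: replicate_index < 1 (wells {list(bad)})")
    dup_rep = df.duplicated(["preparation_id", "condition", "replicate_index"])
    if dup_rep.any():
        rows = df.loc[dup_rep, ["preparation_id", "condition", "replicate_index"]]
        raise ValidationError(
            f"layout: duplicate replicate_index within preparation/condition:\n"
            f"{rows.to_string(index=False)}")
    by_prep = df.groupby("preparation_id")["condition"]
    for prep, conds in by_prep:
        if "ATP" in set(conds) and "BLANK" not in set(conds):
            raise ValidationError(
                f"layout: preparation {prep} has ATP wells but no BLANK well")
    return df.reset_index(drop=True)


def read_metadata(source) -> pd.DataFrame:
    """Read and validate sample metadata (preparation -> animal -> group)."""
    df = _read_csv(source, METADATA_COLUMNS, "metadata")
    df = df[METADATA_COLUMNS].copy()
    df["preparation_id"] = df["preparation_id"].astype(str)
    df["animal_id"] = df["animal_id"].astype(str)

    dupes = df["preparation_id"][df["preparation_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"metadata: duplicate preparation_id {list(dupes)}")
    bad = df.loc[~df["group"].isin(GROUPS), "preparation_id"]
    if len(bad):
        raise ValidationError(
            f"metadata: group must be CON or EXP (preparations {list(bad)})")
    multi = df.groupby("animal_id")["group"].nunique()
    conflicted = multi[multi > 1].index.tolist()
    if conflicted:
        raise ValidationError(
            f"metadata: animal(s) {conflicted} assigned to more than one group")
    df["dilution_factor"] = pd.to_numeric(df["dilution_factor"], errors="coerce")
    if df["dilution_factor"].isna().any() or (df["dilution_factor"] <= 0).any():
        bad = df.loc[df["dilution_factor"].isna() | (df["dilution_factor"] <= 0),
                     "preparation_id"]
        raise ValidationError(
            f"metadata: dilution_factor must be a positive number "
            f"(preparations {list(bad)})")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# kinetics


def _detect_duplicate_headers(source) -> None:
    """pandas silently mangles duplicate column names; catch them here."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            header = next(csv.reader(fh), [])
    elif hasattr(source, "read"):
        pos = source.tell()
        header = next(csv.reader(source), [])
        source.seek(pos)
    else:
        return
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ValidationError(f"kinetics: duplicate well column {name!r}")
        seen.add(name)


def read_kinetic_table(source, layout: pd.DataFrame) -> list[FluorescenceTrace]:
    """Read a wide kinetics table into one trace per well column.

    The table must carry a ``time_s`` column with strictly increasing
    times; times are re-based so the first reading is t = 0.  Every well
    column must appear in the layout and every cell must be numeric.
    """
    _detect_duplicate_headers(source)
    df = _read_csv(source, ["time_s"], "kinetics")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    if times.isna().any():
        row = int(times.index[times.isna()][0])
        raise ValidationError(f"kinetics: non-numeric time_s at row {row}")
    times = times.to_numpy(dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValidationError("kinetics: time_s must be strictly increasing")
    times = times - times[0]

    layout_map = layout.set_index("well_id")
    wells = [c for c in df.columns if c != "time_s"]
    unknown = [w for w in wells if w not in layout_map.index]
    if unknown:
        raise ValidationError(f"kinetics: wells {unknown} absent from layout")

    traces: list[FluorescenceTrace] = []
    for well in wells:
        col = pd.to_numeric(df[well], errors="coerce")
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise ValidationError(
                f"kinetics: non-numeric value at row {row}, column {well!r}")
        info = layout_map.loc[well]
        traces.append(FluorescenceTrace(
            well_id=well,
            times=times.copy(),
            intensities=col.to_numpy(dtype=float),
            condition=str(info["condition"]),
            preparation_id=str(info["preparation_id"]),
        ))
    return traces


# ---------------------------------------------------------------------------
# A280 / densitometry


def read_a280_table(source) -> list[AbsorbanceSet]:
    """Read long-format A280 readings into per-sample absorbance sets."""
    df = _read_csv(source, A280_COLUMNS, "a280")
    df["a280_reading"] = pd.to_numeric(df["a280_reading"], errors="coerce")
    if df["a280_reading"].isna().any():
        row = int(df.index[df["a280_reading"].isna()][0])
        raise ValidationError(f"a280: non-numeric a280_reading at row {row}")
    sets: list[AbsorbanceSet] = []
    for (sample_id, role), grp in df.groupby(["sample_id", "role"], sort=False):
        nominal = pd.to_numeric(grp["nominal_mg_per_ml"], errors="coerce")
        nominal_val = float(nominal.iloc[0]) if nominal.notna().any() else 0.0
        grp = grp.sort_values("repeat_index")
        sets.append(AbsorbanceSet(
            sample_id=str(sample_id),
            role=str(role),
            readings=tuple(float(x) for x in grp["a280_reading"]),
            nominal_mg_per_ml=nominal_val,
        ))
    return sets


def read_densitometry_table(source) -> pd.DataFrame:
    """Read MyHC band volumes (long format, bands MyHC_I / MyHC_IIa)."""
    df = _read_csv(source, DENSITOMETRY_COLUMNS, "densitometry")
    df = df[DENSITOMETRY_COLUMNS].copy()
    df["preparation_id"] = df["preparation_id"].astype(str)
    bad = df.loc[~df["band"].isin(BANDS), "preparation_id"]
    if len(bad):
        raise ValidationError(
            f"densitometry: band must be in {BANDS} (preparations {list(bad)})")
    df["volume"] = pd.to_numeric(df["volume"], errors="coerce")
    if df["volume"].isna().any() or (df["volume"] < 0).any():
        bad = df.loc[df["volume"].isna() | (df["volume"] < 0), "preparation_id"]
        raise ValidationError(
            f"densitometry: volume must be a number >= 0 "
            f"(preparations {list(bad)})")
    dup = df.duplicated(["preparation_id", "band"])
    if dup.any():
        raise ValidationError(
            f"densitometry: duplicate band rows for "
            f"{df.loc[dup, 'preparation_id'].tolist()}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# results


RESULT_COLUMNS = [
    "record_type", "preparation_id", "animal_id", "group", "stratum",
    "replicate_index", "atp_rate_per_s", "blank_rate_per_s", "net_rate_per_s",
    "concentration_mg_per_ml", "efficiency_index", "qc_status", "n",
    "mean_index", "sd_index", "t_statistic", "degrees_of_freedom",
    "p_two_sided", "notes",
]


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if isinstance(x, float):
        return repr(x)  # shortest round-trippable representation
    return str(x)


def write_results(results, dest) -> None:
    """Write replicate rows plus preparation/animal/group summary blocks.

    ``results`` is a :class:`~qdtherm.model.ThermometryResults`; column
    order is fixed and floats use shortest round-trip formatting so a
    re-read preserves every value bit for bit and re-runs are
    byte-identical.
    """
    rows: list[dict] = []
    for rec in results.records:
        rows.append({
            "record_type": "replicate",
            "preparation_id": rec.preparation_id,
            "animal_id": rec.animal_id,
            "group": rec.group,
            "stratum": rec.stratum,
            "replicate_index": rec.replicate_index,
            "atp_rate_per_s": rec.atp_rate,
            "blank_rate_per_s": rec.blank_rate,
            "net_rate_per_s": rec.net_rate,
            "concentration_mg_per_ml": rec.concentration_mg_per_ml,
            "efficiency_index": rec.efficiency_index,
            "qc_status": rec.qc_status,
            "notes": "",
        })
    for prep in results.preparations:
        rows.append({
            "record_type": "preparation_summary",
            "preparation_id": prep.preparation_id,
            "animal_id": prep.animal_id,
            "group": prep.group,
            "stratum": prep.stratum,
            "n": prep.n_included,
            "mean_index": prep.mean_index,
            "sd_index": prep.sd_index,
            "notes": "failed" if prep.failed else "",
        })
    for animal in results.animals:
        rows.append({
            "record_type": "animal_summary",
            "animal_id": animal.animal_id,
            "group": animal.group,
            "stratum": animal.stratum,
            "n": animal.n_preparations,
            "mean_index": animal.mean_index,
            "notes": "",
        })
    for gs in results.group_summaries:
        rows.append({
            "record_type": "group_summary",
            "group": gs.group,
            "stratum": gs.stratum,
            "n": gs.n_animals,
            "mean_index": gs.mean_index,
            "sd_index": gs.sd_index,
            "notes": "",
        })
    if results.comparison is not None:
        cmp_ = results.comparison
        rows.append({
            "record_type": "group_comparison",
            "group": f"{cmp_.group_a}_vs_{cmp_.group_b}",
            "stratum": "main",
            "t_statistic": cmp_.t_statistic,
            "degrees_of_freedom": cmp_.degrees_of_freedom,
            "p_two_sided": cmp_.p_two_sided,
            "notes": ";".join(cmp_.notes),
        })

    lines = ["\t".join(RESULT_COLUMNS)]
    for row in rows:
        lines.append("\t".join(_fmt(row.get(c)) for c in RESULT_COLUMNS))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        try:
            Path(dest).write_text(text, encoding="utf-8")
        except OSError as exc:
            raise ValidationError(f"could not write results to {dest}: {exc}")


def read_results(source) -> pd.DataFrame:
    """Re-read a results TSV (numeric fields restored to full precision)."""
    df = pd.read_csv(source, sep="\t", dtype={"notes": str},
                     float_precision="round_trip")
    return df
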