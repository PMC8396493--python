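"""Record CSV dialect and configuration files.

The record table is a wide CSV with one row per individual::

    individual_id,diet,tray,age_hatch,age_larva_end,age_proto_end,
    age_deuto_end,died_in_stage,sex,adult_death_age,eggs_day_1..eggs_day_K

Transition-age cells are empty from the first failed transition onward;
``eggs_day_d`` holds the egg count on adult-life day d−1 (females only,
empty otherwise).  K is the longest adult lifespan in the file.  Writing
then parsing a table reproduces the records exactly.

Cohort configurations are plain YAML: either a single mapping of
:class:`~cohortlife.synthetic_cohort.CohortConfig` fields or
``{"diets": [mapping, ...]}`` for a multi-diet experiment.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import InputError, ValidationError
from .records import IndividualRecord
from .synthetic_cohort import CohortConfig

AGE_COLUMNS = ("age_hatch", "age_larva_end", "age_proto_end", "age_deuto_end")
FIXED_COLUMNS = ("individual_id", "diet", "tray", *AGE_COLUMNS,
                 "died_in_stage", "sex", "adult_death_age")


def write_records(records: list[IndividualRecord], path) -> None:
    """Write a cohort (or multi-diet experiment) to the wide CSV dialect."""
    records = list(records)
    k = max((len(r.daily_eggs) for r in records), default=0)
    rows = []
    for r in records:
        row: dict = {
            "individual_id": r.individual_id,
            "diet": r.diet_label,
            "tray": r.tray_id,
            "died_in_stage": r.died_in_stage,
            "sex": r.sex,
            "adult_death_age": "" if r.adult_death_age is None
            else f"{r.adult_death_age:g}",
        }
        for col, age in zip(AGE_COLUMNS, r.transition_ages):
            row[col] = f"{age:g}"
        for d in range(k):
            row[f"eggs_day_{d + 1}"] = (
                str(r.daily_eggs[d]) if d < len(r.daily_eggs) else ""
            )
        rows.append(row)
    cols = list(FIXED_COLUMNS) + [f"eggs_day_{d + 1}" for d in range(k)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_records(path) -> list[IndividualRecord]:
    """Parse and validate a record CSV.

    Raises
    ------
    InputError
        If the header is missing required columns.
    ValidationError
        Listing, with 1-based data-row numbers, every record that violates
        the record invariants (non-monotone ages, inconsistent fate/sex, ...).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"record file {path} lacks required columns: {missing}")
    egg_cols = [c for c in df.columns if c.startswith("eggs_day_")]
    egg_cols.sort(key=lambda c: int(c.rsplit("_", 1)[1]))

    records, row_errors = [], {}
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        problems: list[str] = []
        ages = []
        for col in AGE_COLUMNS:
            cell = row[col].strip()
            if cell == "":
                break
            try:
                ages.append(float(cell))
            except ValueError:
                problems.append(f"{col}: not a number ({cell!r})")
                break
        death = row["adult_death_age"].strip()
        eggs = []
        for c in egg_cols:
            cell = row[c].strip()
            if cell == "":
                continue
            try:
                eggs.append(int(cell))
            except ValueError:
                problems.append(f"{c}: not an integer ({cell!r})")
        rec = IndividualRecord(
            individual_id=row["individual_id"],
            diet_label=row["diet"],
            tray_id=row["tray"],
            transition_ages=tuple(ages),
            died_in_stage=row["died_in_stage"].strip() or "none",
            sex=row["sex"].strip() or "unknown",
            adult_death_age=float(death) if death else None,
            daily_eggs=tuple(eggs),
        )
        problems.extend(rec.violations())
        if problems:
            row_errors[idx] = problems
        else:
            records.append(rec)
    if row_errors:
        raise ValidationError(row_errors)
    return records


def read_configs(path) -> list[CohortConfig]:
    """Read one or several cohort configurations from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InputError(f"config file {path} must contain a mapping")
    entries = data["diets"] if "diets" in data else [data]
    return [CohortConfig.from_dict(e) for e in entries]


def write_configs(configs: list[CohortConfig], path) -> None:
    data = {"diets": [c.to_dict() for c in configs]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
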