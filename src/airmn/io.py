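"""Reading and writing the delimited scoring-table format.

One row per insert; comma- or tab-delimited with a header; UTF-8.

Required columns: ``chemical``, ``concentration_ug_per_ml``, ``insert_id``,
and at least one complete count block — nucleation classes (``n_mono``,
``n_bi``, ``n_multi``) and/or MN scoring (``n_bnc_scored``, ``n_bnc_mn``).
Optional columns: ``teer_ohm``, ``ak_rlu``, ``pooled``; blanks allowed.

Validation errors carry the 1-based physical line number of the offending
row (header = line 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .data_model import (
    CellClassCounts,
    DoseGroup,
    Experiment,
    InsertRecord,
    MnCounts,
)
from .errors import InvalidRecordError, SchemaError

__all__ = [
    "SCHEMA_COLUMNS",
    "read_scoring_table",
    "write_scoring_table",
    "experiments_to_frame",
]

SCHEMA_COLUMNS = (
    "chemical",
    "concentration_ug_per_ml",
    "insert_id",
    "n_mono",
    "n_bi",
    "n_multi",
    "n_bnc_scored",
    "n_bnc_mn",
    "teer_ohm",
    "ak_rlu",
    "pooled",
)
_REQUIRED = ("chemical", "concentration_ug_per_ml", "insert_id")


def _detect_sep(path: Path) -> str:
    header = path.open(encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def _cell(row, name):
    v = row.get(name)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return v


def _count(row, name, line) -> int | None:
    v = _cell(row, name)
    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        raise SchemaError(f"{name} is not a number: {v!r}", line)
    if f < 0 or f != int(f):
        raise SchemaError(f"{name} must be a non-negative integer: {v!r}", line)
    return int(f)


def _record(row, line) -> tuple[str, float, InsertRecord]:
    for col in _REQUIRED:
        if _cell(row, col) is None:
            raise SchemaError(f"missing required value in column {col!r}", line)
    chemical = str(row["chemical"])
    try:
        conc = float(row["concentration_ug_per_ml"])
    except (TypeError, ValueError):
        raise SchemaError(
            f"concentration is not a number: {row['concentration_ug_per_ml']!r}",
            line,
        )
    if conc < 0:
        raise SchemaError(f"negative concentration: {conc}", line)

    classes = [_count(row, c, line) for c in ("n_mono", "n_bi", "n_multi")]
    class_counts = None
    if any(c is not None for c in classes):
        if any(c is None for c in classes):
            raise SchemaError(
                "n_mono, n_bi, n_multi must be given together", line
            )
        class_counts = CellClassCounts(
            classes[0], classes[1], classes[2], sum(classes)
        )

    scored = _count(row, "n_bnc_scored", line)
    n_mn = _count(row, "n_bnc_mn", line)
    mn_counts = None
    if scored is not None or n_mn is not None:
        if scored is None or n_mn is None:
            raise SchemaError(
                "n_bnc_scored and n_bnc_mn must be given together", line
            )
        try:
            mn_counts = MnCounts(scored, n_mn)
        except InvalidRecordError as e:
            raise SchemaError(str(e), line)

    pooled_v = _cell(row, "pooled")
    pooled = str(pooled_v).strip().lower() in ("true", "1", "yes") if pooled_v is not None else False
    try:
        record = InsertRecord(
            insert_id=str(row["insert_id"]),
            class_counts=class_counts,
            mn_counts=mn_counts,
            teer_ohm=None if (t := _cell(row, "teer_ohm")) is None else float(t),
            ak_rlu=None if (a := _cell(row, "ak_rlu")) is None else float(a),
            pooled=pooled,
        )
    except (InvalidRecordError, ValueError) as e:
        raise SchemaError(str(e), line)
    return chemical, conc, record


def read_scoring_table(path: Union[str, Path]) -> list[Experiment]:
    """Parse a scoring table into one validated Experiment per chemical.

    Rows are grouped by chemical and concentration; each chemical must
    include a concentration-0 solvent-control group.  Output order follows
    first appearance in the file; within a chemical, dose groups are
    sorted by ascending concentration.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=object, encoding="utf-8")
    if df.empty:
        raise SchemaError("scoring table has no data rows")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    # chemical -> concentration -> [records]; preserves file order of chemicals
    by_chem: dict[str, dict[float, list[InsertRecord]]] = {}
    for pos, row in enumerate(df.to_dict("records")):
        line = pos + 2  # header is line 1
        chemical, conc, record = _record(row, line)
        by_chem.setdefault(chemical, {}).setdefault(conc, []).append(record)

    experiments = []
    for chemical, groups in by_chem.items():
        if 0.0 not in groups:
            raise SchemaError(
                f"chemical {chemical!r} has no solvent-control group "
                "(concentration 0)"
            )
        dose_groups = {
            conc: DoseGroup(
                chemical=chemical,
                concentration=conc,
                inserts=tuple(records),
                is_control=conc == 0,
            )
            for conc, records in groups.items()
        }
        treated = tuple(
            dose_groups[c] for c in sorted(c for c in dose_groups if c > 0)
        )
        experiments.append(
            Experiment(control=dose_groups[0.0], treated=treated)
        )
    return experiments


def experiments_to_frame(experiments: Sequence[Experiment]) -> pd.DataFrame:
    """Flatten experiments back into the scoring-table schema."""
    rows = []
    for exp in experiments:
        for group in exp.groups:
            for ins in group.inserts:
                cc, mn = ins.class_counts, ins.mn_counts
                rows.append(
                    {
                        "chemical": group.chemical,
                        "concentration_ug_per_ml": group.concentration,
                        "insert_id": ins.insert_id,
                        "n_mono": cc.n_mono if cc else None,
                        "n_bi": cc.n_bi if cc else None,
                        "n_multi": cc.n_multi if cc else None,
                        "n_bnc_scored": mn.n_bnc_scored if mn else None,
                        "n_bnc_mn": mn.n_bnc_mn if mn else None,
                        "teer_ohm": ins.teer_ohm,
                        "ak_rlu": ins.ak_rlu,
                        "pooled": ins.pooled,
                    }
                )
    return pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))


def write_scoring_table(
    experiments: Sequence[Experiment], path: Union[str, Path], sep: str = ","
) -> None:
    """Write experiments as a delimited scoring table (UTF-8, header)."""
    experiments_to_frame(experiments).to_csv(
        path, sep=sep, index=False, encoding="utf-8"
    )
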