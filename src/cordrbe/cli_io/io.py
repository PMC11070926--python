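"""CSV/JSON readers and writers.

Animal tables use a fixed UTF-8 CSV dialect with a header row, '.'
decimal separator and one record per row; schema violations are
reported with 1-based data row numbers.  JSON result files embed the
package version and a hash of the writing configuration so a run can be
traced back to its inputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from pathlib import Path
from typing import Any

from ..actuarial import DoseGroupSummary
from ..synthetic_cohort import AnimalRecord

__all__ = [
    "ANIMAL_COLUMNS",
    "SchemaError",
    "read_animal_table",
    "write_animal_table",
    "read_group_table",
    "write_group_table",
    "write_results",
    "config_hash",
]

ANIMAL_COLUMNS = (
    "animal_id", "radiation_label", "let_value", "n_fractions", "total_dose",
    "responder", "event_day", "followup_day", "excluded", "exclusion_reason",
)

GROUP_COLUMNS = (
    "radiation_label", "let_value", "n_fractions", "total_dose",
    "n_crude", "p_actuarial", "var_p", "n_eff", "r_eff",
)


class SchemaError(ValueError):
    """Malformed table: wrong columns or unparseable cell values."""


def _parse_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"row {row}: column {column!r}: cannot parse {value!r}") from None


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1"):
        return True
    if v in ("false", "0"):
        return False
    raise SchemaError(f"row {row}: column {column!r}: cannot parse {value!r}")


def write_animal_table(path: str | Path, records: list[AnimalRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ANIMAL_COLUMNS)
        for r in records:
            w.writerow([
                r.animal_id, r.radiation_label, repr(r.let_value), r.n_fractions,
                repr(r.total_dose), r.responder,
                "" if r.event_day is None else repr(r.event_day),
                repr(r.followup_day), r.excluded, r.exclusion_reason,
            ])


def read_animal_table(path: str | Path) -> list[AnimalRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = tuple(reader.fieldnames or ())
        missing = [c for c in ANIMAL_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(AnimalRecord(
                    animal_id=row["animal_id"],
                    radiation_label=row["radiation_label"],
                    let_value=_parse_float(row["let_value"], "let_value", i),
                    n_fractions=int(_parse_float(row["n_fractions"], "n_fractions", i)),
                    total_dose=_parse_float(row["total_dose"], "total_dose", i),
                    responder=_parse_bool(row["responder"], "responder", i),
                    event_day=(None if row["event_day"] == ""
                               else _parse_float(row["event_day"], "event_day", i)),
                    followup_day=_parse_float(row["followup_day"], "followup_day", i),
                    excluded=_parse_bool(row["excluded"], "excluded", i),
                    exclusion_reason=row["exclusion_reason"],
                ))
            except ValueError as exc:
                if isinstance(exc, SchemaError):
                    raise
                raise SchemaError(f"row {i}: {exc}") from exc
    return records


def write_group_table(path: str | Path, groups: list[DoseGroupSummary]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(GROUP_COLUMNS)
        for g in groups:
            w.writerow([g.radiation_label, repr(g.let_value), g.n_fractions,
                        repr(g.total_dose), g.n_crude, repr(g.p_actuarial),
                        repr(g.var_p), repr(g.n_eff), repr(g.r_eff)])


def read_group_table(path: str | Path) -> list[DoseGroupSummary]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = tuple(reader.fieldnames or ())
        missing = [c for c in GROUP_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        groups = []
        for i, row in enumerate(reader, start=1):
            groups.append(DoseGroupSummary(
                radiation_label=row["radiation_label"],
                let_value=_parse_float(row["let_value"], "let_value", i),
                n_fractions=int(_parse_float(row["n_fractions"], "n_fractions", i)),
                total_dose=_parse_float(row["total_dose"], "total_dose", i),
                n_crude=int(_parse_float(row["n_crude"], "n_crude", i)),
                p_actuarial=_parse_float(row["p_actuarial"], "p_actuarial", i),
                var_p=_parse_float(row["var_p"], "var_p", i),
                n_eff=_parse_float(row["n_eff"], "n_eff", i),
                r_eff=_parse_float(row["r_eff"], "r_eff", i),
            ))
    return groups


def config_hash(config: Any) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    if hasattr(obj, "__dict__"):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_results(path: str | Path, payload: dict, config: Any = None) -> None:
    """JSON result file with embedded package version and config hash."""
    from .. import __version__

    doc = {
        "package_version": __version__,
        "config_hash": config_hash(config) if config is not None else None,
        **_jsonable(payload),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
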