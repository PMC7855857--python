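"""File round-tripping: cohort tables, schema files, config files, manifests.

Cohorts are delimited text (comma default) with a header row:
``id, <covariates in schema order>, time, event``.  Missing covariate
entries may be empty or ``NA`` on input and are emitted as empty fields.
Rows lacking a time or event are dropped at read time with a logged count.
Schemas and run configs are YAML.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import fields as dataclass_fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .data_model import (
    CohortSchema,
    CohortValidationError,
    CovariateSpec,
    PatientRecord,
    SchemaError,
)

logger = logging.getLogger(__name__)

_MISSING_TOKENS = ("", "NA")


class ConfigError(ValueError):
    """A configuration file is malformed or names unknown keys."""


def check_known_keys(mapping: dict, cls, context: str) -> None:
    """Reject unknown keys, naming the offender."""
    allowed = {f.name for f in dataclass_fields(cls)}
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"{context}: unknown key {key!r}")


# -- schema files ----------------------------------------------------------


def read_schema(path) -> CohortSchema:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "covariates" not in payload:
        raise ConfigError(f"{path}: schema file must have a 'covariates' list")
    specs = []
    for entry in payload["covariates"]:
        unknown = set(entry) - {"name", "kind", "codes"}
        if unknown:
            raise ConfigError(f"{path}: unknown schema key {unknown.pop()!r}")
        specs.append(
            CovariateSpec(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                codes={str(k): int(v) for k, v in entry["codes"].items()}
                if entry.get("codes")
                else None,
            )
        )
    return CohortSchema(covariates=tuple(specs))


def write_schema(schema: CohortSchema, path) -> None:
    payload = {
        "covariates": [
            {"name": c.name, "kind": c.kind}
            | ({"codes": dict(c.codes)} if c.codes else {})
            for c in schema.covariates
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# -- cohort tables ---------------------------------------------------------


def read_cohort(
    path, schema: CohortSchema, delimiter: str = ","
) -> list[PatientRecord]:
    """Parse a cohort table; rows with missing time/event are dropped and
    counted in the log.  Records come back in file order."""
    expected = ["id", *schema.names, "time", "event"]
    records: list[PatientRecord] = []
    n_dropped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortValidationError(f"{path}: empty file") from None
        if header != expected:
            raise SchemaError(
                f"{path}: header mismatch; expected {expected}, got {header}"
            )
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(expected):
                raise CohortValidationError(
                    f"{path}: row {line_no}: expected {len(expected)} fields, "
                    f"got {len(row)}"
                )
            t_raw, s_raw = row[-2], row[-1]
            if t_raw.strip() in _MISSING_TOKENS or s_raw.strip() in _MISSING_TOKENS:
                n_dropped += 1
                continue
            values = []
            for spec, field_value in zip(schema.covariates, row[1:-2]):
                token = field_value.strip()
                if token in _MISSING_TOKENS:
                    values.append(None)
                elif spec.kind == "continuous":
                    try:
                        values.append(float(token))
                    except ValueError:
                        raise CohortValidationError(
                            f"{path}: row {line_no}: malformed numeric field "
                            f"{token!r} for covariate {spec.name!r}"
                        ) from None
                else:
                    values.append(token)
            try:
                time = float(t_raw)
                event = int(s_raw)
            except ValueError:
                raise CohortValidationError(
                    f"{path}: row {line_no}: malformed time/event "
                    f"({t_raw!r}, {s_raw!r})"
                ) from None
            records.append(
                PatientRecord(
                    id=row[0], values=tuple(values), time=time, event=event
                )
            )
    if n_dropped:
        logger.info("%s: dropped %d rows with missing time/event", path, n_dropped)
    return records


def write_cohort(
    records: Sequence[PatientRecord],
    schema: CohortSchema,
    path,
    delimiter: str = ",",
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id", *schema.names, "time", "event"])
        for rec in records:
            row = [rec.id]
            for v in rec.values:
                if v is None:
                    row.append("")
                elif isinstance(v, float):
                    row.append(repr(v))
                else:
                    row.append(str(v))
            row.extend([repr(float(rec.time)), str(int(rec.event))])
            writer.writerow(row)


# -- manifests -------------------------------------------------------------


def write_manifest(out_path, config: dict, seed: Optional[int]) -> None:
    """Provenance sidecar written next to every CLI output."""
    from . import __version__

    manifest = {
        "package": "survnet",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    path = Path(str(out_path) + ".manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
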