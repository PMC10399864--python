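"""Validated TSV input/output shared by all assay stages.

One dialect everywhere: UTF-8, tab-delimited, LF line endings, with a single
leading comment line recording the tool version and a hash of the generating
configuration. Schemas are declared centrally so readers can fail with the
offending column and row named.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .errors import SchemaError

try:
    __version__ = version("birkit")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    __version__ = "0+unknown"

#: schema id -> {column: pandas dtype}
SCHEMAS: dict[str, dict[str, str]] = {
    "colonies": {
        "strain": "string",
        "ade_phenotype": "string",
        "leu_phenotype": "string",
        "count": "int64",
    },
    "colony_truth": {"strain": "string", "colony": "int64", "mechanism": "string"},
    "plating": {
        "strain": "string",
        "timepoint_hr": "float64",
        "replicate": "int64",
        "lys_colonies": "int64",
        "viable_colonies": "int64",
        "dilution_selective": "float64",
        "dilution_permissive": "float64",
    },
    "droplets": {
        "strain": "string",
        "time_hr": "float64",
        "locus": "string",
        "n_total": "int64",
        "n_positive": "int64",
    },
    "series": {
        "time_hr": "float64",
        "locus": "string",
        "ratio": "float64",
        "copy_number": "float64",
        "ci_low": "float64",
        "ci_high": "float64",
    },
    "cq": {
        "strain": "string",
        "locus": "string",
        "control_locus": "string",
        "replicate": "int64",
        "cq_ip_target": "float64",
        "cq_input_target": "float64",
        "cq_ip_control": "float64",
        "cq_input_control": "float64",
        "input_dilution": "float64",
    },
    "spores": {
        "source": "string",
        "n_tetrads": "int64",
        "ura_phenotype": "string",
        "g418_phenotype": "string",
        "count": "int64",
    },
    "motifs": {
        "seq_id": "string",
        "start": "int64",
        "end": "int64",
        "matched": "string",
    },
    "decomposition": {
        "class": "string",
        "count": "float64",
        "frequency": "float64",
    },
}


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, schema_id: str, config: dict | None = None) -> None:
    """Write a TSV with the standard comment header, validating the schema first."""
    schema = _schema(schema_id)
    _validate_columns(df, schema, where=str(path))
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# birkit={__version__} schema={schema_id} config_sha1={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path, schema_id: str) -> pd.DataFrame:
    """Read and validate a TSV against a registered schema.

    Raises :class:`~birkit.errors.SchemaError` naming the missing/unknown
    column or the first offending row when a value cannot be coerced.
    """
    schema = _schema(schema_id)
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype="string")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no rows")
    _validate_columns(df, schema, where=str(path))
    out = {}
    for col, dtype in schema.items():
        try:
            out[col] = df[col].astype(dtype)
        except (ValueError, TypeError):
            bad = _first_bad_row(df[col], dtype)
            raise SchemaError(
                f"{path}: column {col!r} row {bad} cannot be read as {dtype}"
            ) from None
    result = pd.DataFrame(out)
    result.index = df.index
    return result


def _schema(schema_id: str) -> dict[str, str]:
    if schema_id not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_id!r}; known: {sorted(SCHEMAS)}")
    return SCHEMAS[schema_id]


def _validate_columns(df: pd.DataFrame, schema: dict[str, str], where: str) -> None:
    missing = set(schema) - set(df.columns)
    unknown = set(df.columns) - set(schema)
    problems = []
    if missing:
        problems.append(f"missing column(s) {sorted(missing)}")
    if unknown:
        problems.append(f"unknown column(s) {sorted(unknown)}")
    if problems:
        raise SchemaError(f"{where}: " + "; ".join(problems))


def _first_bad_row(series: pd.Series, dtype: str) -> int:
    for idx, value in series.items():
        try:
            pd.Series([value]).astype(dtype)
        except (ValueError, TypeError):
            return int(idx) + 2  # 1-based, plus header line
    return -1
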