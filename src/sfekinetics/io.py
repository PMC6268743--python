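"""Curve and config readers/writers, reports and run manifests.

All on-disk formats are delimited UTF-8 text with "." as the decimal
separator: extraction curves are two-column CSV with the header
``t_s,e_kg_per_kg``; system parameters live in one flat-key YAML config
(N, epsilon, rho_s, d_p, F, rho_f, P, T, all SI); fit reports are
``key,value`` CSV, bit-stable for fixed inputs and seed.  Every CLI run
also writes a JSON manifest tying outputs to the command, a config
snapshot, input checksums, the seed and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .systems import BedSpec, ExtractionCurve, SolventSpec

__all__ = [
    "read_curve",
    "write_curve",
    "read_config",
    "write_report",
    "read_report",
    "RunManifest",
    "write_manifest",
]

CURVE_COLUMNS = ("t_s", "e_kg_per_kg")
CONFIG_KEYS = ("N", "epsilon", "rho_s", "d_p", "F", "rho_f")


def read_curve(path) -> ExtractionCurve:
    """Read a two-column extraction-curve file with validation.

    Rows out of time order are sorted with a warning; duplicated times,
    non-numeric fields or negative values raise :class:`ParseError` with
    the offending line number (1-based, header included).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse curve file: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns {CURVE_COLUMNS}")
    df = df.iloc[:, :2]
    for col_idx, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 to 1-based
            raise ParseError(
                f"{path}:{line}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        df[col] = numeric
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}:{line}: missing value")
    t = df.iloc[:, 0].to_numpy(float)
    e = df.iloc[:, 1].to_numpy(float)
    if np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: rows out of time order; sorting by time", stacklevel=2)
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
    dup = np.nonzero(np.diff(t) == 0)[0]
    if dup.size:
        raise ParseError(f"{path}:{int(dup[0]) + 3}: duplicated time {t[dup[0]]!r}")
    try:
        return ExtractionCurve(t, e)
    except Exception as exc:
        raise ParseError(f"{path}: invalid curve: {exc}") from exc


def write_curve(curve: ExtractionCurve, path) -> None:
    """Write a curve in the standard two-column format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_config(path) -> tuple[BedSpec, SolventSpec, dict]:
    """Load a flat-key YAML config into bed and solvent specs.

    Returns ``(bed, solvent, extras)`` where ``extras`` holds every key
    beyond the geometric/flow ones (model parameters such as C0, q0, r,
    k_f, k_s, K are passed through untouched).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping of flat keys")
    missing = [k for k in CONFIG_KEYS if k not in raw]
    if missing:
        raise SchemaError(f"{path}: missing config keys: {', '.join(missing)}")
    bed = BedSpec(
        N=float(raw["N"]),
        epsilon=float(raw["epsilon"]),
        rho_s=float(raw["rho_s"]),
        d_p=float(raw["d_p"]),
    )
    solvent = SolventSpec(
        F=float(raw["F"]),
        rho_f=float(raw["rho_f"]),
        P=float(raw["P"]) if raw.get("P") is not None else None,
        T=float(raw["T"]) if raw.get("T") is not None else None,
    )
    extras = {k: v for k, v in raw.items() if k not in CONFIG_KEYS + ("P", "T")}
    return bed, solvent, extras


def _flatten_result(result) -> dict[str, object]:
    if dataclasses.is_dataclass(result):
        d = {}
        for f in dataclasses.fields(result):
            v = getattr(result, f.name)
            if isinstance(v, np.ndarray):
                continue  # residual vectors live on the object, not in reports
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    d[f"{f.name}.{k2}"] = v2
            elif v is None or isinstance(v, (int, float, str, bool)):
                d[f.name] = v
        return d
    if isinstance(result, dict):
        return dict(result)
    raise SchemaError(f"cannot serialize result of type {type(result).__name__}")


def write_report(result, path) -> None:
    """Write a result as two-column ``key,value`` text.

    Keys keep insertion order, floats are rendered with ``repr`` — two
    runs with the same inputs and seed produce byte-identical files.
    """
    d = _flatten_result(result)
    if not d:
        raise SchemaError("empty report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["key,value"]
    for k, v in d.items():
        lines.append(f"{k},{v!r}" if isinstance(v, str) else f"{k},{v}")
    path.write_text("\n".join(lines) + "\n")


def read_report(path) -> dict[str, object]:
    """Read back a ``key,value`` report into a dict (floats where possible)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != "key,value":
        raise SchemaError(f"{path}: not a report file")
    out: dict[str, object] = {}
    for line in lines[1:]:
        if not line:
            continue
        k, _, v = line.partition(",")
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v.strip("'")
    return out


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    config: dict
    inputs: dict[str, str]  # path -> sha256
    seed: int | None
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        missing = {f.name for f in dataclasses.fields(cls)} - set(d)
        if missing:
            raise SchemaError(f"manifest missing fields: {sorted(missing)}")
        return cls(**d)


def write_manifest(
    command: str,
    out_path,
    config: dict | None = None,
    inputs: list | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Write ``<out_path>.manifest.json`` next to an output file."""
    from . import __version__

    manifest = RunManifest(
        command=command,
        config=config or {},
        inputs={str(p): _sha256(p) for p in (inputs or [])},
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    p = Path(str(out_path) + ".manifest.json")
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(manifest.to_json() + "\n")
    return manifest
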