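"""Reading and writing the tabular formats used by the pipeline.

The genotype file is a comma- or tab-delimited table (delimiter auto-detected)
with a header row: four leading columns naming the sample id, patch, and grid
x/y coordinates, followed by exactly two columns per locus.  Allele states are
integers in repeat units; a configurable sentinel (0 by default) marks missing
alleles.  A converter is provided for files scored in base pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .core import MISSING, GenotypeTable, GenotypeTableError, PatchGeo, RunConfig

_ID_NAMES = {"id", "sample", "sample_id", "stem", "stem_id"}
_PATCH_NAMES = {"patch", "patch_id", "pop", "population"}


class ParseError(ValueError):
    """Raised on a malformed input file; the message names the offending
    row or column."""


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _locus_names_from_columns(cols: list[str]) -> list[str]:
    """Derive locus names from paired allele columns (``Spar05_1, Spar05_2``)."""
    names = []
    for k in range(0, len(cols), 2):
        a, b = cols[k], cols[k + 1]
        # strip a trailing separator+index if the two columns share a prefix
        prefix = ""
        for ca, cb in zip(a, b):
            if ca != cb:
                break
            prefix += ca
        prefix = prefix.rstrip("_. -")
        names.append(prefix if prefix else f"L{k // 2 + 1}")
    # de-duplicate defensively
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def read_genotypes(
    path: str | Path,
    config: RunConfig | None = None,
    *,
    allele_units: str = "repeat",
    repeat_lengths: Mapping[str, int] | None = None,
    repeat_offsets: Mapping[str, int] | None = None,
) -> GenotypeTable:
    """Read a genotype table.

    Parameters
    ----------
    path
        Delimited text file as described in the module docstring.
    config
        Supplies the missing-allele sentinel (default 0).
    allele_units
        ``"repeat"`` (default) or ``"bp"``.  With ``"bp"`` each allele is
        converted to repeat units as ``(size - offset) / repeat_length`` using
        the per-locus maps ``repeat_lengths`` / ``repeat_offsets``.
    """
    config = config or RunConfig()
    sentinel = config.missing_sentinel
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str).rename(columns=lambda c: c.strip())

    cols = list(df.columns)
    if len(cols) < 6:
        raise ParseError(f"{path}: expected id, patch, x, y plus >=2 allele columns")
    lowered = [c.lower() for c in cols[:4]]
    if lowered[0] not in _ID_NAMES or lowered[1] not in _PATCH_NAMES:
        raise ParseError(
            f"{path}: header must start with sample-id and patch columns, got {cols[:4]}"
        )
    if lowered[2] != "x" or lowered[3] != "y":
        raise ParseError(f"{path}: columns 3-4 must be named x and y, got {cols[2:4]}")
    allele_cols = cols[4:]
    if len(allele_cols) % 2:
        raise ParseError(
            f"{path}: odd number of allele columns ({len(allele_cols)}); "
            "each locus needs exactly two"
        )
    locus_names = _locus_names_from_columns(allele_cols)

    def _to_int(value: str, row: int, col: str) -> int:
        try:
            return int(value)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-integer allele {value!r} at data row {row}, column {col}"
            ) from None

    n = len(df)
    alleles = np.empty((n, len(locus_names), 2), dtype=int)
    for j in range(len(locus_names)):
        for slot in range(2):
            col = allele_cols[2 * j + slot]
            for i, v in enumerate(df[col]):
                alleles[i, j, slot] = _to_int(v, i, col)
    if allele_units == "bp":
        if repeat_lengths is None:
            raise ValueError("allele_units='bp' requires repeat_lengths")
        repeat_offsets = repeat_offsets or {}
        for j, name in enumerate(locus_names):
            rl = repeat_lengths[name]
            off = repeat_offsets.get(name, 0)
            present = alleles[:, j, :] != sentinel
            converted = (alleles[:, j, :][present] - off) / rl
            rounded = np.rint(converted).astype(int)
            if np.any(np.abs(converted - rounded) > 1e-9):
                warnings.warn(
                    f"locus {name}: base-pair sizes not integral in repeat units; rounded"
                )
            alleles[:, j, :][present] = rounded
    elif allele_units != "repeat":
        raise ValueError(f"unknown allele_units {allele_units!r}")

    alleles[alleles == sentinel] = MISSING
    try:
        return GenotypeTable(
            sample_id=df[cols[0]].to_numpy(dtype=object),
            patch_id=df[cols[1]].to_numpy(dtype=object),
            x=df[cols[2]].astype(int).to_numpy(),
            y=df[cols[3]].astype(int).to_numpy(),
            alleles=alleles,
            locus_names=locus_names,
        )
    except GenotypeTableError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genotypes(
    table: GenotypeTable, path: str | Path, config: RunConfig | None = None, sep: str = ","
) -> None:
    """Write a genotype table in the dialect :func:`read_genotypes` accepts."""
    config = config or RunConfig()
    out = {"sample_id": table.sample_id, "patch": table.patch_id, "x": table.x, "y": table.y}
    a = table.alleles.copy()
    a[a == MISSING] = config.missing_sentinel
    for j, name in enumerate(table.locus_names):
        out[f"{name}_1"] = a[:, j, 0]
        out[f"{name}_2"] = a[:, j, 1]
    pd.DataFrame(out).to_csv(path, sep=sep, index=False)


def read_patch_geo(path: str | Path) -> PatchGeo:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns=lambda c: c.strip().lower())
    required = {"patch_id", "latitude", "longitude"}
    aliases = {"patch": "patch_id", "lat": "latitude", "lon": "longitude", "lng": "longitude"}
    df = df.rename(columns=aliases)
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns patch_id, latitude, longitude")
    return PatchGeo(
        patch_id=df["patch_id"].to_numpy(dtype=object),
        latitude=df["latitude"].to_numpy(dtype=float),
        longitude=df["longitude"].to_numpy(dtype=float),
    )


def write_patch_geo(geo: PatchGeo, path: str | Path) -> None:
    pd.DataFrame(
        {"patch_id": geo.patch_id, "latitude": geo.latitude, "longitude": geo.longitude}
    ).to_csv(path, index=False)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o: Any):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        return super().default(o)


def write_report(results: Any, path: str | Path) -> None:
    """Serialize a pipeline product to JSON, deterministically (sorted keys)."""
    with open(path, "w") as fh:
        json.dump(results, fh, cls=_ReportEncoder, sort_keys=True, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Human-readable companion table for a report."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
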