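"""Readers and writers for the pipeline's tab-separated file dialects.

All tables are UTF-8 TSV with ``NA`` as the missing sentinel on output
(``NA``, the empty string and ``.`` are all accepted on input) and begin
with ``#``-prefixed comment headers recording the tool version, the run
seed and a configuration hash, so every artifact is traceable to the run
that produced it.  Malformed rows are reported with 1-based line numbers.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simpop import GeneticMap

__all__ = [
    "config_hash",
    "read_map", "write_map",
    "read_genotypes", "write_genotypes",
    "read_families", "write_families",
    "read_phenotypes", "write_phenotypes",
    "write_table", "read_table",
]

MISSING_TOKENS = {"NA", "", "."}


def config_hash(config: dict | None) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(seed=None, config=None, extra: dict | None = None) -> list[str]:
    lines = [f"# abqtl {__version__}"]
    lines.append(f"# seed: {'NA' if seed is None else seed}")
    lines.append(f"# config: {config_hash(config)}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_table(df: pd.DataFrame, path, seed=None, config=None, index=True,
                float_format: str | None = None) -> None:
    """Write any DataFrame as a commented TSV artifact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", na_rep="NA", index=index, float_format=float_format)
    path.write_text("\n".join(_header_lines(seed, config)) + "\n" + buf.getvalue())


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col,
                       na_values=sorted(MISSING_TOKENS), keep_default_na=False)


def _read_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Split a TSV into (column names, [(1-based line number, fields), ...])."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                if len(fields) != len(header):
                    raise ValueError(
                        f"{path}: line {lineno}: expected {len(header)} columns, got {len(fields)}"
                    )
                rows.append((lineno, fields))
    if header is None:
        raise ValueError(f"{path}: empty file")
    return header, rows


def write_map(gmap: GeneticMap, path, seed=None, config=None) -> None:
    write_table(gmap.to_frame(), path, seed=seed, config=config, index=False)


def read_map(path) -> GeneticMap:
    """Read a genetic-map TSV (snp_id, chromosome, position_cM)."""
    header, rows = _read_rows(path)
    expected = ["snp_id", "chromosome", "position_cM"]
    if header != expected:
        raise ValueError(f"{path}: map header must be {expected}, got {header}")
    ids, chroms, pos = [], [], []
    for lineno, (snp, chrom, p) in rows:
        try:
            pos.append(float(p))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: bad cM position {p!r}") from exc
        ids.append(snp)
        chroms.append(chrom)
    return GeneticMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.array(pos))


def write_genotypes(genotypes: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write a line x SNP dosage matrix; integral dosages print as integers."""
    out = genotypes.copy()
    if np.all(np.isin(out.to_numpy(dtype=float), [0.0, 1.0, 2.0]) | np.isnan(out.to_numpy(dtype=float))):
        out = out.astype("Int64")
    out.index.name = "line_id"
    write_table(out, path, seed=seed, config=config)


def read_genotypes(path, allow_fractional: bool = False) -> pd.DataFrame:
    """Read a genotype dosage matrix, validating states {0, 1, 2, missing}.

    ``allow_fractional`` admits real-valued (imputed) dosages in [0, 2].
    """
    header, rows = _read_rows(path)
    if header[0] != "line_id":
        raise ValueError(f"{path}: first column must be line_id, got {header[0]!r}")
    snp_ids = header[1:]
    lines, data = [], []
    for lineno, fields in rows:
        lines.append(fields[0])
        vals = np.empty(len(snp_ids))
        for j, tok in enumerate(fields[1:]):
            if tok in MISSING_TOKENS:
                vals[j] = np.nan
                continue
            try:
                v = float(tok)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}, column {snp_ids[j]!r}: non-numeric dosage {tok!r}"
                ) from exc
            if allow_fractional:
                if not 0.0 <= v <= 2.0:
                    raise ValueError(
                        f"{path}: line {lineno}, column {snp_ids[j]!r}: dosage {tok!r} outside [0, 2]"
                    )
            elif v not in (0.0, 1.0, 2.0):
                raise ValueError(
                    f"{path}: line {lineno}, column {snp_ids[j]!r}: dosage {tok!r} not in {{0, 1, 2}}"
                )
            vals[j] = v
        data.append(vals)
    return pd.DataFrame(data, index=pd.Index(lines, name="line_id"), columns=snp_ids)


def write_families(families: pd.Series, path, seed=None, config=None) -> None:
    df = families.rename("family").to_frame()
    df.index.name = "line_id"
    write_table(df, path, seed=seed, config=config)


def read_families(path) -> pd.Series:
    header, rows = _read_rows(path)
    if header != ["line_id", "family"]:
        raise ValueError(f"{path}: family file header must be ['line_id', 'family']")
    idx = [f[0] for _, f in rows]
    fam = [f[1] for _, f in rows]
    return pd.Series(fam, index=pd.Index(idx, name="line_id"), name="family")


PHENO_COLUMNS = ["line_id", "environment", "n_level", "trait", "value"]


def write_phenotypes(table: pd.DataFrame, path, seed=None, config=None) -> None:
    write_table(table[PHENO_COLUMNS], path, seed=seed, config=config, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    header, rows = _read_rows(path)
    if header != PHENO_COLUMNS:
        raise ValueError(f"{path}: phenotype header must be {PHENO_COLUMNS}, got {header}")
    recs = []
    for lineno, fields in rows:
        tok = fields[4]
        if tok in MISSING_TOKENS:
            val = np.nan
        else:
            try:
                val = float(tok)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value {tok!r}") from exc
        recs.append(fields[:4] + [val])
    df = pd.DataFrame(recs, columns=PHENO_COLUMNS)
    df["value"] = df["value"].astype(float)
    return df
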