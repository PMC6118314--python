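"""Delimited-text I/O and run configuration.

Genotype and phenotype files are comma-delimited UTF-8 with a header row
and a line-identifier first column; chains and result tables are written in
the same form.  Every output table carries the seed and a configuration
hash in a leading ``#`` comment so re-runs are byte-comparable (timestamps
are deliberately excluded from content).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError


def read_genotypes(path) -> pd.DataFrame:
    """Marker matrix indexed by line identifier; entries must be numeric."""
    df = _read_table(path, "genotype")
    if not np.all(np.isfinite(df.to_numpy())):
        raise FormatError(f"{path}: non-finite genotype entries")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table indexed by line identifier, one column per trait."""
    return _read_table(path, "phenotype")


def _read_table(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} file not found: {path}")
    try:
        df = pd.read_csv(path, index_col=0, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as delimited {kind} table: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate line identifier {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in {kind} table: {exc}") from exc
    return df


def align_tables(genotypes: pd.DataFrame, phenotypes: pd.DataFrame):
    """Align phenotype rows to the genotype identifiers, erroring on gaps."""
    missing = genotypes.index.difference(phenotypes.index)
    if len(missing):
        raise FormatError(f"phenotypes missing line identifier(s): {list(missing[:5])}")
    return genotypes, phenotypes.loc[genotypes.index]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, *, seed=None, config: dict | None = None,
                index: bool = True) -> None:
    """Write a result table with a reproducibility header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        meta = {}
        if seed is not None:
            meta["seed"] = seed
        if config is not None:
            meta["config_hash"] = config_hash(config)
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, index=index)


def load_config(path) -> dict:
    """Load a YAML run configuration as a plain mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
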