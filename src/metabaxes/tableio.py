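"""Plain-TSV table I/O with schema validation and id alignment.

All tables are tab-separated with a header row; participant-keyed
tables carry participant_id as the first column.  Missing values are
written as empty fields and read back as NaN.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metabaxes.preprocess import MetaboliteMatrix, PhenotypeTable


class TableError(ValueError):
    pass


def write_tsv(frame: pd.DataFrame, path: Path | str, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, na_rep="")
    return path


def read_participant_table(path: Path | str) -> pd.DataFrame:
    """Read a participant-keyed TSV (first column = participant_id)."""
    # round_trip parsing keeps write-then-read bit-identical for floats
    frame = pd.read_csv(
        Path(path), sep="\t", index_col=0, na_values=["", "NA"],
        float_precision="round_trip",
    )
    frame.index = frame.index.astype(str)
    frame.index.name = "participant_id"
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].tolist()
        raise TableError(f"duplicate participant ids in {path}: {dups[:5]}")
    return frame


def read_metabolite_matrix(
    path: Path | str, qc_path: Path | str | None = None,
    cv_path: Path | str | None = None,
) -> MetaboliteMatrix:
    values = read_participant_table(path)
    qc = None
    if qc_path is not None and Path(qc_path).exists():
        qc = pd.read_csv(Path(qc_path), sep="\t", index_col=0, na_values=["", "NA"])
    cv = None
    if cv_path is not None and Path(cv_path).exists():
        cv = pd.read_csv(Path(cv_path), sep="\t", index_col=0).iloc[:, 0]
    return MetaboliteMatrix(values=values, qc=qc, cv=cv)


def read_phenotype_table(path: Path | str, config_path: Path | str) -> PhenotypeTable:
    """Phenotype values TSV plus a YAML metadata config.

    The config maps each phenotype id to ``domain``, ``adverse``,
    ``transform``, and ``index_to_height``.
    """
    values = read_participant_table(path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    phen_cfg = cfg.get("phenotypes", cfg)
    missing = [c for c in values.columns if c not in phen_cfg]
    if missing:
        raise TableError(f"phenotypes missing from config: {missing}")
    meta = pd.DataFrame.from_dict(phen_cfg, orient="index")
    meta.index.name = "phenotype_id"
    defaults = {"adverse": False, "transform": "none", "index_to_height": False}
    for col, default in defaults.items():
        if col not in meta.columns:
            meta[col] = default
        meta[col] = meta[col].fillna(default)
    if "domain" not in meta.columns:
        raise TableError("phenotype config must declare a domain per phenotype")
    return PhenotypeTable(values=values, meta=meta)


def load_tables(
    metabolites: MetaboliteMatrix,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
) -> tuple[MetaboliteMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Align participant-keyed tables on their common sorted id set."""
    ids = (
        metabolites.values.index.intersection(phenotypes.index)
        .intersection(covariates.index)
        .sort_values()
    )
    if len(ids) == 0:
        raise TableError("no participants shared across tables")
    dropped = max(
        len(metabolites.values), len(phenotypes), len(covariates)
    ) - len(ids)
    if dropped:
        warnings.warn(f"dropping {dropped} participants absent from some table")
    mm = MetaboliteMatrix(
        values=metabolites.values.loc[ids], qc=metabolites.qc, cv=metabolites.cv
    )
    out = outcomes
    if outcomes is not None:
        out = outcomes[outcomes["participant_id"].astype(str).isin(set(ids.astype(str)))]
    return mm, phenotypes.loc[ids], covariates.loc[ids], out


def file_digest(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def json_digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()
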