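"""Readers, writers, configuration and run manifests.

Beta matrices travel as TSV with sites as rows and a header row of sample
ids (EWAS convention); sample sheets, truth tables and result tables as
CSV. Gzip is handled transparently by pandas via the ``.gz`` suffix.
Cohort configuration is YAML with unknown keys rejected (no silent
typos). Every CLI run writes a manifest with the resolved configuration,
seed, input digests and versions, sufficient to reproduce deterministic
runs bit for bit.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd
import yaml

from .simulate import CohortConfig

__all__ = ["read_beta", "read_sheet", "write_results", "load_config",
           "RunManifest", "ValidationError"]

SHEET_COLUMNS = ["sample_id", "individual_id", "cell_type", "age", "sex",
                 "brain_bank", "phenotype"]


class ValidationError(ValueError):
    pass


def read_beta(path) -> pd.DataFrame:
    """Read a sites x samples beta TSV; validates range and uniqueness."""
    beta = pd.read_csv(path, sep="\t", index_col=0)
    beta.index.name = "site_id"
    if beta.index.duplicated().any():
        dups = beta.index[beta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate site ids: {dups[:5]}")
    if beta.columns.duplicated().any():
        dups = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    vals = beta.to_numpy()
    bad = (vals < 0) | (vals > 1) | pd.isna(vals)
    if bad.any():
        i, j = next(zip(*bad.nonzero()))
        raise ValidationError(
            f"beta value out of [0, 1] at site {beta.index[i]!r}, "
            f"sample {beta.columns[j]!r}: {vals[i, j]!r}"
        )
    return beta


def read_sheet(path) -> pd.DataFrame:
    """Read a sample sheet CSV with the documented schema."""
    sheet = pd.read_csv(path)
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in sheet: {dups[:5]}")
    pairs = sheet[["individual_id", "cell_type"]]
    if pairs.duplicated().any():
        raise ValidationError("duplicate (individual_id, cell_type) pairs")
    return sheet


def check_alignment(beta: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Verify that the sheet and beta matrix describe the same samples."""
    missing = [s for s in sheet["sample_id"] if s not in beta.columns]
    extra = [s for s in beta.columns if s not in set(sheet["sample_id"])]
    if missing or extra:
        raise ValidationError(
            f"sample alignment mismatch; in sheet but not beta: "
            f"{missing[:5]}, in beta but not sheet: {extra[:5]}"
        )


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t")


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV with one row per site."""
    table.to_csv(path, sep="\t")


def load_config(path, schema=CohortConfig):
    """Load a YAML configuration into ``schema`` (a dataclass type).

    Unknown keys are rejected with a close-match suggestion rather than
    silently ignored; an empty file yields all defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(schema)}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValidationError(f"unknown config key {key!r}{suggestion}")
    for key, val in raw.items():
        if isinstance(val, list):
            raw[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in val
            )
    return schema(**raw)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @classmethod
    def collect(cls, command, seed, config=None, input_paths=()):
        cfg = config or {}
        if dataclasses.is_dataclass(cfg):
            cfg = dataclasses.asdict(cfg)
        return cls(command=command, seed=seed, config=cfg,
                   inputs={str(p): _digest(p) for p in input_paths})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
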