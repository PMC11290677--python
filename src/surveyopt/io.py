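"""Readers, writers and run manifests.

Sample matrices travel as CSV in either long format (``sample_id, site,
method, species, abundance``) or wide format (one row per sample, one
column per species).  Optimization results are written as a per-cost
curve CSV plus a compact report table with one row per diversity
dimension, mirroring how optimal protocols are usually tabulated.

Every CLI run also writes a manifest (input hashes, configuration echo,
seed, software version, timestamps) so any reported protocol can be
reproduced exactly.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .optimizer import LONG_COLUMNS, OptResult, SampleMatrix

__all__ = [
    "read_sample_matrix",
    "write_sample_matrix",
    "long_to_wide",
    "wide_to_long",
    "report_table",
    "RunManifest",
]

META_COLUMNS = ["sample_id", "site", "method"]


def wide_to_long(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"wide sample matrix missing columns {missing}")
    long = frame.melt(id_vars=META_COLUMNS, var_name="species", value_name="abundance")
    long["abundance"] = long["abundance"].fillna(0)
    # keep empty samples representable: retain one zero row per sample
    nonzero = long[long["abundance"] > 0]
    empty_ids = set(frame["sample_id"].astype(str)) - set(nonzero["sample_id"].astype(str))
    keep_zero = long[long["sample_id"].astype(str).isin(empty_ids)].drop_duplicates("sample_id")
    return pd.concat([nonzero, keep_zero], ignore_index=True)


def long_to_wide(frame: pd.DataFrame) -> pd.DataFrame:
    wide = (
        frame.pivot_table(
            index=META_COLUMNS, columns="species", values="abundance", fill_value=0, aggfunc="sum"
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
    return wide


def read_sample_matrix(path, dialect: str = "long") -> SampleMatrix:
    """Read a sample matrix from CSV; ``dialect`` is ``long`` or ``wide``."""
    frame = pd.read_csv(path)
    if dialect == "wide":
        frame = wide_to_long(frame)
    elif dialect != "long":
        raise ValueError("dialect must be 'long' or 'wide'")
    return SampleMatrix(frame)


def write_sample_matrix(data: SampleMatrix, path, dialect: str = "long") -> None:
    if dialect == "long":
        data.frame.to_csv(path, index=False)
    elif dialect == "wide":
        long_to_wide(data.frame).to_csv(path, index=False)
    else:
        raise ValueError("dialect must be 'long' or 'wide'")


def report_table(
    results: Mapping[str, OptResult],
    path,
    budget: Optional[float] = None,
) -> pd.DataFrame:
    """Write the optimal protocol per diversity dimension as CSV.

    One row per dimension label: per-method sample counts of the best
    allocation within ``budget`` (or overall), its cost, and the achieved
    proportion of diversity / efficiency, formatted to 3 decimals.
    """
    methods = sorted({m for r in results.values() for m in r.methods})
    rows = []
    for label, result in results.items():
        entry = result.best(budget)
        row = {"dimension": label}
        row.update({m: entry.combination[m] for m in methods})
        row["cost"] = entry.cost
        row["value"] = f"{entry.value:.3f}"
        rows.append(row)
    table = pd.DataFrame(rows, columns=["dimension", *methods, "cost", "value"])
    table.to_csv(path, index=False)
    return table


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record tying a run's outputs to its exact inputs."""

    command: str
    seed: Optional[int]
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = ""
    created: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.created:
            self.created = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
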