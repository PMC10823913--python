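"""Tabular I/O and run configuration.

The published tree-table schema has exactly five columns —
``cellID25, sp, n, dbh, h`` — one row per set of identical stems in a
cell (``n`` an integer >= 1). CSV dialect everywhere: comma separator,
'.' decimal, UTF-8, no index column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import ConfigurationError, InvalidInputError

__all__ = ["RunConfig", "write_tree_table", "read_tree_table",
           "load_config", "save_model_sets", "load_model_sets"]

TREE_COLUMNS = ["cellID25", "sp", "n", "dbh", "h"]


@dataclass
class RunConfig:
    """Options steering a pipeline run (paths, matching, rounding seed)."""

    plots_path: str | None = None
    metrics_path: str | None = None
    output_dir: str = "."
    strata: dict = field(default_factory=dict)
    broadleaf: dict[str, bool] = field(default_factory=dict)
    model_transform: str = "none"
    max_vars: int = 6
    min_plots_per_stratum: int = 30
    forest_type_matching: bool = False
    seed: int = 0
    height_site: str = "bauges"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)


def write_tree_table(table: pd.DataFrame, path) -> None:
    """Write the generated tree table in the published schema.

    Identical (cellID25, sp, dbh, h) rows are merged with summed n; rows
    are ordered by (cellID25, sp, dbh) so output is deterministic. A row
    with n < 1 is an internal invariant violation and raises.
    """
    df = table.copy()
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"tree table missing columns: {missing}")
    if len(df) and (df["n"] < 1).any():
        raise InvalidInputError("tree table contains a row with n < 1")
    df = (
        df.groupby(["cellID25", "sp", "dbh", "h"], as_index=False)["n"]
        .sum()
        .sort_values(["cellID25", "sp", "dbh"], kind="mergesort")
    )
    df["n"] = df["n"].astype(int)
    df[TREE_COLUMNS].to_csv(path, index=False)


def read_tree_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"tree table missing columns: {missing}")
    return df


def save_model_sets(model_sets: dict, path) -> None:
    """Serialize fitted model sets to YAML (reproduces predictions exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {var: ms.to_dict() for var, ms in model_sets.items()},
            fh,
            sort_keys=True,
        )


def load_model_sets(path) -> dict:
    from .models import StratifiedModelSet

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {var: StratifiedModelSet.from_dict(d) for var, d in raw.items()}
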