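"""Mixed-type species trait tables (numeric / categorical / ordinal)."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: column-type tags understood by the Gower machinery downstream
NUMERIC, CATEGORICAL, ORDINAL = "numeric", "categorical", "ordinal"


def simulate_trait_table(
    n_species: int,
    n_numeric: int = 4,
    n_categorical: int = 2,
    n_ordinal: int = 2,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a species x trait table with declared column types.

    Numeric traits are uniform on [0, 1); categorical traits have 2-6
    levels; ordinal traits have ordered integer levels 0..L-1. Returns
    (table, column_types). The default 4+2+2 layout yields 8 traits.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if n_numeric + n_categorical + n_ordinal < 1:
        raise ValueError("need at least one trait column")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]
    data: dict[str, np.ndarray] = {}
    types: dict[str, str] = {}
    for i in range(n_numeric):
        name = f"num{i + 1}"
        data[name] = rng.random(n_species)
        types[name] = NUMERIC
    for i in range(n_categorical):
        name = f"cat{i + 1}"
        n_levels = int(rng.integers(2, 7))
        data[name] = np.array([f"level{j}" for j in rng.integers(0, n_levels, n_species)])
        types[name] = CATEGORICAL
    for i in range(n_ordinal):
        name = f"ord{i + 1}"
        n_levels = int(rng.integers(3, 6))
        data[name] = rng.integers(0, n_levels, n_species).astype(float)
        types[name] = ORDINAL
    table = pd.DataFrame(data, index=pd.Index(species, name="species"))
    if missing_rate > 0:
        holes = rng.random(table.shape) < missing_rate
        table = table.mask(holes)
    return table, types


def trait_table_to_csv(table: pd.DataFrame, types: dict[str, str], path) -> None:
    """Write the table with a second header row carrying the column types."""
    header = pd.DataFrame([types], index=pd.Index(["#type"], name="species"))
    pd.concat([header, table.astype(object)]).to_csv(path)


def trait_table_from_csv(path) -> tuple[pd.DataFrame, dict[str, str]]:
    raw = pd.read_csv(path, index_col=0, dtype=object)
    types = raw.loc["#type"].to_dict()
    table = raw.drop(index="#type")
    for col, t in types.items():
        if t in (NUMERIC, ORDINAL):
            table[col] = pd.to_numeric(table[col])
    table.index.name = "species"
    return table, types
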