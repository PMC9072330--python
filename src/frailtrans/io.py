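"""Reading and writing cohort tables as delimited text.

The column dictionary ships as a versioned schema file (``schema.yaml``);
missing values are empty cells.  Categorical levels are validated on read.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml


def load_schema() -> dict:
    with resources.files("frailtrans").joinpath("schema.yaml").open() as fh:
        return yaml.safe_load(fh)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a participant table, enforcing schema dtypes and level sets."""
    schema = load_schema()
    dtypes = {}
    for col in schema["columns"]:
        if col["type"] in ("categorical", "string"):
            dtypes[col["name"]] = "object"
        else:
            dtypes[col["name"]] = "float64"
    df = pd.read_csv(path, dtype=dtypes)
    missing_cols = [c["name"] for c in schema["columns"] if c["name"] not in df.columns]
    if missing_cols:
        raise ValueError(f"input is missing schema columns: {missing_cols}")
    for col in schema["columns"]:
        if col["type"] == "categorical":
            levels = set(map(str, col["levels"]))
            bad = set(df[col["name"]].dropna().unique()) - levels
            if bad:
                raise ValueError(f"column {col['name']!r} has unknown levels {sorted(bad)}")
        elif col["type"] == "binary":
            vals = df[col["name"]].dropna()
            if not vals.isin((0.0, 1.0)).all():
                raise ValueError(f"binary column {col['name']!r} has non-0/1 values")
    if df["gender"].isna().any():
        raise ValueError("gender must be non-missing for every participant")
    if (df["age"].dropna() <= 0).any():
        raise ValueError("age must be positive")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    schema = load_schema()
    cols = [c["name"] for c in schema["columns"] if c["name"] in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df.loc[:, cols + extra].to_csv(path, index=False)
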