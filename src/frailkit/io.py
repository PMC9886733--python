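"""Cohort and report I/O.

Cohort files are plain CSV with a header row, one subject per row, and empty
cells for missing values.  The codebook (YAML) is the single source of truth
for column typing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .deficits import Codebook

logger = logging.getLogger(__name__)

__all__ = ["read_cohort", "write_cohort"]


def read_cohort(path, codebook: Codebook) -> pd.DataFrame:
    """Read and validate a cohort CSV against the codebook.

    Continuous deficit columns and numeric covariates are parsed as floats;
    binary/ordinal deficits keep their raw representation (numeric when
    parseable).  Empty cells become missing.  Unknown columns are reported at
    warning level but retained.
    """
    df = pd.read_csv(path, na_values=[""], keep_default_na=False)
    declared = set(codebook.names) | set(codebook.covariates.values())
    missing = [c for c in codebook.names if c not in df.columns]
    if missing:
        raise KeyError(f"cohort lacks declared deficit column(s): {missing}")
    unknown = [c for c in df.columns if c not in declared]
    if unknown:
        logger.warning("cohort has %d column(s) not declared in the codebook: %s", len(unknown), unknown)

    for spec in codebook.deficits:
        col = df[spec.name]
        if spec.kind == "continuous":
            try:
                df[spec.name] = pd.to_numeric(col)
            except (ValueError, TypeError) as exc:
                bad = col[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
                row = bad.index[0] if len(bad) else "?"
                raise ValueError(
                    f"unparseable cell in column {spec.name!r}, row {row}: {bad.iloc[0] if len(bad) else ''!r}"
                ) from exc
        else:
            numeric = pd.to_numeric(col, errors="coerce")
            if numeric.notna().sum() == col.notna().sum():
                df[spec.name] = numeric
    for role in ("age", "education", "cdrsb", "mmse", "time", "event"):
        name = codebook.covariate(role)
        if name and name in df.columns:
            df[name] = pd.to_numeric(df[name], errors="coerce")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV with empty strings for missing cells."""
    out = df.copy()
    # avoid "1.0" artefacts for integer-valued object columns
    for c in out.columns:
        if out[c].dtype == object:
            out[c] = out[c].map(lambda v: int(v) if isinstance(v, float) and not np.isnan(v) and v == int(v) else v)
    out.to_csv(path, index=False, na_rep="")
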