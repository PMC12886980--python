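"""Delimited-text persistence for cohort and count tables.

Cohorts are CSV (one header row, one row per child, categorical fields as
lowercase tokens, missing values as empty cells). Count tables are TSV with
the sample id in the first column, plus companion taxonomy and run-label
TSVs sharing the same base path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from stuntsem.cohort import REQUIRED_COHORT_COLUMNS
from stuntsem.taxa import TaxaCountTable

_CATEGORY_COLUMNS = ("child_id", "stunting_category", "aat_class", "birth_size")


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> Path:
    """Write a cohort table as CSV; returns the path written."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises if mandatory columns are missing or child ids are duplicated.
    """
    df = pd.read_csv(path, dtype={c: "string" for c in _CATEGORY_COLUMNS})
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    dup = df["child_id"][df["child_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated child ids: {sorted(set(dup))}")
    for c in _CATEGORY_COLUMNS:
        df[c] = df[c].astype(object)
    return df


def _counts_paths(base: str | Path) -> tuple[Path, Path, Path]:
    base = Path(base)
    return (
        base.with_suffix(".counts.tsv"),
        base.with_suffix(".taxonomy.tsv"),
        base.with_suffix(".runs.tsv"),
    )


def write_counts(base: str | Path, table: TaxaCountTable) -> tuple[Path, Path, Path]:
    """Write a count table as three TSVs (counts, taxonomy, run labels).

    ``base`` is a path prefix; suffixes ``.counts.tsv``, ``.taxonomy.tsv``
    and ``.runs.tsv`` are appended.
    """
    counts_p, tax_p, runs_p = _counts_paths(base)
    table.counts.to_csv(counts_p, sep="\t")
    table.taxonomy.to_csv(tax_p, sep="\t")
    table.run_label.to_frame().to_csv(runs_p, sep="\t")
    return counts_p, tax_p, runs_p


def read_counts(base: str | Path) -> TaxaCountTable:
    """Read a count table written by :func:`write_counts`, with validation.

    Raises on non-integer or negative counts (naming the offending sample and
    taxon) and on duplicated sample ids.
    """
    counts_p, tax_p, runs_p = _counts_paths(base)
    counts = pd.read_csv(counts_p, sep="\t", index_col="sample_id")
    if counts.index.duplicated().any():
        dups = sorted(set(counts.index[counts.index.duplicated()]))
        raise ValueError(f"duplicated sample ids: {dups}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr), atol=0, rtol=0):
            bad = np.argwhere(arr != np.round(arr))[0]
            raise ValueError(
                f"non-integer count at sample {counts.index[bad[0]]!r}, "
                f"taxon {counts.columns[bad[1]]!r}"
            )
        counts = counts.astype(int)
        arr = counts.to_numpy()
    if (arr < 0).any():
        bad = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at sample {counts.index[bad[0]]!r}, "
            f"taxon {counts.columns[bad[1]]!r}"
        )
    taxonomy = pd.read_csv(tax_p, sep="\t", index_col="taxon")
    run = pd.read_csv(runs_p, sep="\t", index_col="sample_id")["run_label"]
    return TaxaCountTable(counts=counts, taxonomy=taxonomy, run_label=run)
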