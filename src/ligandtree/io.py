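"""Table readers/writers, schemas, and the packaged cell-line fixture.

One flat dialect for all pipeline tables: comma-separated, UTF-8, header
row, ``#`` comment lines allowed (written artifacts carry the config hash
of the run that produced them in such a comment).  The packaged cell-line
reference table is tab-separated with receptor columns in thousands per
cell (suffix ``_thousand_per_cell``), converted to molecules/cell on load.
"""

from __future__ import annotations

import hashlib
import io as _io
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .network import CellLineContext


class TableSchemaError(ValueError):
    """A table does not match its declared schema."""


#: schema name -> (required columns, numeric columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "cell_lines": (
        ("cell_line", "kras_mutation", "pik3ca_mutation", "egfr_thousand_per_cell",
         "her2_thousand_per_cell", "erbb3_thousand_per_cell", "met_thousand_per_cell"),
        ("egfr_thousand_per_cell", "her2_thousand_per_cell",
         "erbb3_thousand_per_cell", "met_thousand_per_cell"),
    ),
    "measurements": (
        ("cell_line", "observable", "condition", "time_min", "replicate", "value", "sigma"),
        ("time_min", "replicate", "value", "sigma"),
    ),
    "viability": (
        ("cell_line", "treatment", "day", "replicate", "value"),
        ("day", "replicate", "value"),
    ),
    "features": (("cell_line", "ligand"), ()),
    "calls": (("cell_line", "treatment", "ratio", "p_value", "responder"),
              ("ratio", "p_value")),
    "evaluation": (("rep", "ligand", "accuracy"), ("rep", "accuracy")),
    "expression": ((), ()),
}


def read_table(path, schema: str, sep: str = ",") -> pd.DataFrame:
    """Read and schema-check a table; raises :class:`TableSchemaError`
    naming the missing column or the first offending row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise TableSchemaError(f"{path}: file is empty") from exc
    except pd.errors.ParserError as exc:
        raise TableSchemaError(
            f"{path}: could not parse (wrong delimiter? expected {sep!r}): {exc}"
        ) from exc
    if len(df) == 0:
        raise TableSchemaError(f"{path}: table has no rows")
    required, numeric = SCHEMAS[schema]
    if required and len(df.columns) == 1 and sep not in str(df.columns[0]):
        # a single mega-column usually means the wrong delimiter
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableSchemaError(
                f"{path}: only one column parsed — wrong delimiter? expected {sep!r}"
            )
    for col in required:
        if col not in df.columns:
            raise TableSchemaError(f"{path}: missing required column {col!r}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise TableSchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row}"
            )
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Write a pipeline table; prepends the producing config hash as a
    comment so every artifact is traceable to its run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if config_hash:
        buf.write(f"# config: {config_hash}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def config_hash(obj) -> str:
    """Stable short hash of any YAML-serializable configuration object."""
    text = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# packaged cell-line reference table

def load_cell_line_table() -> pd.DataFrame:
    """The packaged 58-line reference panel (receptor surface levels in
    thousands per cell plus KRAS/PIK3CA mutation annotations)."""
    with resources.as_file(resources.files("ligandtree.data") / "cell_lines.tsv") as p:
        return read_table(p, "cell_lines", sep="\t")


def contexts_from_table(df: pd.DataFrame, igf1r_thousand: float = 30.0) -> list[CellLineContext]:
    """Build simulation contexts from the reference table.

    Receptor columns are in thousands/cell (multiplied by 1e3 on load).
    The table carries no IGF-1R column; it is imputed as a constant
    (default 30k molecules/cell, the scale of the ErbB3/Met columns) and
    flagged in the returned contexts.
    """
    contexts = []
    for _, row in df.iterrows():
        contexts.append(CellLineContext(
            name=row["cell_line"],
            receptor_expression={
                "EGFR": row["egfr_thousand_per_cell"] * 1e3,
                "HER2": row["her2_thousand_per_cell"] * 1e3,
                "ErbB3": row["erbb3_thousand_per_cell"] * 1e3,
                "Met": row["met_thousand_per_cell"] * 1e3,
                "IGF1R": igf1r_thousand * 1e3,
            },
            kras_mutant=str(row["kras_mutation"]).strip().lower() != "wt",
            pik3ca_mutant=str(row["pik3ca_mutation"]).strip().lower() != "wt",
            igf1r_imputed=True,
        ))
    return contexts


def fixture_contexts(igf1r_thousand: float = 30.0) -> list[CellLineContext]:
    return contexts_from_table(load_cell_line_table(), igf1r_thousand=igf1r_thousand)


def mutation_frequencies() -> tuple[float, float]:
    """(KRAS, PIK3CA) mutant fractions of the packaged panel, computed at
    run time from the table."""
    df = load_cell_line_table()
    kras = (df["kras_mutation"].str.strip().str.lower() != "wt").mean()
    pik = (df["pik3ca_mutation"].str.strip().str.lower() != "wt").mean()
    return float(kras), float(pik)
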