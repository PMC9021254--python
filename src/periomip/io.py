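"""Readers and writers for the tabular and tree formats the pipeline touches.

In-memory conventions
---------------------
* **Count table** — :class:`pandas.DataFrame`, samples as rows, features as
  columns, non-negative integer counts.  This is the orientation every other
  module expects; :func:`read_count_table` normalises to it.
* **Sample metadata** — :class:`pandas.DataFrame` indexed by ``sample_id``.
  Known clinical/demographic columns are typed; anything else is kept as a
  string column.  Missing values (``NA`` or empty cells) become ``NaN`` and
  propagate to per-model listwise deletion downstream.
* **Taxonomy** — :class:`pandas.Series` mapping ``feature_id`` to a
  semicolon-delimited lineage string (``k__...; p__...; ...; s__...``).
* **Phylogeny** — :class:`skbio.TreeNode`, rooted, non-negative branch
  lengths.

All TSV I/O is tab-delimited UTF-8; lines starting with ``#`` are treated as
comments except the QIIME-style ``#OTU ID`` feature-table header.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FormatError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "validate_count_table",
    "NUMERIC_METADATA_COLUMNS",
    "CATEGORICAL_METADATA_COLUMNS",
]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


#: Metadata columns coerced to float on read.
NUMERIC_METADATA_COLUMNS = (
    "pocket_depth_mm",
    "attachment_loss_mm",
    "pct_bop",
    "meansbp",
    "meandbp",
    "glucose",
    "insulin",
    "homa_ir",
    "hba1c",
    "age",
    "bmi",
    "faith_pd",
)

#: Metadata columns kept as (pandas string) categoricals.
CATEGORICAL_METADATA_COLUMNS = ("participant_id", "site_class", "sex", "race", "smoking")


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples × features count table and return it as int64.

    Raises :class:`FormatError` on duplicate identifiers, negative or
    non-integer entries.
    """
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers: {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature identifiers: {dups}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = _first_bad_cell(table, lambda v: not _is_number(v))
        raise FormatError(f"non-numeric count at sample {bad[0]!r}, feature {bad[1]!r}")
    if np.isnan(values.astype(float)).any():
        bad = _first_bad_cell(table, lambda v: pd.isna(v))
        raise FormatError(f"missing count at sample {bad[0]!r}, feature {bad[1]!r}")
    if (values < 0).any():
        bad = _first_bad_cell(table, lambda v: float(v) < 0)
        raise FormatError(f"negative count at sample {bad[0]!r}, feature {bad[1]!r}")
    return table.astype(np.int64)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_bad_cell(table: pd.DataFrame, pred):
    for sid, row in table.iterrows():
        for fid, v in row.items():
            if pred(v):
                return sid, fid
    raise AssertionError("no offending cell found")


def _read_tsv_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    lines = []
    for ln in text.splitlines():
        if ln.startswith("#") and not ln.startswith("#OTU ID"):
            continue
        if ln.strip() == "":
            continue
        lines.append(ln)
    return lines


def read_count_table(path, orientation: str = "auto") -> pd.DataFrame:
    """Read a TSV feature table and return a samples × features DataFrame.

    Parameters
    ----------
    path : path-like
        Tab-separated table with one header row.
    orientation : {"auto", "samples_as_rows", "features_as_rows"}
        ``auto`` recognises the QIIME ``#OTU ID`` header as features-as-rows
        and otherwise requires an explicit orientation (it refuses to guess).
    """
    lines = _read_tsv_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty table")
    header_is_otu = lines[0].startswith("#OTU ID")
    if orientation == "auto":
        if header_is_otu:
            orientation = "features_as_rows"
        else:
            raise FormatError(
                f"{path}: cannot auto-detect orientation (no '#OTU ID' header); "
                "pass orientation='samples_as_rows' or 'features_as_rows'"
            )
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        r = mask.any(axis=1).idxmax()
        c = mask.loc[r].idxmax()
        raise FormatError(f"{path}: non-numeric cell at row {r!r}, column {c!r}")
    if orientation == "features_as_rows":
        numeric = numeric.T
    numeric.index.name = "sample_id"
    numeric.columns.name = "feature_id"
    return validate_count_table(numeric)


def write_count_table(table: pd.DataFrame, path, orientation: str = "samples_as_rows") -> None:
    """Write a count table as TSV; ``features_as_rows`` emits a QIIME-style export."""
    table = validate_count_table(table)
    path = Path(path)
    if orientation == "samples_as_rows":
        out = table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
    elif orientation == "features_as_rows":
        out = table.T
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV (first column ``sample_id``).

    Known numeric columns are coerced to float with ``NA``/empty treated as
    missing; an unparsable numeric cell raises :class:`FormatError` naming the
    row and column.  Unknown columns are preserved as strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    if df.columns[0] != "sample_id":
        df = df.rename(columns={df.columns[0]: "sample_id"})
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample_id values: {dups}")
    df = df.set_index("sample_id")
    df = df.replace({"NA": np.nan, "": np.nan})
    for col in df.columns:
        if col in NUMERIC_METADATA_COLUMNS:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = bad.idxmax()
                raise FormatError(f"{path}: unparsable numeric value at row {row!r}, column {col!r}")
            df[col] = coerced
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_taxonomy(path) -> pd.Series:
    """Read a two-column TSV of ``feature_id<TAB>lineage``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None, names=["feature_id", "lineage"])
    if df["feature_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate feature_id in taxonomy")
    return pd.Series(df["lineage"].values, index=df["feature_id"].values, name="lineage")


def write_taxonomy(taxonomy: pd.Series, path) -> None:
    pd.DataFrame({"feature_id": taxonomy.index, "lineage": taxonomy.values}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree.

    A trifurcating (or worse) top level is rejected as unrooted; negative
    branch lengths raise; a missing length is treated as 0 with a warning.
    Internal polytomies below the root are allowed.
    """
    tree = TreeNode.read(str(path), format="newick")
    if len(tree.children) > 2:
        raise FormatError(
            f"{path}: top-level {len(tree.children)}-furcation — tree appears unrooted; "
            "root it (e.g. midpoint or outgroup rooting) before use"
        )
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError(f"{path}: duplicate leaf labels")
    missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            missing += 1
        elif node.length < 0:
            raise FormatError(f"{path}: negative branch length on {node.name!r}")
    if missing:
        warnings.warn(f"{path}: {missing} branch(es) had no length; treated as 0", stacklevel=2)
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# -- FASTQ (PHRED offset fixed at 33; gzip-aware) ---------------------------

PHRED_OFFSET = 33


def _open_maybe_gzip(path, mode="rt"):
    import gzip

    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ as ``(read_id, sequence, phred_scores)`` tuples."""
    records = []
    with _open_maybe_gzip(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: FASTQ length not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        idx = i // 4
        if not head.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed FASTQ record at index {idx}")
        if len(seq) != len(qual):
            raise FormatError(f"{path}: sequence/quality length mismatch at record {idx}")
        records.append((head[1:].split()[0], seq, [ord(c) - PHRED_OFFSET for c in qual]))
    return records


def write_fastq(records, path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for rid, seq, quals in records:
            qstr = "".join(chr(q + PHRED_OFFSET) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
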