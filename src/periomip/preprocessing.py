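"""Read- and table-level filters, taxonomic collapse, and table merging.

The read-level rule mirrors QIIME's q-score filter: a read is truncated at
the start of the first run of ``run_length`` consecutive basecalls with PHRED
at or below ``phred_floor``, and discarded entirely if the truncated length
falls below ``min_fraction`` of the original.  Table-level filters drop
samples below a minimum depth and features below a minimum prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import validate_count_table

__all__ = [
    "QualityFilterParams",
    "TrimReport",
    "quality_trim",
    "filter_samples_by_depth",
    "filter_features_by_prevalence",
    "collapse_taxonomy",
    "merge_tables",
    "RANKS",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))


@dataclass(frozen=True)
class QualityFilterParams:
    """Quality-trim thresholds (defaults follow the QIIME q-score defaults)."""

    phred_floor: int = 4
    run_length: int = 3
    min_fraction: float = 0.75
    phred_offset: int = 33

    def __post_init__(self):
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")


@dataclass
class TrimReport:
    n_input: int = 0
    n_kept_untrimmed: int = 0
    n_trimmed: int = 0
    n_removed: int = 0

    @property
    def n_output(self) -> int:
        return self.n_kept_untrimmed + self.n_trimmed


def _trim_point(quals: list[int], params: QualityFilterParams) -> int | None:
    """0-based index at which to truncate, or None if the read passes whole.

    The read is cut immediately before the first base of the first window of
    ``run_length`` consecutive calls with PHRED <= ``phred_floor``.
    """
    q = np.asarray(quals)
    low = q <= params.phred_floor
    if len(low) < params.run_length:
        return None
    window = np.convolve(low.astype(int), np.ones(params.run_length, dtype=int), "valid")
    hits = np.nonzero(window == params.run_length)[0]
    if hits.size == 0:
        return None
    return int(hits[0])


def quality_trim(records, params: QualityFilterParams | None = None):
    """Apply the trim-and-drop rule to FASTQ records.

    Parameters
    ----------
    records : iterable of (read_id, sequence, phred_scores)
    params : QualityFilterParams

    Returns
    -------
    (kept_records, report)
    """
    params = params or QualityFilterParams()
    report = TrimReport()
    kept = []
    for idx, rec in enumerate(records):
        try:
            rid, seq, quals = rec
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed FASTQ record at index {idx}") from exc
        if len(seq) != len(quals):
            raise ValueError(f"malformed FASTQ record at index {idx}: length mismatch")
        report.n_input += 1
        cut = _trim_point(list(quals), params)
        if cut is None:
            report.n_kept_untrimmed += 1
            kept.append((rid, seq, list(quals)))
        elif cut < params.min_fraction * len(seq):
            report.n_removed += 1
        else:
            report.n_trimmed += 1
            kept.append((rid, seq[:cut], list(quals[:cut])))
    return kept, report


def filter_samples_by_depth(table: pd.DataFrame, min_reads: int = 1000) -> pd.DataFrame:
    """Drop samples with fewer than ``min_reads`` total counts.

    The boundary is "less than": a sample with exactly ``min_reads`` is kept.
    """
    table = validate_count_table(table)
    if table.shape[0] == 0:
        raise ValueError("empty table")
    keep = table.sum(axis=1) >= min_reads
    if not keep.any():
        raise ValueError(f"all samples have < {min_reads} reads")
    return table.loc[keep]


def filter_features_by_prevalence(table: pd.DataFrame, min_fraction: float = 0.01) -> pd.DataFrame:
    """Keep features present (count > 0) in at least ``min_fraction`` of samples.

    The threshold is inclusive: exactly 1% prevalence survives the default.
    """
    table = validate_count_table(table)
    prevalence = (table > 0).mean(axis=0)
    keep = prevalence >= min_fraction
    if not keep.any():
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return table.loc[:, keep]


def _lineage_prefix(lineage: str, rank: str) -> str:
    """Lineage truncated at ``rank``; features unassigned at that rank pool
    under their deepest assigned prefix."""
    depth = RANKS.index(rank) + 1
    parts = [p.strip() for p in str(lineage).split(";")]
    parts = parts[:depth]
    # strip trailing empty assignments like "s__" so they pool at genus level
    while parts and len(parts[-1]) <= 3:
        parts = parts[:-1]
    return ";".join(parts) if parts else "unassigned"


def collapse_taxonomy(table: pd.DataFrame, taxonomy: pd.Series, rank: str = "species") -> pd.DataFrame:
    """Sum features sharing a lineage prefix down to ``rank``.

    Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    table = validate_count_table(table)
    missing = [f for f in table.columns if f not in taxonomy.index]
    if missing:
        raise ValueError(f"features without lineage: {missing[:5]}")
    keys = [_lineage_prefix(taxonomy.loc[f], rank) for f in table.columns]
    collapsed = table.T.groupby(pd.Index(keys, name="lineage"), sort=True).sum().T
    return collapsed


def merge_tables(a: pd.DataFrame, b: pd.DataFrame):
    """Outer-join two count tables on features, zero-filling.

    Sample ids must be disjoint.  Returns the merged table plus an overlap
    report ``{"unique_to_a": int, "unique_to_b": int, "shared": int}``.
    """
    a = validate_count_table(a)
    b = validate_count_table(b)
    overlap_samples = set(a.index) & set(b.index)
    if overlap_samples:
        raise ValueError(f"overlapping sample ids: {sorted(overlap_samples)[:5]}")
    fa, fb = set(a.columns), set(b.columns)
    report = {
        "unique_to_a": len(fa - fb),
        "unique_to_b": len(fb - fa),
        "shared": len(fa & fb),
    }
    merged = pd.concat([a, b], axis=0).fillna(0).astype(np.int64)
    return merged, report
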