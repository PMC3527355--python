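"""Taxa-by-sample count tables: containers, IO, rare-taxa pooling, RAD ranking.

The central layout is the classic microbiome count matrix: ``P`` samples in
rows, ``K`` taxa in columns, cell ``X[i, k]`` holding the number of sequence
reads from sample ``i`` assigned to taxon ``k``. A taxon absent from a sample
is an explicit zero, never missing. Row totals ``N_i`` (reads per sample),
column totals and the grand total are derived, never stored independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxaCountTable",
    "GroupedTables",
    "read_count_table",
    "read_biom_table",
    "read_group_assignments",
    "split_by_group",
    "pool_rare_taxa",
    "to_rank_abundance",
]

#: counts within this distance of an integer are rounded; beyond it, rejected
_INT_TOL = 1e-6


class TableValidationError(ValueError):
    """Raised when a count table violates its structural invariants."""


@dataclass(frozen=True)
class TaxaCountTable:
    """Immutable P x K table of non-negative integer read counts.

    Parameters
    ----------
    counts
        Integer matrix, samples in rows, taxa in columns.
    sample_ids
        Unique sample identifiers, one per row.
    taxon_labels
        Unique taxon names, one per column.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise TableValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.all(np.isfinite(counts)):
                raise TableValidationError("counts contain non-finite values")
            if np.max(np.abs(counts - rounded), initial=0.0) > _INT_TOL:
                bad = np.unravel_index(
                    int(np.argmax(np.abs(counts - rounded))), counts.shape
                )
                raise TableValidationError(
                    f"non-integer count {counts[bad]!r} at sample "
                    f"{self._label(bad[0], 'sample')}, taxon {self._label(bad[1], 'taxon')}"
                )
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=True)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise TableValidationError(
                f"negative count at sample {self._label(bad[0], 'sample')}, "
                f"taxon {self._label(bad[1], 'taxon')}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

        sample_ids = tuple(str(s) for s in self.sample_ids)
        taxon_labels = tuple(str(t) for t in self.taxon_labels)
        if len(sample_ids) != counts.shape[0]:
            raise TableValidationError(
                f"{len(sample_ids)} sample ids for {counts.shape[0]} rows"
            )
        if len(taxon_labels) != counts.shape[1]:
            raise TableValidationError(
                f"{len(taxon_labels)} taxon labels for {counts.shape[1]} columns"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise TableValidationError("duplicate sample ids")
        if len(set(taxon_labels)) != len(taxon_labels):
            raise TableValidationError("duplicate taxon labels")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "taxon_labels", taxon_labels)

    def _label(self, index: int, axis: str) -> str:
        ids = self.sample_ids if axis == "sample" else self.taxon_labels
        try:
            return repr(ids[index])
        except (IndexError, TypeError):
            return f"#{index}"

    # -- derived totals ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Reads per sample, ``N_i``."""
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Reads per taxon across samples."""
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Per-sample taxa frequencies X[i, k] / N_i (rows with 0 reads -> 0)."""
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / totals[:, None]
        return np.nan_to_num(p)

    # -- constructors / conversion ----------------------------------------
    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray | Sequence[Sequence[int]],
        sample_ids: Sequence[str] | None = None,
        taxon_labels: Sequence[str] | None = None,
    ) -> "TaxaCountTable":
        counts = np.asarray(counts)
        if sample_ids is None:
            sample_ids = [f"sample_{i + 1}" for i in range(counts.shape[0])]
        if taxon_labels is None:
            taxon_labels = [f"taxon_{k + 1}" for k in range(counts.shape[1])]
        return cls(counts, tuple(sample_ids), tuple(taxon_labels))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "TaxaCountTable":
        return cls(
            frame.to_numpy(),
            tuple(str(i) for i in frame.index),
            tuple(str(c) for c in frame.columns),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(),
            index=list(self.sample_ids),
            columns=list(self.taxon_labels),
        )

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        """Write in the samples-in-rows layout with a leading id column."""
        frame = self.to_dataframe()
        frame.index.name = "sample_id"
        frame.to_csv(path, sep=delimiter)

    # -- structural edits --------------------------------------------------
    def select_taxa(self, indices: Sequence[int]) -> "TaxaCountTable":
        idx = list(indices)
        return TaxaCountTable(
            self.counts[:, idx],
            self.sample_ids,
            tuple(self.taxon_labels[i] for i in idx),
        )

    def select_samples(self, indices: Sequence[int]) -> "TaxaCountTable":
        idx = list(indices)
        return TaxaCountTable(
            self.counts[idx, :],
            tuple(self.sample_ids[i] for i in idx),
            self.taxon_labels,
        )

    def reindex_taxa(self, labels: Sequence[str]) -> "TaxaCountTable":
        """Reorder columns onto ``labels``, zero-filling taxa not present."""
        pos = {t: k for k, t in enumerate(self.taxon_labels)}
        out = np.zeros((self.n_samples, len(labels)), dtype=np.int64)
        for j, lab in enumerate(labels):
            if lab in pos:
                out[:, j] = self.counts[:, pos[lab]]
        return TaxaCountTable(out, self.sample_ids, tuple(labels))


@dataclass(frozen=True)
class GroupedTables:
    """Ordered collection of (group label, table) sharing one taxon list."""

    groups: tuple[tuple[str, TaxaCountTable], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise TableValidationError("at least one group is required")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise TableValidationError("duplicate group labels")
        ref = self.groups[0][1].taxon_labels
        for name, table in self.groups:
            if table.n_samples < 1:
                raise TableValidationError(f"group {name!r} has no samples")
            if table.taxon_labels != ref:
                raise TableValidationError(
                    f"group {name!r} taxa differ from group "
                    f"{self.groups[0][0]!r}; align tables first"
                )
        object.__setattr__(self, "groups", tuple(self.groups))

    @classmethod
    def from_tables(
        cls, tables: Iterable[tuple[str, TaxaCountTable]], align: bool = True
    ) -> "GroupedTables":
        pairs = list(tables)
        if align and pairs:
            union: list[str] = []
            seen: set[str] = set()
            for _, t in pairs:
                for lab in t.taxon_labels:
                    if lab not in seen:
                        seen.add(lab)
                        union.append(lab)
            pairs = [(g, t.reindex_taxa(union)) for g, t in pairs]
        return cls(tuple(pairs))

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self) -> Iterator[tuple[str, TaxaCountTable]]:
        return iter(self.groups)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)

    @property
    def tables(self) -> tuple[TaxaCountTable, ...]:
        return tuple(t for _, t in self.groups)

    @property
    def taxon_labels(self) -> tuple[str, ...]:
        return self.groups[0][1].taxon_labels

    def combined(self) -> TaxaCountTable:
        """Stack all groups into one table (sample ids prefixed by group)."""
        counts = np.vstack([t.counts for _, t in self.groups])
        ids = [
            f"{g}:{s}" for g, t in self.groups for s in t.sample_ids
        ]
        return TaxaCountTable(counts, tuple(ids), self.taxon_labels)

    def map_tables(self, fn) -> "GroupedTables":
        return GroupedTables(tuple((g, fn(t)) for g, t in self.groups))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    orientation: str = "samples-in-rows",
    delimiter: str | None = None,
) -> TaxaCountTable:
    """Read a delimited count table.

    The first column holds row labels and the header row column labels.
    ``orientation`` is ``"samples-in-rows"`` (default) or ``"taxa-in-rows"``
    (the table is transposed after reading). The delimiter is sniffed from
    the extension (``.csv`` -> comma, otherwise tab) unless given.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as exc:
        raise TableValidationError(f"cannot parse {path}: {exc}") from exc
    if frame.empty:
        raise TableValidationError(f"{path} contains no counts")
    non_numeric = frame.columns[
        [not np.issubdtype(d, np.number) for d in frame.dtypes]
    ]
    if len(non_numeric):
        raise TableValidationError(
            f"non-numeric column(s) {list(non_numeric)} in {path}"
        )
    if orientation not in ("samples-in-rows", "taxa-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "taxa-in-rows":
        frame = frame.T
    return TaxaCountTable.from_dataframe(frame)


def read_biom_table(path: str | Path) -> TaxaCountTable:
    """Read a BIOM v1 (JSON) table; BIOM stores observations (taxa) in rows."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])  # (taxa, samples)
    dense = np.zeros(shape, dtype=float)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            dense[int(r), int(c)] = v
    else:
        dense = np.asarray(doc["data"], dtype=float)
    return TaxaCountTable.from_counts(dense.T, samples, taxa)


def read_group_assignments(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (sample_id, group) mapping; header optional."""
    frame = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if frame.shape[1] < 2:
        raise TableValidationError(f"{path} must have two columns")
    first = frame.iloc[0]
    if str(first[0]).lower() in ("sample", "sample_id", "id"):
        frame = frame.iloc[1:]
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def split_by_group(
    table: TaxaCountTable, assignment: dict[str, str]
) -> GroupedTables:
    """Split one table into groups according to a sample -> group map."""
    missing = [s for s in table.sample_ids if s not in assignment]
    if missing:
        raise TableValidationError(f"samples without group assignment: {missing}")
    order: list[str] = []
    for s in table.sample_ids:
        g = assignment[s]
        if g not in order:
            order.append(g)
    pairs = []
    for g in order:
        idx = [i for i, s in enumerate(table.sample_ids) if assignment[s] == g]
        pairs.append((g, table.select_samples(idx)))
    return GroupedTables(tuple(pairs))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def pool_rare_taxa(
    tables: GroupedTables | TaxaCountTable,
    threshold: float = 0.01,
    pooled_label: str = "Pooled taxa",
    drop: bool = False,
):
    """Combine rare taxa into one pooled column (or drop them).

    A taxon is rare when its weighted-average frequency over all groups
    combined — pooled column total divided by pooled grand total — is
    strictly below ``threshold``. Rare columns are summed into a single
    taxon appended last; retained taxa keep their order, and every sample's
    read total is unchanged. With ``drop=True`` rare columns are removed
    instead of pooled (read totals then shrink).
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    single = isinstance(tables, TaxaCountTable)
    grouped = (
        GroupedTables((("all", tables),)) if single else tables
    )
    totals = np.sum([t.col_totals for t in grouped.tables], axis=0)
    grand = totals.sum()
    if grand == 0:
        raise TableValidationError("cannot pool an all-zero table")
    freqs = totals / grand
    rare = freqs < threshold
    if rare.all():
        raise TableValidationError(
            "every taxon falls below the pooling threshold; "
            "lower the threshold or drop taxa explicitly"
        )
    if not rare.any():
        return tables
    keep = np.flatnonzero(~rare)
    pool = np.flatnonzero(rare)
    kept_labels = [grouped.taxon_labels[k] for k in keep]
    if not drop and pooled_label in kept_labels:
        raise TableValidationError(
            f"pooled label {pooled_label!r} collides with a retained taxon"
        )

    def transform(t: TaxaCountTable) -> TaxaCountTable:
        kept = t.counts[:, keep]
        if drop:
            return TaxaCountTable(kept, t.sample_ids, tuple(kept_labels))
        pooled = t.counts[:, pool].sum(axis=1, keepdims=True)
        return TaxaCountTable(
            np.hstack([kept, pooled]),
            t.sample_ids,
            tuple(kept_labels) + (pooled_label,),
        )

    out = grouped.map_tables(transform)
    return out.groups[0][1] if single else out


def to_rank_abundance(table: TaxaCountTable) -> TaxaCountTable:
    """Sort each sample's counts in non-increasing order, discarding labels.

    The result is the rank abundance distribution (RAD) view: column ``j``
    holds each sample's ``j``-th most abundant count, under positional labels
    ``rank_1 .. rank_K``. Ranking is per sample, so a column no longer refers
    to one taxon. Ties keep their original relative order (stable sort).
    """
    order = np.argsort(-table.counts, axis=1, kind="stable")
    ranked = np.take_along_axis(table.counts, order, axis=1)
    labels = tuple(f"rank_{j + 1}" for j in range(table.n_taxa))
    return TaxaCountTable(ranked, table.sample_ids, labels)
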