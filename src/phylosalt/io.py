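"""Data model and file IO: count tables, sample metadata, Newick trees.

Count tables are taxa-as-rows, samples-as-columns TSV. Trees are Newick read
into :class:`skbio.TreeNode`. ID matching is exact and case-sensitive
throughout: silent case-folding hides upstream errors.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import log_stage, logger

ORIGINS = ("fresh", "salt")


class TaxonCountTable:
    """Integer read counts of taxa (rows) across samples (columns).

    Wraps a pandas DataFrame and enforces the container invariants: unique
    IDs on both axes, non-negative integer counts, at least one taxon and
    one sample.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("count table needs at least one taxon and one sample")
        dup_t = data.index[data.index.duplicated()].unique().tolist()
        if dup_t:
            raise ValueError(f"duplicate taxon ID(s): {dup_t}")
        dup_s = data.columns[data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample ID(s): {dup_s}")
        arr = data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count table contains non-numeric cells")
        if np.any(arr < 0):
            bad = data.columns[np.any(arr < 0, axis=0)].tolist()
            raise ValueError(f"negative counts in sample(s): {bad}")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("count table contains non-integer cells")
        self.data = data.astype(np.int64)
        self.data.index.name = "taxon_id"

    # -- convenience views ------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    @property
    def taxon_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.data.to_numpy().sum())

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample read fractions (columns sum to 1)."""
        totals = self.sample_totals
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"zero-total sample(s): {bad}")
        return self.data / totals

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonCountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"TaxonCountTable({len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples)"


class SampleMetadata:
    """Per-sample design factors: origin, host (each fresh/salt), replicate.

    Extra numeric columns (salinity, sulfate, ...) ride along and are
    available to :func:`summarize_env_by_factor`.
    """

    REQUIRED = ("origin", "host", "replicate")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"metadata missing column(s): {missing}")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ID(s) in metadata: {dup}")
        for col in ("origin", "host"):
            bad = set(data[col]) - set(ORIGINS)
            if bad:
                raise ValueError(f"{col} values must be in {ORIGINS}, got {sorted(bad)}")
        if (data["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be positive")
        triples = data[["origin", "host", "replicate"]]
        if triples.duplicated().any():
            raise ValueError("(origin, host, replicate) triples must be unique")
        self.data = data.copy()
        self.data["replicate"] = self.data["replicate"].astype(int)
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def treatment_codes(self) -> pd.Series:
        """Two-letter origin-host codes (FF, FS, SF, SS) per sample."""
        return (
            self.data["origin"].str[0].str.upper()
            + self.data["host"].str[0].str.upper()
        )

    def __repr__(self) -> str:
        return f"SampleMetadata({len(self.data)} samples)"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv") -> TaxonCountTable:
    """Read a taxa x samples count table from TSV.

    The header row holds sample IDs; the first column holds taxon IDs.
    ``biom_tsv`` additionally tolerates the classic ``# Constructed from
    biom file`` banner and an ``#OTU ID`` first header field.
    """
    if format not in ("tsv", "biom_tsv"):
        raise ValueError(f"unknown count-table format {format!r}")
    path = Path(path)
    if format == "biom_tsv":
        # BIOM TSV export: optional '# Constructed from biom file' banner,
        # then a header line beginning '#OTU ID'
        lines = path.read_text().splitlines()
        start = 0
        while start < len(lines) - 1 and lines[start + 1].startswith("#"):
            start += 1
        lines[start] = lines[start].lstrip("#").lstrip()
        from io import StringIO
        source = StringIO("\n".join(lines[start:]))
    else:
        source = path
    try:
        df = pd.read_csv(source, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # locate malformed numeric cells before handing to the validator
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"malformed numeric cell at taxon {df.index[r]!r}, sample "
            f"{df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    table = TaxonCountTable(numeric)
    log_stage("read_count_table", path=path, taxa=len(table.taxon_ids),
              samples=len(table.sample_ids))
    return table


def write_count_table(table: TaxonCountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t")


def read_tree(path: str | Path, missing_length: str = "error") -> TreeNode:
    """Read a rooted Newick tree and validate its branch lengths.

    Parameters
    ----------
    missing_length : {'error', 'zero'}
        Policy for branches without a length. The default refuses them:
        silently defaulted lengths corrupt PD. ``zero`` assigns 0.
    """
    if missing_length not in ("error", "zero"):
        raise ValueError(f"unknown missing-length policy {missing_length!r}")
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValueError(f"cannot parse Newick from {path}: {exc}") from exc
    return _validate_tree(tree, missing_length)


def parse_tree(newick: str, missing_length: str = "error") -> TreeNode:
    """Parse a Newick string (same validation as :func:`read_tree`)."""
    if missing_length not in ("error", "zero"):
        raise ValueError(f"unknown missing-length policy {missing_length!r}")
    tree = TreeNode.read([newick], format="newick")
    return _validate_tree(tree, missing_length)


def _validate_tree(tree: TreeNode, missing_length: str) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        seen, dup = set(), set()
        for n in names:
            (dup if n in seen else seen).add(n)
        raise ValueError(f"duplicate tip label(s): {sorted(dup)}")
    if tree.length is None:
        tree.length = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_length == "error":
                label = node.name or "<internal>"
                raise ValueError(f"branch without length at node {label!r}")
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise ValueError(f"invalid branch length {node.length!r}")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy TSV: taxon_id, lineage (ranked, semicolon-delimited)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.index = df.index.astype(str)
    if "lineage" not in df.columns:
        raise ValueError("taxonomy table needs a 'lineage' column")
    return df


def read_function_table(path: str | Path) -> pd.DataFrame:
    """Functional-activity TSV: samples as rows, numeric variables as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# alignment and metadata summaries
# ---------------------------------------------------------------------------

def align_inputs(
    table: TaxonCountTable,
    tree: TreeNode,
    meta: SampleMetadata | None = None,
    missing_taxa: str = "drop",
) -> tuple[TaxonCountTable, TreeNode]:
    """Prune the tree to the table's taxa and reconcile the taxon sets.

    Taxa in the table but absent from the tree are dropped with a warning
    (or raise, with ``missing_taxa='error'``). Samples without metadata are
    an error. An empty taxon intersection is fatal. Idempotent.
    """
    if missing_taxa not in ("drop", "error"):
        raise ValueError(f"unknown missing-taxa policy {missing_taxa!r}")
    if meta is not None:
        absent = sorted(set(table.sample_ids) - set(meta.sample_ids))
        if absent:
            raise ValueError(f"samples without metadata: {absent}")
    tip_names = {t.name for t in tree.tips()}
    table_taxa = set(table.taxon_ids)
    shared = table_taxa & tip_names
    if not shared:
        raise ValueError("no taxa shared between count table and tree")
    missing = sorted(table_taxa - tip_names)
    if missing:
        if missing_taxa == "error":
            raise ValueError(f"taxa absent from tree: {missing}")
        logger.warning("dropping %d taxa absent from tree: %s",
                       len(missing), missing[:10])
        keep = [t for t in table.taxon_ids if t in shared]
        table = TaxonCountTable(table.data.loc[keep])
    if tip_names != shared:
        tree = tree.shear(shared)
        tree.prune()
        if tree.length is None:
            tree.length = 0.0
    log_stage("align_inputs", taxa=len(table.taxon_ids),
              tips=len(shared), dropped=len(missing))
    return table, tree


def summarize_env_by_factor(
    meta: SampleMetadata | pd.DataFrame,
    variable: str,
    factor: str = "host",
) -> pd.Series:
    """Arithmetic mean of a numeric metadata variable per factor level.

    Works on raw per-sample metadata or on a table of per-treatment means:
    with a balanced design both give the mean of treatment means per level
    of ``origin`` or ``host``.
    """
    df = meta.data if isinstance(meta, SampleMetadata) else meta
    if factor not in df.columns:
        raise ValueError(f"unknown factor {factor!r}")
    if variable not in df.columns:
        raise ValueError(f"unknown variable {variable!r}")
    values = pd.to_numeric(df[variable], errors="coerce")
    if values.isna().any():
        raise ValueError(f"variable {variable!r} is not numeric")
    return values.groupby(df[factor]).mean()
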