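"""Shared data model and readers for the pipeline's standard formats.

The central objects are a taxa x samples integer count table (ASV table), a
rooted branch-length-bearing phylogeny over the taxon ids, and a per-sample
metadata table carrying the study design (farm, niche, health status) plus
farm-level coordinates and soil chemistry.  ``harmonize`` cross-validates the
three against each other before any analysis runs.

Internal orientation is always taxa rows x sample columns.  Ids are
case-sensitive and whitespace-trimmed at field edges only.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger("ecoassembly")

NICHES = ("bulk_soil", "rhizosphere_soil", "root", "shoot")
HEALTH_STATES = ("healthy", "unhealthy")
CHEMISTRY_VARS = ("pH", "P2O5", "Mg", "K2O", "organic_carbon")
METADATA_REQUIRED = (
    "sample_id",
    "farm_id",
    "niche",
    "health",
    "latitude",
    "longitude",
) + CHEMISTRY_VARS

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Malformed input file (bad cell, duplicate id, unparseable tree ...)."""


class VocabularyError(ValueError):
    """Metadata value outside its closed vocabulary or numeric range."""


class MismatchError(ValueError):
    """Table / tree / metadata id sets do not line up under the strict policy."""


def _check_ids(ids: list[str], kind: str) -> None:
    if any(not i for i in ids):
        raise FormatError(f"empty {kind} id")
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer read counts."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t).strip() for t in self.taxon_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        _check_ids(self.taxon_ids, "taxon")
        _check_ids(self.sample_ids, "sample")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if self.counts.dtype.kind == "f":
            if not np.all(np.isfinite(self.counts)) or np.any(self.counts % 1 != 0):
                bad = np.argwhere(~np.isfinite(self.counts) | (self.counts % 1 != 0))[0]
                raise FormatError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
        self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids: list[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(list(taxon_ids), list(self.sample_ids), self.counts[idx, :])


@dataclass
class RelativeAbundanceTable:
    """Taxa x samples proportions; columns of all-zero source samples stay zero."""

    taxon_ids: list[str]
    sample_ids: list[str]
    proportions: np.ndarray
    zero_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < -1e-12) or np.any(self.proportions > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")
        totals = self.proportions.sum(axis=0)
        nonzero = [s for s in self.sample_ids if s not in set(self.zero_samples)]
        idx = [self.sample_ids.index(s) for s in nonzero]
        if idx and not np.allclose(totals[idx], 1.0, atol=1e-9):
            raise ValueError("non-degenerate columns must sum to 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.taxon_ids, columns=self.sample_ids
        )


@dataclass
class Phylogeny:
    """Rooted tree with non-negative branch lengths over taxon ids.

    Thin wrapper around ``skbio.TreeNode`` exposing what downstream modules
    need: the leaf set, patristic distances and pruning.
    """

    tree: TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names()
        _check_ids(names, "leaf")
        n_missing = 0
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise FormatError(f"negative branch length at {node.name!r}")
        if n_missing:
            logger.warning("%d branches had no length; set to 0", n_missing)

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.tips())

    def patristic_matrix(self) -> DistanceMatrix:
        """Pairwise path-length distances between all leaves."""
        return self.tree.tip_tip_distances()

    def prune_to(self, taxa: list[str]) -> "Phylogeny":
        keep = set(taxa)
        missing = keep - set(self.leaf_names())
        if missing:
            raise MismatchError(f"taxa not in tree: {sorted(missing)[:10]}")
        return Phylogeny(self.tree.shear(keep))

    def write(self, path: str) -> None:
        self.tree.write(path)


@dataclass
class SampleMetadata:
    """Per-sample design variables plus (possibly farm-level) chemistry.

    Backed by a DataFrame indexed by sample id; extra columns are preserved
    untouched.  Missing chemistry / coordinate values are allowed and stay
    NaN — downstream correlation and regression operations drop them pairwise.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str).str.strip()
        _check_ids(list(df["sample_id"]), "sample")
        bad_niche = sorted(set(df["niche"]) - set(NICHES))
        if bad_niche:
            raise VocabularyError(
                f"unknown niche value(s) {bad_niche}; allowed: {list(NICHES)}"
            )
        bad_health = sorted(set(df["health"]) - set(HEALTH_STATES))
        if bad_health:
            raise VocabularyError(
                f"unknown health value(s) {bad_health}; allowed: {list(HEALTH_STATES)}"
            )
        for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
            vals = pd.to_numeric(df[col], errors="coerce")
            present = vals.notna()
            if ((vals < lo) | (vals > hi))[present].any():
                off = df.loc[present & ((vals < lo) | (vals > hi)), "sample_id"]
                raise VocabularyError(
                    f"{col} out of [{lo}, {hi}] for sample(s) {list(off)[:5]}"
                )
            df[col] = vals
        for col in CHEMISTRY_VARS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        self.frame = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def select(self, sample_ids: list[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[sample_ids].reset_index(drop=True))

    def group_labels(self, cols: tuple[str, ...] = ("niche", "health")) -> pd.Series:
        return self.frame[list(cols)].agg("/".join, axis=1)

    def farm_table(self) -> pd.DataFrame:
        """One row per farm with its coordinates and chemistry (first sample wins)."""
        cols = ["farm_id", "latitude", "longitude", *CHEMISTRY_VARS]
        return self.frame[cols].groupby("farm_id").first()


Taxonomy = dict[str, list[str]]


# ---------------------------------------------------------------------------
# readers / writers


def _read_table_text(path: str) -> pd.DataFrame:
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        # QIIME2 flat tables label the header line itself "#OTU ID"
        if lines[start].split("\t")[0].strip().lower() in ("#otu id", "#asv id"):
            lines[start] = lines[start].lstrip("#")
            break
        start += 1
    if start == len(lines):
        raise FormatError(f"{path}: no header line found")
    return pd.read_csv(io.StringIO("".join(lines[start:])), sep="\t", dtype=str)


def read_count_table(path: str, orientation: str = "taxa_rows") -> CountTable:
    """Read a tab-separated count table; tolerates a leading ``#OTU ID`` header."""
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table_text(path)
    row_ids = [str(v).strip() for v in df.iloc[:, 0]]
    col_ids = [str(c).strip() for c in df.columns[1:]]
    data = df.iloc[:, 1:]
    mat = np.empty(data.shape, dtype=np.int64)
    for j, col in enumerate(data.columns):
        for i, raw in enumerate(data[col]):
            try:
                val = int(str(raw).strip())
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer cell {raw!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
            mat[i, j] = val
    if orientation == "samples_rows":
        mat = mat.T
        row_ids, col_ids = col_ids, row_ids
    return CountTable(row_ids, col_ids, mat)


def write_count_table(table: CountTable, path: str) -> None:
    df = table.to_dataframe()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def read_tree(path: str) -> Phylogeny:
    try:
        tree = TreeNode.read(path, format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"{path}: unparseable newick ({exc})") from exc
    return Phylogeny(tree)


def read_metadata(path: str) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str) -> Taxonomy:
    """TSV of taxon id + semicolon-delimited lineage -> rank lists (length <= 7)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Taxonomy = {}
    for tid, lineage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        ranks = [r.strip() or "unclassified" for r in str(lineage).split(";")][:7]
        out[str(tid).strip()] = ranks
    return out


def write_taxonomy(tax: Taxonomy, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tlineage\n")
        for tid in tax:
            fh.write(f"{tid}\t{';'.join(tax[tid])}\n")


# ---------------------------------------------------------------------------
# harmonization


def harmonize(
    table: CountTable,
    tree: Phylogeny | None,
    meta: SampleMetadata,
    policy: str = "intersect",
) -> tuple[CountTable, Phylogeny | None, SampleMetadata]:
    """Cross-restrict table, tree and metadata to their common id sets.

    Under ``intersect`` taxa are restricted to tree leaves, samples to
    metadata rows, the tree is pruned, and all-zero rows/columns are dropped
    (logged).  Under ``strict`` any mismatch raises a :class:`MismatchError`.
    Idempotent: applying it to already-harmonized inputs is a no-op.
    """
    if policy not in ("intersect", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    tree_leaves = set(tree.leaf_names()) if tree is not None else None
    meta_ids = set(meta.sample_ids)

    if policy == "strict":
        if tree_leaves is not None:
            off = set(table.taxon_ids) - tree_leaves
            if off:
                raise MismatchError(f"taxa absent from tree: {sorted(off)[:10]}")
        off = set(table.sample_ids) - meta_ids
        if off:
            raise MismatchError(f"samples absent from metadata: {sorted(off)[:10]}")

    keep_taxa = [
        t for t in table.taxon_ids if tree_leaves is None or t in tree_leaves
    ]
    keep_samples = [s for s in table.sample_ids if s in meta_ids]
    if not keep_taxa or not keep_samples:
        raise MismatchError("empty intersection of table with tree/metadata ids")

    out = table
    if keep_taxa != table.taxon_ids:
        out = out.select_taxa(keep_taxa)
    if keep_samples != out.sample_ids:
        out = out.select_samples(keep_samples)

    nz_taxa = [t for t, row in zip(out.taxon_ids, out.counts) if row.sum() > 0]
    nz_samples = [
        s for s, tot in zip(out.sample_ids, out.sample_totals()) if tot > 0
    ]
    n_dropped = (out.n_taxa - len(nz_taxa)) + (out.n_samples - len(nz_samples))
    if n_dropped:
        logger.info("harmonize: dropped %d all-zero rows/columns", n_dropped)
    if not nz_taxa or not nz_samples:
        raise MismatchError("harmonization left no non-empty taxa/samples")
    if nz_taxa != out.taxon_ids:
        out = out.select_taxa(nz_taxa)
    if nz_samples != out.sample_ids:
        out = out.select_samples(nz_samples)

    out_tree = tree
    if tree is not None and set(out.taxon_ids) != tree_leaves:
        out_tree = tree.prune_to(out.taxon_ids)
    out_meta = meta
    if out.sample_ids != meta.sample_ids:
        out_meta = meta.select(out.sample_ids)
    return out, out_tree, out_meta
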