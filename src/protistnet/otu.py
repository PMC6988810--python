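"""OTU count tables, sample metadata and the normalization steps applied to them.

The central object is :class:`OtuTable`, a validated non-negative integer
count matrix (OTUs as rows, samples as columns) with optional taxonomy
binding.  All downstream stages (diversity, CLAM classification, network
inference) consume tables produced by the transformations in this module:
replicate pooling, singleton removal, rarefying (random subsampling without
replacement to a common depth), minimum-abundance filtering, per-habitat
pooling, and the Hellinger transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = ("sample_id", "station", "habitat", "date", "replicate")


class OtuTableError(ValueError):
    """Raised when an OTU table or metadata file violates its contract."""


@dataclass
class OtuTable:
    """Non-negative integer OTU-by-sample count matrix.

    Parameters
    ----------
    counts
        DataFrame with OTU ids as index and sample ids as columns. Values
        must be non-negative integers.
    taxonomy
        Optional mapping ``otu_id -> lineage`` (semicolon-joined ranked
        lineage string); every key must be an OTU id present in ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        validate_counts(self.counts)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.counts.index)
            if unknown:
                raise OtuTableError(
                    f"taxonomy refers to {len(unknown)} OTU ids absent from the "
                    f"table (e.g. {sorted(unknown)[:3]})"
                )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def with_counts(self, counts: pd.DataFrame) -> "OtuTable":
        """New table with the same taxonomy binding restricted to ``counts``."""
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in counts.index if o in self.taxonomy}
        return OtuTable(counts=counts, taxonomy=tax)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")


def validate_counts(counts: pd.DataFrame) -> None:
    # Zero OTUs is legal (filters may drop everything); zero samples is not.
    if counts.shape[1] == 0:
        raise OtuTableError("OTU table has no sample columns")
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise OtuTableError(f"duplicated OTU id: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise OtuTableError(f"duplicated sample id: {dup!r}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        try:
            arr = arr.astype(float)
        except (TypeError, ValueError):
            raise OtuTableError("non-numeric cell in OTU table")
    if counts.size == 0:
        return
    if np.any(arr != np.floor(arr)):
        i, j = np.argwhere(arr != np.floor(arr))[0]
        raise OtuTableError(
            f"non-integer count at OTU {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}: {arr[i, j]}"
        )
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise OtuTableError(
            f"negative count at OTU {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}: {arr[i, j]}"
        )


def read_otu_table(path: str | Path, transpose: bool = False) -> OtuTable:
    """Read a TSV OTU table (first column ``otu_id``, remaining columns counts).

    ``transpose=True`` handles samples-as-rows files.
    """
    # pandas mangles duplicated header names (s1 -> s1.1); check them raw
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise OtuTableError(f"empty OTU table: {path}")
    if len(header) != len(set(header)):
        dup = next(h for h in header if header.count(h) > 1)
        raise OtuTableError(f"duplicated sample id in header: {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if transpose:
        df = df.T
    if df.shape[0] == 0:
        raise OtuTableError(f"empty OTU table: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            flt = arr.astype(float)
            if np.any(flt != np.floor(flt)):
                validate_counts(df)  # produce a precise error message
            df = df.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise OtuTableError(f"OTU table {path}: counts are not integers ({exc})")
    return OtuTable(counts=df)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, station, habitat, date, replicate."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(REQUIRED_METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise OtuTableError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise OtuTableError("duplicated sample_id in metadata")
    return meta


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``otu_id<TAB>lineage`` into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise OtuTableError("taxonomy file needs otu_id and lineage columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def check_metadata_binding(table: OtuTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate that every table sample has exactly one metadata record.

    Returns metadata restricted to the table's samples, in table order.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise OtuTableError(f"samples without metadata: {missing[:5]}")
    sub = meta.loc[table.sample_ids]
    habitats = sub["habitat"].unique()
    if len(habitats) > 2:
        raise OtuTableError(f"more than two habitats in metadata: {sorted(habitats)}")
    return sub.reset_index()


def pool_replicates(table: OtuTable, metadata: pd.DataFrame) -> tuple[OtuTable, pd.DataFrame]:
    """Sum replicate samples within each (station, date) group.

    Returns the pooled table (one column per station-date pair, named
    ``{station}_{date}``) and pooled metadata (replicate column dropped).
    """
    meta = check_metadata_binding(table, metadata)
    groups = meta.groupby(["station", "date"], sort=False)
    pooled_cols: dict[str, np.ndarray] = {}
    rows = []
    for (station, date), grp in groups:
        name = f"{station}_{date}"
        pooled_cols[name] = table.counts[grp["sample_id"]].sum(axis=1).to_numpy()
        rows.append(
            {"sample_id": name, "station": station, "habitat": grp["habitat"].iloc[0],
             "date": date, "replicate": "pooled"}
        )
    pooled = pd.DataFrame(pooled_cols, index=table.counts.index)
    logger.info("pool_replicates: %d samples -> %d pooled columns", len(meta), pooled.shape[1])
    return table.with_counts(pooled), pd.DataFrame(rows)


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across all samples is 1 (or 0).

    May return a table with zero OTU rows if every OTU was a singleton.
    """
    totals = table.counts.sum(axis=1)
    keep = totals >= 2
    dropped = int((~keep).sum())
    if dropped:
        logger.info("remove_singletons: dropped %d of %d OTUs", dropped, len(totals))
    return table.with_counts(table.counts.loc[keep])


def rarefy_vector(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample one count vector to ``depth`` reads without replacement."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise OtuTableError(f"rarefaction depth {depth} exceeds column total {total}")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy(
    table: OtuTable,
    depth: int,
    seed: int,
    drop_below_depth: bool = True,
    with_replacement: bool = False,
) -> OtuTable:
    """Rarefy every column to a common depth by random subsampling.

    Columns whose total is below ``depth`` are dropped with a warning
    (``drop_below_depth=True``, the default) or raise an error. Subsampling
    is a multivariate hypergeometric draw (without replacement); a
    with-replacement multinomial mode exists behind a flag.
    """
    if depth <= 0:
        raise OtuTableError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    below = [s for s in table.sample_ids if totals[s] < depth]
    if below:
        if not drop_below_depth:
            raise OtuTableError(
                f"samples below rarefaction depth {depth}: {below}"
            )
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s", len(below), depth, below
        )
    keep = [s for s in table.sample_ids if s not in set(below)]
    if not keep:
        raise OtuTableError("no samples at or above the rarefaction depth")
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy(dtype=np.int64)
        if with_replacement:
            p = col / col.sum()
            out[s] = rng.multinomial(depth, p)
        else:
            out[s] = rarefy_vector(col, depth, rng)
    rar = pd.DataFrame(out, index=table.counts.index)
    return table.with_counts(rar)


def resolve_depth(table: OtuTable, policy: str | int) -> int:
    """Resolve a rarefaction depth policy: ``lowest``, ``second-lowest`` or a fixed int."""
    if isinstance(policy, int):
        return policy
    totals = sorted(int(t) for t in table.counts.sum(axis=0))
    if policy == "lowest":
        return totals[0]
    if policy == "second-lowest":
        if len(totals) < 2:
            raise OtuTableError("second-lowest depth policy needs >= 2 samples")
        return totals[1]
    try:
        return int(policy)
    except (TypeError, ValueError):
        raise OtuTableError(f"unknown depth policy: {policy!r}")


def filter_min_total(table: OtuTable, min_reads: int) -> OtuTable:
    """Keep OTUs with total abundance >= ``min_reads`` ("less than" excluded)."""
    totals = table.counts.sum(axis=1)
    keep = totals >= min_reads
    logger.info(
        "filter_min_total(%d): %d -> %d OTUs", min_reads, len(totals), int(keep.sum())
    )
    return table.with_counts(table.counts.loc[keep])


def pool_by_habitat(
    table: OtuTable,
    metadata: pd.DataFrame,
    stations: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pool counts per habitat (optionally over a station subset) and equalize depths.

    Each habitat's selected samples are summed into one count vector; the
    larger pool is then rarefied down to the smaller pool's total so the two
    habitats are directly comparable (the CLAM test's input). Returns a
    DataFrame indexed by OTU id with one column per habitat.
    """
    meta = check_metadata_binding(table, metadata)
    if stations is not None:
        meta = meta[meta["station"].isin(stations)]
    habitats = sorted(meta["habitat"].unique())
    if len(habitats) != 2:
        raise OtuTableError(
            f"pool_by_habitat needs exactly two habitats with samples, got {habitats}"
        )
    pools = {}
    for hab in habitats:
        samples = meta.loc[meta["habitat"] == hab, "sample_id"].tolist()
        if not samples:
            raise OtuTableError(f"habitat {hab!r} has no selected samples")
        pools[hab] = table.counts[samples].sum(axis=1).to_numpy(dtype=np.int64)
    target = min(int(v.sum()) for v in pools.values())
    rng = np.random.default_rng(seed)
    for hab in habitats:
        if pools[hab].sum() > target:
            pools[hab] = rarefy_vector(pools[hab], target, rng)
    return pd.DataFrame(pools, index=table.counts.index)


def hellinger_transform(table: OtuTable) -> pd.DataFrame:
    """sqrt of per-sample relative abundance; each column has unit squared norm."""
    arr = table.counts.to_numpy(dtype=float)
    colsum = arr.sum(axis=0)
    if np.any(colsum == 0):
        bad = table.sample_ids[int(np.argmax(colsum == 0))]
        raise OtuTableError(f"all-zero sample column: {bad!r}")
    return pd.DataFrame(
        np.sqrt(arr / colsum), index=table.counts.index, columns=table.counts.columns
    )
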