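"""Alpha diversity, analytic rarefaction curves, Bray-Curtis dissimilarity
and the shared/exclusive two-habitat partition of OTUs and reads."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import entropy

from .otu import OtuTable, OtuTableError, check_metadata_binding


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) over positive counts."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise OtuTableError("Shannon index of an all-zero vector is undefined")
    if np.any(c < 0):
        raise OtuTableError("negative count in Shannon input")
    return float(entropy(c[c > 0]))


def richness(counts) -> int:
    """Observed OTU richness (number of positive counts)."""
    return int(np.count_nonzero(np.asarray(counts)))


def diversity_summary(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed richness and Shannon H (nats)."""
    rows = []
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        rows.append({"sample_id": s, "richness": richness(col), "shannon_H": shannon(col)})
    return pd.DataFrame(rows).set_index("sample_id")


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected OTU richness at each subsampling depth (exact hypergeometric).

    E[S(d)] = sum_i [1 - C(N-N_i, d) / C(N, d)]: the expected number of OTUs
    with at least one read in a uniform without-replacement subsample of size
    d from the N total reads. Computed with log-gamma for numerical range.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    n_total = int(c.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if np.any(depths < 1) or np.any(depths > n_total):
        raise OtuTableError(
            f"rarefaction depths must be in [1, {n_total}], got range "
            f"[{depths.min()}, {depths.max()}]"
        )

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.empty(len(depths), dtype=float)
    for j, d in enumerate(depths):
        rest = n_total - c  # reads not belonging to OTU i
        with np.errstate(invalid="ignore"):
            log_p_absent = log_comb(rest, d) - log_comb(n_total, d)
        p_absent = np.where(rest >= d, np.exp(log_p_absent), 0.0)
        out[j] = float(np.sum(1.0 - p_absent))
    return out


def bray_curtis(table: OtuTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (symmetric, in [0,1])."""
    arr = table.counts.to_numpy(dtype=float).T  # samples x OTUs
    if np.any(arr.sum(axis=1) == 0):
        raise OtuTableError("Bray-Curtis undefined for an all-zero sample")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class VennPartition:
    """Shared/exclusive OTU counts and read fractions between two habitats."""

    habitat_a: str
    habitat_b: str
    shared_otus: int
    exclusive_a_otus: int
    exclusive_b_otus: int
    absent_otus: int
    shared_read_fraction: float
    exclusive_a_read_fraction: float
    exclusive_b_read_fraction: float

    def to_dict(self) -> dict:
        return {
            "habitat_a": self.habitat_a,
            "habitat_b": self.habitat_b,
            "shared_otus": self.shared_otus,
            "exclusive_a_otus": self.exclusive_a_otus,
            "exclusive_b_otus": self.exclusive_b_otus,
            "absent_otus": self.absent_otus,
            "shared_read_fraction": self.shared_read_fraction,
            "exclusive_a_read_fraction": self.exclusive_a_read_fraction,
            "exclusive_b_read_fraction": self.exclusive_b_read_fraction,
        }


def venn_partition(table: OtuTable, metadata: pd.DataFrame) -> VennPartition:
    """Partition OTUs (and their reads) into shared and habitat-exclusive sets.

    An OTU is shared iff it has a positive total in both habitats; read
    fractions are computed over the whole table's reads.
    """
    meta = check_metadata_binding(table, metadata)
    habitats = sorted(meta["habitat"].unique())
    if len(habitats) != 2:
        raise OtuTableError(f"venn_partition needs two habitats, got {habitats}")
    hab_a, hab_b = habitats
    tot = {}
    for hab in habitats:
        samples = meta.loc[meta["habitat"] == hab, "sample_id"].tolist()
        tot[hab] = table.counts[samples].sum(axis=1)
    in_a = tot[hab_a] > 0
    in_b = tot[hab_b] > 0
    grand = float(table.counts.to_numpy().sum())
    if grand == 0:
        raise OtuTableError("venn_partition on an all-zero table")
    reads = table.counts.sum(axis=1)
    return VennPartition(
        habitat_a=hab_a,
        habitat_b=hab_b,
        shared_otus=int((in_a & in_b).sum()),
        exclusive_a_otus=int((in_a & ~in_b).sum()),
        exclusive_b_otus=int((~in_a & in_b).sum()),
        absent_otus=int((~in_a & ~in_b).sum()),
        shared_read_fraction=float(reads[in_a & in_b].sum() / grand),
        exclusive_a_read_fraction=float(reads[in_a & ~in_b].sum() / grand),
        exclusive_b_read_fraction=float(reads[~in_a & in_b].sum() / grand),
    )
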