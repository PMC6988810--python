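"""CLAM habitat generalist/specialist classification from two-habitat counts.

Each OTU's pooled, depth-equalized counts ``(a, b)`` in habitats A and B are
treated as a draw from ``Bin(a + b, pi)`` after conditioning on the total,
where ``pi = p_A / (p_A + p_B)`` is the OTU's preference for habitat A. A
two-sided exact (Clopper-Pearson) confidence interval for ``pi`` at level
``1 - 2*alpha`` is compared with the supermajority threshold ``K``:

* specialist for A if the interval lies entirely above ``K``;
* specialist for B if it lies entirely below ``1 - K``;
* generalist if it lies entirely within ``[1 - K, K]``;
* otherwise the OTU is *too rare to classify* with confidence.

With the defaults ``K = 2/3`` and ``alpha = 0.005`` a specialist call
requires roughly two-thirds supermajority support at high confidence, which
keeps the procedure conservative on rare OTUs without excluding them a
priori. A normal-approximation mode on the Poisson-ratio scale is provided
as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GENERALIST = "generalist"
SPECIALIST_A = "specialist_A"
SPECIALIST_B = "specialist_B"
TOO_RARE = "too_rare"
CLASSES = (GENERALIST, SPECIALIST_A, SPECIALIST_B, TOO_RARE)


@dataclass(frozen=True)
class ClamParams:
    """Tuning parameters of the CLAM classification.

    K : specialization threshold in (0.5, 1); an A-specialist's true share of
        the two-habitat total exceeds K. Default 2/3 (supermajority rule).
    alpha : per-side significance level of the interval, default 0.005.
    ci_method : 'exact_binomial' (Clopper-Pearson, default) or
        'poisson_normal' (normal approximation on the log-ratio scale).
    """

    K: float = 2.0 / 3.0
    alpha: float = 0.005
    ci_method: str = "exact_binomial"

    def __post_init__(self) -> None:
        if not 0.5 < self.K < 1.0:
            raise ValueError(f"K must be in (0.5, 1), got {self.K}")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.ci_method not in ("exact_binomial", "poisson_normal"):
            raise ValueError(f"unknown ci_method: {self.ci_method!r}")


def proportion_ci(a: np.ndarray, n: np.ndarray, alpha: float, method: str):
    """Two-sided (1 - 2*alpha) confidence bounds on a binomial proportion.

    Vectorized over OTUs. For ``exact_binomial`` the Clopper-Pearson bounds
    are the usual beta quantiles, with lower = 0 at a = 0 and upper = 1 at
    a = n. Entries with n = 0 get the vacuous interval [0, 1].
    """
    a = np.asarray(a, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lo = np.zeros(len(a))
    hi = np.ones(len(a))
    pos = n > 0
    if method == "exact_binomial":
        with np.errstate(all="ignore"):
            l_ = stats.beta.ppf(alpha, a, n - a + 1)
            h_ = stats.beta.ppf(1 - alpha, a + 1, n - a)
        lo[pos] = np.where(a[pos] > 0, l_[pos], 0.0)
        hi[pos] = np.where(a[pos] < n[pos], h_[pos], 1.0)
    elif method == "poisson_normal":
        # Normal interval for log(lambda_A/lambda_B) with a 0.5 continuity
        # correction, mapped back to the proportion scale.
        z = stats.norm.ppf(1 - alpha)
        ac = a[pos] + 0.5
        bc = n[pos] - a[pos] + 0.5
        log_ratio = np.log(ac / bc)
        se = np.sqrt(1.0 / ac + 1.0 / bc)
        lo_r = np.exp(log_ratio - z * se)
        hi_r = np.exp(log_ratio + z * se)
        lo[pos] = lo_r / (1.0 + lo_r)
        hi[pos] = hi_r / (1.0 + hi_r)
    else:  # pragma: no cover
        raise ValueError(method)
    return lo, hi


class ClamTest:
    """CLAM classification model for aligned two-habitat count vectors.

    Parameters
    ----------
    counts_a, counts_b
        Per-OTU pooled counts in habitats A and B, aligned on ``otu_ids``.
        The habitat pools are expected to be depth-equalized upstream
        (see :func:`protistnet.otu.pool_by_habitat`).
    otu_ids
        Optional OTU identifiers; defaults to positional ids.
    params
        :class:`ClamParams`.
    """

    def __init__(self, counts_a, counts_b, otu_ids=None, params: ClamParams | None = None):
        a = np.asarray(counts_a, dtype=np.int64)
        b = np.asarray(counts_b, dtype=np.int64)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError(
                f"count vectors must be 1-D and aligned, got {a.shape} vs {b.shape}"
            )
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("negative habitat counts")
        if otu_ids is None:
            otu_ids = [f"OTU{i}" for i in range(len(a))]
        if len(otu_ids) != len(a):
            raise ValueError("otu_ids misaligned with count vectors")
        self.counts_a = a
        self.counts_b = b
        self.otu_ids = list(otu_ids)
        self.params = params or ClamParams()

    @classmethod
    def from_pools(cls, pools: pd.DataFrame, params: ClamParams | None = None) -> "ClamTest":
        """Build from the two-column output of ``pool_by_habitat`` (A = first column)."""
        if pools.shape[1] != 2:
            raise ValueError("expected a two-column habitat pool frame")
        return cls(
            pools.iloc[:, 0].to_numpy(),
            pools.iloc[:, 1].to_numpy(),
            otu_ids=list(pools.index),
            params=params,
        )

    def fit(self) -> "ClamResults":
        p = self.params
        n = self.counts_a + self.counts_b
        lo, hi = proportion_ci(self.counts_a, n, p.alpha, p.ci_method)
        classes = np.full(len(n), TOO_RARE, dtype=object)
        # Ties at a threshold resolve toward the less specific class:
        # specialist requires a strict inequality, generalist allows equality.
        spec_a = lo > p.K
        spec_b = hi < 1.0 - p.K
        general = (lo >= 1.0 - p.K) & (hi <= p.K)
        classes[general] = GENERALIST
        classes[spec_a] = SPECIALIST_A
        classes[spec_b] = SPECIALIST_B
        classes[n == 0] = TOO_RARE
        with np.errstate(invalid="ignore"):
            pi_hat = np.where(n > 0, self.counts_a / np.maximum(n, 1), np.nan)
        frame = pd.DataFrame(
            {
                "count_A": self.counts_a,
                "count_B": self.counts_b,
                "pi_hat": pi_hat,
                "ci_low": lo,
                "ci_high": hi,
                "clam_class": classes,
            },
            index=pd.Index(self.otu_ids, name="otu_id"),
        )
        return ClamResults(model=self, frame=frame)


@dataclass
class ClamResults:
    """Per-OTU CLAM classes with the counts and confidence bounds behind them."""

    model: ClamTest
    frame: pd.DataFrame = field(repr=False)

    @property
    def classes(self) -> pd.Series:
        return self.frame["clam_class"]

    def class_counts(self) -> dict[str, int]:
        vc = self.frame["clam_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}

    def read_fractions(self) -> dict[str, float]:
        """Fraction of pooled reads carried by each class."""
        total = float((self.frame["count_A"] + self.frame["count_B"]).sum())
        out = {}
        for c in CLASSES:
            sub = self.frame[self.frame["clam_class"] == c]
            out[c] = float((sub["count_A"] + sub["count_B"]).sum() / total) if total else 0.0
        return out

    def summary(self) -> str:
        p = self.model.params
        counts = self.class_counts()
        fracs = self.read_fractions()
        lines = [
            "CLAM habitat classification",
            "===========================",
            f"OTUs: {len(self.frame)}   K = {p.K:.4f}   alpha = {p.alpha}   "
            f"CI = {p.ci_method}",
            f"{'class':<14}{'OTUs':>8}{'read fraction':>16}",
        ]
        for c in CLASSES:
            lines.append(f"{c:<14}{counts[c]:>8}{fracs[c]:>16.4f}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def clam_classify(counts_a, counts_b, params: ClamParams | None = None,
                  otu_ids=None) -> ClamResults:
    """Functional wrapper: classify aligned two-habitat counts in one call."""
    return ClamTest(counts_a, counts_b, otu_ids=otu_ids, params=params).fit()


def clam_min_abundance(params: ClamParams | None = None, max_scan: int = 100000) -> int:
    """Smallest total count t such that (t, 0) is called a specialist.

    This is the minimum evidence an OTU needs to escape the too-rare class;
    found by scanning t upward with the classifier itself.
    """
    params = params or ClamParams()
    for t in range(1, max_scan + 1):
        res = clam_classify([t], [0], params=params)
        if res.classes.iloc[0] == SPECIALIST_A:
            return t
    raise RuntimeError(f"no specialist call up to t = {max_scan}")
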