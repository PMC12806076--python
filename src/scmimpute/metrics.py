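"""External clustering agreement metrics from contingency-table definitions.

Implements the adjusted Rand index (Hubert-Arabie), normalized and adjusted
mutual information, and the Fowlkes-Mallows index natively from their
pair-counting / information-theoretic definitions, so each can be verified
against brute-force enumeration.  Natural logarithms are used throughout
(the metrics are ratio-normalized, so the base cancels) with the standard
0*log(0) = 0 convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import Partition, ValidationError

__all__ = [
    "ContingencyTable", "MetricReport",
    "contingency", "adjusted_rand_index", "normalized_mutual_information",
    "adjusted_mutual_information", "fowlkes_mallows_index",
    "expected_mutual_information", "evaluate",
]

logger = logging.getLogger(__name__)

AVERAGE_METHODS = ("arithmetic", "geometric", "min", "max")


@dataclass(frozen=True)
class ContingencyTable:
    """Joint label counts of two partitions of the same n items.

    ``counts[u, v]`` is the number of items with label u in the first
    partition and v in the second; ``row_sums`` and ``col_sums`` are the
    cluster sizes of the two partitions.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or (c < 0).any():
            raise ValidationError("contingency counts must be a non-negative 2-D array")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class MetricReport:
    """The four agreement metrics of one predicted-vs-truth comparison."""

    ari: float
    ami: float
    nmi: float
    fmi: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ari": self.ari, "ami": self.ami, "nmi": self.nmi, "fmi": self.fmi,
            **{k: v for k, v in self.metadata.items()},
        }


def contingency(u: Partition, v: Partition) -> ContingencyTable:
    """Build the joint count table of two partitions, aligning cells by id."""
    su, sv = set(u.cell_ids), set(v.cell_ids)
    if su != sv:
        diff = sorted(su.symmetric_difference(sv))
        raise ValidationError(f"partitions cover different cells; symmetric difference: {diff}")
    v_lab_by_id = dict(zip(v.cell_ids, v.labels))
    v_aligned = [v_lab_by_id[cid] for cid in u.cell_ids]
    ucodes = u.label_array()
    vmap: dict = {}
    vcodes = np.array([vmap.setdefault(lab, len(vmap)) for lab in v_aligned], dtype=np.int64)
    ku = int(ucodes.max()) + 1 if len(ucodes) else 0
    kv = int(vcodes.max()) + 1 if len(vcodes) else 0
    counts = np.zeros((ku, kv), dtype=np.int64)
    np.add.at(counts, (ucodes, vcodes), 1)
    return ContingencyTable(counts)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1.0) / 2.0


def adjusted_rand_index(t: ContingencyTable) -> float:
    """Hubert-Arabie chance-adjusted Rand index.

    (sum C(n_uv,2) - E) / (0.5*[sum C(a_u,2) + sum C(b_v,2)] - E) with
    E = sum C(a_u,2) * sum C(b_v,2) / C(n,2); 1 for identical partitions,
    expectation ~0 under independent labelings.
    """
    n = t.n
    if n < 2:
        raise ValidationError("ARI needs at least 2 items")
    sum_pairs = _comb2(t.counts).sum()
    a_pairs = _comb2(t.row_sums).sum()
    b_pairs = _comb2(t.col_sums).sum()
    expected = a_pairs * b_pairs / _comb2(n)
    denom = 0.5 * (a_pairs + b_pairs) - expected
    if denom == 0.0:
        # both all-singletons or both one cluster: partitions are identical
        return 1.0
    return min(1.0, float((sum_pairs - expected) / denom))


def _entropy(sizes: np.ndarray, n: int) -> float:
    p = sizes[sizes > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(t: ContingencyTable) -> float:
    n = t.n
    nz = t.counts > 0
    nij = t.counts[nz].astype(float)
    outer = np.outer(t.row_sums, t.col_sums)[nz].astype(float)
    return float((nij / n * (np.log(nij * n) - np.log(outer))).sum())


def _generalized_average(hu: float, hv: float, method: str) -> float:
    if method == "arithmetic":
        return 0.5 * (hu + hv)
    if method == "geometric":
        return float(np.sqrt(hu * hv))
    if method == "min":
        return min(hu, hv)
    if method == "max":
        return max(hu, hv)
    raise ValidationError(f"unknown average method {method!r}; valid: {list(AVERAGE_METHODS)}")


def normalized_mutual_information(
    t: ContingencyTable, average_method: str = "arithmetic"
) -> float:
    """NMI = I(U;V) / mean(H(U), H(V)); in [0, 1], 1 iff identical up to renaming."""
    n = t.n
    if n < 1:
        raise ValidationError("NMI needs at least 1 item")
    hu = _entropy(t.row_sums, n)
    hv = _entropy(t.col_sums, n)
    if hu == 0.0 and hv == 0.0:
        return 1.0  # both trivial single-cluster partitions, hence identical
    norm = _generalized_average(hu, hv, average_method)
    if norm == 0.0:
        return 0.0
    return min(1.0, float(_mutual_information(t) / norm))


def expected_mutual_information(t: ContingencyTable) -> float:
    """Exact expected MI under the hypergeometric (fixed-marginals) null model.

    Sums, for every (u, v) cell and every feasible joint count nij, the MI
    contribution weighted by the hypergeometric probability of nij given
    the marginals.
    """
    n = t.n
    a = t.row_sums.astype(np.int64)
    b = t.col_sums.astype(np.int64)
    lg = gammaln(np.arange(n + 2) + 1.0)  # log(k!) lookup
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term = nij / n * (np.log(nij) + np.log(n) - np.log(ai) - np.log(bj))
            logp = (
                lg[ai] + lg[bj] + lg[n - ai] + lg[n - bj]
                - lg[n] - lg[nij] - lg[ai - nij] - lg[bj - nij] - lg[n - ai - bj + nij]
            )
            emi += float((term * np.exp(logp)).sum())
    return emi


def adjusted_mutual_information(
    t: ContingencyTable, average_method: str = "arithmetic"
) -> float:
    """AMI = (I - E[I]) / (mean(H(U), H(V)) - E[I]); ~0 under independent labelings."""
    n = t.n
    if n < 2:
        raise ValidationError("AMI needs at least 2 items")
    hu = _entropy(t.row_sums, n)
    hv = _entropy(t.col_sums, n)
    if hu == 0.0 and hv == 0.0:
        logger.info("both partitions single-cluster; AMI defined as 1.0")
        return 1.0
    mi = _mutual_information(t)
    emi = expected_mutual_information(t)
    norm = _generalized_average(hu, hv, average_method)
    denom = norm - emi
    if denom == 0.0:
        return 1.0 if mi == emi else 0.0
    return min(1.0, float((mi - emi) / denom))


def fowlkes_mallows_index(t: ContingencyTable) -> float:
    """FMI = TP / sqrt((TP+FP)(TP+FN)) over co-clustered cell pairs."""
    tp = _comb2(t.counts).sum()
    tp_fp = _comb2(t.row_sums).sum()
    tp_fn = _comb2(t.col_sums).sum()
    if tp_fp == 0.0 or tp_fn == 0.0:
        logger.info("a partition has no co-clustered pair; FMI defined as 0.0")
        return 0.0
    return min(1.0, float(tp / np.sqrt(tp_fp * tp_fn)))


def evaluate(
    u: Partition, v: Partition,
    average_method: str = "arithmetic",
    metadata: dict | None = None,
) -> MetricReport:
    """All four metrics from one shared contingency table; symmetric in (u, v)."""
    t = contingency(u, v)
    return MetricReport(
        ari=adjusted_rand_index(t),
        ami=adjusted_mutual_information(t, average_method),
        nmi=normalized_mutual_information(t, average_method),
        fmi=fowlkes_mallows_index(t),
        metadata=dict(metadata or {}),
    )
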