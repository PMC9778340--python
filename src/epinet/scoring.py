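"""Mutual-information scoring of SNP sets against the phenotype.

A k-order SNP set X' is scored by the plug-in (maximum-likelihood) mutual
information MI(X'; Y) = H(X') + H(Y) - H(X', Y), in bits, computed from the
joint contingency table over the 3^k genotype combinations and the two
phenotype classes.  Orders 2 and 3 are scored exhaustively; the whole point
of the downstream network stage is to avoid exhaustive scoring at k >= 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeDataset

__all__ = [
    "InteractionScore",
    "RankedInteractionList",
    "entropy",
    "mi_score",
    "enumerate_interactions",
]


class InteractionScore(NamedTuple):
    """One scored SNP set: sorted index tuple, its order k and MI in bits."""

    snps: tuple[int, ...]
    order: int
    mi: float


@dataclass
class RankedInteractionList:
    """Interactions of one order, sorted by MI descending.

    Ties are broken by lexicographic SNP-index tuple, so the ordering is a
    deterministic function of the data.  Backed by arrays; item access
    returns :class:`InteractionScore`.
    """

    snps: np.ndarray  # (m, k) int32, each row strictly increasing
    mi: np.ndarray  # (m,) float64, non-increasing
    order: int

    def __len__(self) -> int:
        return int(self.mi.shape[0])

    def __getitem__(self, item):
        if isinstance(item, slice):
            return RankedInteractionList(
                snps=self.snps[item], mi=self.mi[item], order=self.order
            )
        i = int(item)
        return InteractionScore(
            snps=tuple(int(s) for s in self.snps[i]),
            order=self.order,
            mi=float(self.mi[i]),
        )

    def __iter__(self) -> Iterator[InteractionScore]:
        for i in range(len(self)):
            yield self[i]

    def head(self, m: int) -> "RankedInteractionList":
        return self[: max(0, int(m))]

    def index_tuples(self) -> list[tuple[int, ...]]:
        return [tuple(int(s) for s in row) for row in self.snps]

    def to_frame(self, snp_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Tabular export: one row per interaction (ids, order, MI)."""
        if snp_ids is None:
            labels = [",".join(str(int(s)) for s in row) for row in self.snps]
        else:
            labels = [",".join(snp_ids[int(s)] for s in row) for row in self.snps]
        return pd.DataFrame({"snps": labels, "order": self.order, "mi": self.mi})


def entropy(counts) -> float:
    """Shannon entropy (bits) of a count vector; 0 log 0 := 0.

    Raises if counts are negative or sum to zero.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() <= 0:
        raise ValueError("counts must not all be zero")
    return float(stats.entropy(c, base=2))


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """Plug-in MI (bits) for a stack of joint tables of shape (..., G, 2).

    MI = (S_xy - S_x - S_y)/N + log2(N) with S = sum c*log2(c) over non-empty
    cells; negative rounding residue is clamped to 0.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum(axis=(-2, -1))

    def _s(a: np.ndarray, axis) -> np.ndarray:
        safe = np.where(a > 0, a, 1.0)
        return np.sum(a * np.log2(safe), axis=axis)

    s_xy = _s(c, (-2, -1))
    s_x = _s(c.sum(axis=-1), -1)
    s_y = _s(c.sum(axis=-2), -1)
    mi = (s_xy - s_x - s_y) / n + np.log2(n)
    return np.maximum(mi, 0.0)


def _radix_codes(genotypes: np.ndarray, snps: Sequence[int]) -> np.ndarray:
    """Encode each sample's genotype combination as sum g_j * 3^j."""
    g = genotypes[:, list(snps)].astype(np.int64)
    weights = 3 ** np.arange(len(snps), dtype=np.int64)
    return g @ weights


def mi_score(data: GenotypeDataset, snps: Sequence[int]) -> float:
    """MI (bits) between a k-order genotype combination and the phenotype.

    Builds the 3^k x 2 joint contingency table in one pass via radix
    encoding; empty cells contribute nothing.
    """
    snps = tuple(int(s) for s in snps)
    k = len(snps)
    if k < 2:
        raise ValueError("an interaction needs at least 2 SNPs")
    if len(set(snps)) != k:
        raise ValueError(f"duplicate SNP indices in {snps}")
    if min(snps) < 0 or max(snps) >= data.n_snps:
        raise ValueError(f"SNP index out of range in {snps}")
    codes = _radix_codes(data.genotypes, snps)
    y = data.phenotype.astype(np.int64)
    joint = np.bincount(codes * 2 + y, minlength=2 * 3**k).reshape(3**k, 2)
    return float(_mi_from_counts(joint[None, :, :])[0])


def _sorted_list(snps: np.ndarray, mi: np.ndarray, order: int) -> RankedInteractionList:
    keys = [snps[:, j] for j in range(snps.shape[1] - 1, -1, -1)]
    idx = np.lexsort(tuple(keys) + (-mi,))
    return RankedInteractionList(
        snps=np.ascontiguousarray(snps[idx]), mi=mi[idx], order=order
    )


def enumerate_interactions(data: GenotypeDataset, k: int) -> RankedInteractionList:
    """Score all C(n_snps, k) SNP sets of order k in {2, 3}, ranked by MI.

    The enumeration is chunked internally for vectorisation; the output is
    independent of the chunking.
    """
    if k not in (2, 3):
        raise ValueError("exhaustive enumeration supports k in {2, 3} only")
    n = data.n_snps
    if n < k:
        raise ValueError(f"need at least {k} SNPs, have {n}")
    g = data.genotypes.astype(np.int64)
    y = data.phenotype.astype(np.int64)[:, None]
    cells = 3**k
    stride = 2 * cells

    pair_idx: list[np.ndarray] = []
    mis: list[np.ndarray] = []
    if k == 2:
        for i in range(n - 1):
            span = n - 1 - i
            codes = (2 * g[:, i] + y[:, 0])[:, None] + 6 * g[:, i + 1 :]
            flat = codes + stride * np.arange(span, dtype=np.int64)
            cnt = np.bincount(flat.ravel(), minlength=stride * span)
            mi = _mi_from_counts(cnt.reshape(span, cells, 2))
            left = np.full(span, i, dtype=np.int32)
            right = np.arange(i + 1, n, dtype=np.int32)
            pair_idx.append(np.column_stack([left, right]))
            mis.append(mi)
    else:
        offs = None
        for i in range(n - 2):
            gi2 = 2 * g[:, i] + y[:, 0]
            for j in range(i + 1, n - 1):
                span = n - 1 - j
                base = gi2 + 6 * g[:, j]
                codes = base[:, None] + 18 * g[:, j + 1 :]
                if offs is None or offs.shape[0] < span:
                    offs = stride * np.arange(n, dtype=np.int64)
                flat = codes + offs[:span]
                cnt = np.bincount(flat.ravel(), minlength=stride * span)
                mi = _mi_from_counts(cnt.reshape(span, cells, 2))
                trip = np.empty((span, 3), dtype=np.int32)
                trip[:, 0] = i
                trip[:, 1] = j
                trip[:, 2] = np.arange(j + 1, n, dtype=np.int32)
                pair_idx.append(trip)
                mis.append(mi)
    snps = np.concatenate(pair_idx, axis=0)
    mi_all = np.concatenate(mis, axis=0)
    return _sorted_list(snps, mi_all, k)
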