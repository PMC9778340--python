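"""Elbow selection of high-MI interactions.

The ranked MI sequence s(1) >= s(2) >= ... is summarised by its fluctuation
(second forward difference) Score(s(i)) = s(i+2) - 2 s(i+1) + s(i).  Indices
whose fluctuation falls outside [M - V, M + V] (M = mean, V = population
variance, or the standard deviation under ``band="std"``) are outliers; a
window of preset length slides from the left and stops at the first position
that covers fewer than two outliers.  The window midpoint is the selection
threshold: the ranked prefix up to it enters the SNP network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import RankedInteractionList

__all__ = [
    "ThresholdResult",
    "fluctuation_scores",
    "find_outliers",
    "sliding_threshold",
    "select_interactions",
]

#: floor on the fallback threshold when the sliding rule cannot terminate
_FALLBACK_MIN = 100


@dataclass
class ThresholdResult:
    """Outcome of the fluctuation / outlier-band / sliding-window rule.

    ``threshold_index`` counts ranked entries (1-based, in [1, n]);
    ``selected`` is exactly the ranked prefix of that length.
    ``outlier_indices`` are 0-based positions into ``fluctuation``.
    """

    fluctuation: np.ndarray
    outlier_indices: np.ndarray
    window_len: int
    threshold_index: int
    selected: RankedInteractionList

    def to_frame(self) -> pd.DataFrame:
        """Diagnostics: fluctuation-vector rank, score, outlier flag."""
        m = len(self.fluctuation)
        flag = np.zeros(m, dtype=bool)
        flag[self.outlier_indices] = True
        return pd.DataFrame(
            {
                "rank": np.arange(1, m + 1),
                "fluctuation": self.fluctuation,
                "outlier": flag,
            }
        )


def _mi_vector(ranked) -> np.ndarray:
    if isinstance(ranked, RankedInteractionList):
        return np.asarray(ranked.mi, dtype=float)
    return np.asarray(ranked, dtype=float)


def fluctuation_scores(ranked) -> np.ndarray:
    """Second forward difference of the descending MI sequence (length n-2)."""
    s = _mi_vector(ranked)
    if s.shape[0] < 3:
        raise ValueError(
            "fewer than 3 ranked interactions: keep the whole list instead of thresholding"
        )
    return s[2:] - 2.0 * s[1:-1] + s[:-2]


def find_outliers(fluctuation, band: str = "variance") -> np.ndarray:
    """Indices whose fluctuation score leaves the [M - B, M + B] band.

    B is the population variance of the fluctuation vector (the literal
    rule) or its standard deviation under ``band="std"``.  Returns sorted
    0-based indices.
    """
    f = np.asarray(fluctuation, dtype=float)
    if f.size == 0:
        raise ValueError("fluctuation vector must be non-empty")
    if band not in ("variance", "std"):
        raise ValueError("band must be 'variance' or 'std'")
    m = f.mean()
    v = f.var()  # population variance
    b = v if band == "variance" else np.sqrt(v)
    out = np.flatnonzero((f < m - b) | (f > m + b))
    return out.astype(np.intp)


def sliding_threshold(
    fluctuation,
    outliers,
    window_len: int,
    n: int,
    fallback_index: int | None = None,
) -> int:
    """Slide a window over fluctuation indices; stop when it covers < 2 outliers.

    Returns a 1-based rank threshold p + floor(window_len / 2) for the first
    qualifying window start p (1-based).  When the window is longer than the
    vector, or every window covers two or more outliers, the fallback index
    is returned instead.
    """
    f = np.asarray(fluctuation, dtype=float)
    window_len = int(window_len)
    if window_len < 2:
        raise ValueError("window_len must be at least 2")
    if fallback_index is None:
        fallback_index = min(int(n), _FALLBACK_MIN)
    fallback_index = max(1, min(int(n), int(fallback_index)))
    m = f.shape[0]
    if window_len > m:
        return fallback_index
    is_out = np.zeros(m, dtype=np.int64)
    is_out[np.asarray(outliers, dtype=np.intp)] = 1
    csum = np.concatenate([[0], np.cumsum(is_out)])
    for p0 in range(0, m - window_len + 1):
        if csum[p0 + window_len] - csum[p0] < 2:
            return min(int(n), p0 + 1 + window_len // 2)
    return fallback_index


def _fallback_for(ranked: RankedInteractionList) -> int:
    n = len(ranked)
    n_snps = len(np.unique(ranked.snps))
    return min(n, max(2 * n_snps, _FALLBACK_MIN))


def select_interactions(
    ranked: RankedInteractionList,
    window_len: int = 10,
    band: str = "variance",
) -> ThresholdResult:
    """Apply the full threshold rule to one ranked interaction list.

    With fewer than 3 entries the rule degenerates to keeping everything.
    The same procedure is applied separately to the order-2 and order-3
    lists by the pipeline.
    """
    n = len(ranked)
    if n == 0:
        raise ValueError("ranked interaction list must be non-empty")
    if n < 3:
        return ThresholdResult(
            fluctuation=np.empty(0),
            outlier_indices=np.empty(0, dtype=np.intp),
            window_len=int(window_len),
            threshold_index=n,
            selected=ranked[:n],
        )
    fluct = fluctuation_scores(ranked)
    outliers = find_outliers(fluct, band=band)
    thr = sliding_threshold(
        fluct, outliers, window_len, n, fallback_index=_fallback_for(ranked)
    )
    return ThresholdResult(
        fluctuation=fluct,
        outlier_indices=outliers,
        window_len=int(window_len),
        threshold_index=thr,
        selected=ranked[:thr],
    )
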