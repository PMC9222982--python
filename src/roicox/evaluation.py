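"""Harrell concordance index and the paired model-comparison test.

The C-index is the fraction of *permissible* patient pairs whose risk
ordering agrees with their event ordering, crediting tied risk scores
half a pair.  A pair is permissible only when the earlier of the two
times corresponds to an observed event (a censored earlier time gives no
information on the ordering and the pair is discarded).  Tied event
times: two events at the same time are not comparable; an event tied
with a censoring time is permissible with the event treated as earlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateTestError, ShapeError, UndefinedMetricError

__all__ = ["ConcordanceResult", "concordance_index", "paired_model_comparison"]


@dataclass
class ConcordanceResult:
    c_index: float
    n_concordant: int
    n_discordant: int
    n_tied_score: int
    n_permissible_pairs: int


def concordance_index(
    risk: np.ndarray, t: np.ndarray, e: np.ndarray
) -> ConcordanceResult:
    """Concordance between risk scores and observed time-to-event ordering.

    Higher risk must predict the earlier event.  Raises
    :class:`UndefinedMetricError` when no permissible pair exists (e.g.
    every earlier time is censored).
    """
    risk = np.asarray(risk, dtype=float)
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=int)
    n = risk.shape[0]
    if t.shape[0] != n or e.shape[0] != n:
        raise ShapeError("risk, t, e must have equal lengths")

    # ordered pairs (i, j) where i is the informative earlier subject
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None].astype(bool), e[None, :].astype(bool)
    earlier_event = (ti < tj) & ei
    tied_time = (ti == tj) & ei & ~ej  # event precedes censoring at the same time
    permissible = earlier_event | tied_time

    ri, rj = risk[:, None], risk[None, :]
    concordant = int(np.count_nonzero(permissible & (ri > rj)))
    discordant = int(np.count_nonzero(permissible & (ri < rj)))
    tied_score = int(np.count_nonzero(permissible & (ri == rj)))
    total = concordant + discordant + tied_score
    if total == 0:
        raise UndefinedMetricError("no permissible pairs; C-index undefined")
    return ConcordanceResult(
        c_index=(concordant + 0.5 * tied_score) / total,
        n_concordant=concordant,
        n_discordant=discordant,
        n_tied_score=tied_score,
        n_permissible_pairs=total,
    )


def paired_model_comparison(
    c_a: np.ndarray, c_b: np.ndarray, alternative: str = "greater"
) -> float:
    """One-sided Wilcoxon signed-rank p-value comparing model B against A.

    ``alternative='greater'`` tests whether B's per-task C-indices exceed
    A's.  Zero differences are dropped before ranking (classical Wilcoxon
    treatment); the exact null distribution is used for n <= 25 differences
    and a continuity-corrected normal approximation above.
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    if c_a.shape != c_b.shape:
        raise ShapeError("paired C-index vectors must have equal lengths")
    if c_a.shape[0] < 5:
        raise ValueError("need at least 5 paired tasks")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = c_b - c_a
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(
        d, alternative=alternative, zero_method="wilcox", correction=True, method=method
    )
    return float(res.pvalue)
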