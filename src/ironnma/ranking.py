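"""Treatment ranking: league tables, rank probabilities, and SUCRA.

All quantities are derived from the identical set of pooled posterior
draws of the basic parameters, with the reference node participating at
d = 0.  For the "bad" non-response outcome rank 1 is the smallest
log-odds-ratio (lowest odds of non-response, i.e. the best treatment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .nma import PosteriorSamples


@dataclass(frozen=True)
class LeagueTable:
    """a x a grid: cell (j, k) = median OR and 95% CrI of node k vs node j."""

    labels: list[str]
    median: np.ndarray  # (a, a)
    lo: np.ndarray
    hi: np.ndarray

    def cell(self, node_j: str, node_k: str) -> tuple[float, float, float]:
        j, k = self.labels.index(node_j), self.labels.index(node_k)
        return (float(self.median[j, k]), float(self.lo[j, k]), float(self.hi[j, k]))

    def to_grid(self) -> pd.DataFrame:
        a = len(self.labels)
        cells = [
            [
                "1"
                if j == k
                else f"{self.median[j, k]:.2f} ({self.lo[j, k]:.2f} to {self.hi[j, k]:.2f})"
                for k in range(a)
            ]
            for j in range(a)
        ]
        return pd.DataFrame(cells, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for j, lj in enumerate(self.labels):
            for k, lk in enumerate(self.labels):
                if j == k:
                    continue
                rows.append(
                    {
                        "reference": lj,
                        "comparator": lk,
                        "or_median": self.median[j, k],
                        "or_lo": self.lo[j, k],
                        "or_hi": self.hi[j, k],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RankMatrix:
    """P(v = b): probability that node v holds rank b (rows: nodes)."""

    labels: list[str]  # sorted node labels
    P: np.ndarray      # (a, a); rows sum to 1, columns sum to 1
    direction: str

    @property
    def a(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SucraTable:
    """SUCRA per node with the cumulative rank probabilities behind it."""

    labels: list[str]        # sorted descending by SUCRA
    sucra: np.ndarray        # aligned with labels
    cumulative: np.ndarray   # (a, a): cum_{v,b}, rows aligned with labels

    def as_dict(self) -> dict[str, float]:
        return {l: float(s) for l, s in zip(self.labels, self.sucra)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.labels, "sucra": self.sucra})


def league_table(samples: PosteriorSamples) -> LeagueTable:
    """All-pairs odds-ratio table from a single pooled draw set.

    The diagonal is exactly 1 and cell (j, k) is the reciprocal of cell
    (k, j) at the median (percentile interpolation is symmetric under
    negation of the log-OR draws).
    """
    labels = list(samples.node_labels)
    pooled = samples.pooled_d()  # (N, a)
    a = len(labels)
    med = np.ones((a, a))
    lo = np.ones((a, a))
    hi = np.ones((a, a))
    for j in range(a):
        for k in range(a):
            if j == k:
                continue
            diff = pooled[:, k] - pooled[:, j]
            q = np.percentile(diff, [50.0, 2.5, 97.5])
            med[j, k], lo[j, k], hi[j, k] = np.exp(q)
    return LeagueTable(labels, med, lo, hi)


def rank_matrix(samples: PosteriorSamples, direction: str | None = None) -> RankMatrix:
    """Tally per-draw rankings of all nodes into P(v = b).

    For ``bad_outcome`` rank 1 goes to the smallest d (best treatment);
    for ``good_outcome`` to the largest.  Exact ties are broken by node
    label order (probability ~0 with continuous samplers).
    """
    direction = direction or samples.config.direction
    if direction not in ("bad_outcome", "good_outcome"):
        raise ValidationError(f"unknown direction {direction!r}")
    order_labels = sorted(samples.node_labels)
    cols = [samples.node_labels.index(l) for l in order_labels]
    pooled = samples.pooled_d()[:, cols]  # columns in label order => stable tie-break
    if direction == "good_outcome":
        pooled = -pooled
    a = pooled.shape[1]
    order = np.argsort(pooled, axis=1, kind="stable")       # (N, a): node at each rank
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(a)[None, :], axis=1)  # rank of each node
    counts = np.zeros((a, a))
    for v in range(a):
        counts[v] = np.bincount(ranks[:, v], minlength=a)
    P = counts / pooled.shape[0]
    return RankMatrix(order_labels, P, direction)


def sucra(rank: RankMatrix) -> SucraTable:
    """Surface under the cumulative ranking curve for every node.

    SUCRA_v = sum_{b=1}^{a-1} cum_{v,b} / (a - 1), where cum_{v,b} is
    the probability that node v is among the b best.  1 = certainly
    best, 0 = certainly worst; the mean over nodes is exactly 1/2.
    Returned sorted descending by SUCRA.
    """
    a = rank.a
    if a < 2:
        raise ValidationError("SUCRA needs >= 2 treatments")
    cum = np.cumsum(rank.P, axis=1)
    vals = cum[:, : a - 1].sum(axis=1) / (a - 1)
    idx = np.argsort(-vals, kind="stable")
    return SucraTable([rank.labels[i] for i in idx], vals[idx], cum[idx])
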