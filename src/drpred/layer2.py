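"""Second selection layer: mutual information and greedy mRMR.

Relevance and redundancy are both measured by plug-in mutual information
computed from a joint histogram.  Continuous variables are discretized into
equal-frequency bins (default 10; 5 when n < 100); binary variables keep
their two levels.  MI is reported in nats.  The greedy
minimum-redundancy–maximum-relevance score of a candidate X_i given the
selected set S is

    f_mRMR(X_i) = I(Y, X_i) - (1/|S|) * sum_{X_s in S} I(X_s, X_i)

with the redundancy term defined as 0 while S is empty (the first pick is
pure relevance).  Each pairwise MI is computed once and cached; ties break
to the lowest original column index.

Missing data are handled pairwise-complete: each MI uses only the rows where
both variables are observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import FeatureTable, ResponseVector, SelectionReport, logger


@dataclass
class MutualInfoEstimate:
    """Plug-in MI estimate with the discretization that produced it."""

    value: float          # nats, >= 0
    bins_x: int
    bins_y: int
    n: int                # complete pairs used


@dataclass
class MRMRState:
    """Trace of a greedy mRMR run: selection order and per-step scores."""

    selected: list[str]
    step_scores: list[float]
    relevance: dict[str, float]


def default_bins(n: int) -> int:
    """Equal-frequency bin count: 10, reduced to 5 for small samples."""
    return 5 if n < 100 else 10


def discretize(x: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Map a column to integer codes 0..levels-1 by equal-frequency binning.

    Variables with at most ``bins`` distinct values (e.g. binary features)
    keep their observed levels.  NaNs receive code -1 (missing).
    """
    x = np.asarray(x, dtype=float)
    codes = np.full(x.shape, -1, dtype=np.int64)
    obs = ~np.isnan(x)
    xv = x[obs]
    if xv.size == 0:
        return codes, 0
    uniq = np.unique(xv)
    if uniq.size <= bins:
        codes[obs] = np.searchsorted(uniq, xv)
        return codes, int(uniq.size)
    edges = np.quantile(xv, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(edges)
    c = np.searchsorted(edges, xv, side="right")
    # re-index to consecutive codes in case quantile edges collapsed
    levels, c = np.unique(c, return_inverse=True)
    codes[obs] = c
    return codes, int(levels.size)


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray, kx: int, ky: int) -> float:
    """Plug-in MI (nats) from integer codes; rows with code -1 are dropped."""
    ok = (cx >= 0) & (cy >= 0)
    cx, cy = cx[ok], cy[ok]
    n = cx.size
    if n == 0:
        raise ValueError("no complete pairs for mutual information")
    joint = np.bincount(cx * ky + cy, minlength=kx * ky).reshape(kx, ky)
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def mutual_information(
    x: np.ndarray, y: np.ndarray, bins: int | None = None
) -> MutualInfoEstimate:
    """Mutual information between two columns via the joint histogram.

    Deterministic: no randomness enters the estimator.  Fewer distinct
    complete values than ``bins`` reduces the bin count with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n == 0:
        raise ValueError("zero complete pairs")
    if bins is None:
        bins = default_bins(n)
    n_distinct = min(np.unique(x[ok]).size, np.unique(y[ok]).size)
    if n_distinct < bins:
        logger.debug("reducing bins from %d to %d distinct values", bins, n_distinct)
    cx, kx = discretize(np.where(ok, x, np.nan), bins)
    cy, ky = discretize(np.where(ok, y, np.nan), bins)
    return MutualInfoEstimate(
        value=_mi_from_codes(cx, cy, kx, ky), bins_x=kx, bins_y=ky, n=n
    )


def mrmr_select(
    table: FeatureTable,
    y: ResponseVector,
    m: int,
    bins: int | None = None,
    return_state: bool = False,
) -> tuple[FeatureTable, SelectionReport] | tuple[FeatureTable, SelectionReport, MRMRState]:
    """Greedy mRMR selection of ``m`` features.

    Step 1 picks the feature with maximal relevance I(Y, X_i); each later
    step maximizes relevance minus mean redundancy to the selected set.
    Redundancy MIs are computed once per (selected, candidate) pair.  The
    selection order is recorded in the report (``kept`` is ordered by
    selection) and in the optional ``MRMRState``.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if m > table.n_features:
        raise ValueError(f"m={m} exceeds {table.n_features} candidate features")
    n = table.n_samples
    if bins is None:
        bins = default_bins(n)

    # discretize every column once
    codes = np.empty((table.n_features, n), dtype=np.int64)
    levels = np.empty(table.n_features, dtype=np.int64)
    for j in range(table.n_features):
        codes[j], levels[j] = discretize(table.values[:, j], bins)
    cy, ky = discretize(y.values, bins)

    relevance = np.array(
        [_mi_from_codes(codes[j], cy, levels[j], ky) for j in range(table.n_features)]
    )

    selected: list[int] = []
    step_scores: list[float] = []
    red_sum = np.zeros(table.n_features)
    remaining = np.ones(table.n_features, dtype=bool)
    for _ in range(m):
        if selected:
            score = relevance - red_sum / len(selected)
        else:
            score = relevance.copy()
        score[~remaining] = -np.inf
        best = int(np.argmax(score))  # first max → lowest original index on ties
        selected.append(best)
        step_scores.append(float(score[best]))
        remaining[best] = False
        if len(selected) < m:
            cb, kb = codes[best], levels[best]
            for j in np.flatnonzero(remaining):
                red_sum[j] += _mi_from_codes(cb, codes[j], kb, levels[j])

    kept = [table.feature_ids[j] for j in selected]
    dropped = {
        table.feature_ids[j]: "not selected by mRMR"
        for j in np.flatnonzero(remaining)
    }
    report = SelectionReport(
        layer=2, kept=kept, dropped=dropped,
        scores={table.feature_ids[j]: float(relevance[j]) for j in range(table.n_features)},
    )
    out = table.select_features(kept)
    if return_state:
        state = MRMRState(
            selected=kept,
            step_scores=step_scores,
            relevance={table.feature_ids[j]: float(relevance[j]) for j in range(table.n_features)},
        )
        return out, report, state
    return out, report
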