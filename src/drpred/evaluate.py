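"""Cross-validation, variance-homogeneity testing, and drug recommendation.

Model quality is judged by k-fold cross-validation (ten folds by default):
the sample set is partitioned into seeded near-equal folds, the model —
including, by default, every feature-selection stage, so selection never
sees held-out samples — is refit on each training split, and RMSE, R² and
PICP are computed on the pooled out-of-fold predictions.  A "global
selection" mode (select once on all data, then cross-validate the head
alone) is available for comparability with workflows that select features
up front; it is information leakage and is logged as such.

For treatment recommendation, candidate drugs are compared on both the
point prediction (lower predicted IC50 = more potent) and the width of the
95% prediction interval (shorter = more stable response).  When the most
potent candidates are comparable in point prediction, the shorter interval
wins; interval-width comparisons are backed by a homogeneity-of-variance
test (Levene with median centering by default, Bartlett available, or a
Monte-Carlo comparison of two fitted gamma predictive distributions).  A
candidate whose lower and upper bounds both exceed every competitor's is
flagged as the aggressive/high-risk option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.stats

from .core_data import FeatureTable, ResponseVector, logger
from .glm import PredictionInterval, picp

#: a model spec maps (train_table, train_y, test_table) to predictions:
#: (point, lower, upper) arrays; lower/upper may be None for point-only heads
ModelSpec = Callable[
    [FeatureTable, ResponseVector, FeatureTable],
    tuple[np.ndarray, np.ndarray | None, np.ndarray | None],
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Pooled out-of-fold predictions and the headline metrics."""

    k: int
    fold_assignment: np.ndarray          # fold index per sample
    y_true: np.ndarray
    y_pred: np.ndarray
    lower: np.ndarray | None
    upper: np.ndarray | None
    r2: float
    rmse: float
    picp: float | None
    seed: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "r2": self.r2,
            "rmse": self.rmse,
            "picp": self.picp,
            "seed": self.seed,
            "n": int(self.y_true.size),
        }


def kfold_partition(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Seeded shuffled partition into k near-equal folds (fold id per sample)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        folds[chunk] = f
    return folds


def kfold_cv(
    table: FeatureTable,
    y: ResponseVector,
    model_spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Cross-validate a model spec; metrics on pooled out-of-fold predictions.

    The spec is responsible for everything that must be refit per fold
    (selection layers included when leakage-free evaluation is wanted).
    """
    n = table.n_samples
    folds = kfold_partition(n, k, seed)
    assert np.array_equal(np.sort(np.unique(folds)), np.arange(k))
    y_pred = np.full(n, np.nan)
    lower = np.full(n, np.nan)
    upper = np.full(n, np.nan)
    has_intervals = True
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        point, lo, hi = model_spec(
            table.select_samples(train_idx),
            y.select_samples([int(i) for i in train_idx]),
            table.select_samples(test_idx),
        )
        y_pred[test_idx] = point
        if lo is None or hi is None:
            has_intervals = False
        else:
            lower[test_idx] = lo
            upper[test_idx] = hi
    assert not np.isnan(y_pred).any(), "every sample must be predicted exactly once"
    cov = picp((lower, upper), y.values) if has_intervals else None
    return CVReport(
        k=k, fold_assignment=folds, y_true=y.values.copy(), y_pred=y_pred,
        lower=lower if has_intervals else None,
        upper=upper if has_intervals else None,
        r2=r2_score(y.values, y_pred), rmse=rmse(y.values, y_pred),
        picp=cov, seed=seed,
    )


# ---------------------------------------------------------------------------
# Homogeneity-of-variance tests
# ---------------------------------------------------------------------------

@dataclass
class VarianceTestResult:
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def variance_homogeneity_test(
    sample_a: np.ndarray, sample_b: np.ndarray, method: str = "levene"
) -> VarianceTestResult:
    """Test whether two samples share a variance.

    Levene with median centering (Brown–Forsythe, robust to the skewed
    response scale) by default; Bartlett available.  Two degenerate
    zero-variance samples give statistic 0, p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        logger.warning("both samples have zero variance; test degenerate")
        return VarianceTestResult(method, 0.0, 1.0, a.size, b.size)
    if method == "levene":
        stat, p = scipy.stats.levene(a, b, center="median")
    elif method == "bartlett":
        stat, p = scipy.stats.bartlett(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return VarianceTestResult(method, float(stat), float(p), a.size, b.size)


def gamma_variance_ratio_test(
    mu_a: float, k_a: float, mu_b: float, k_b: float,
    n_draws: int = 2000, seed: int = 0,
) -> VarianceTestResult:
    """Compare two gamma predictive distributions' spreads (Var = mu^2/k)
    via seeded Monte-Carlo draws followed by a Levene test."""
    rng = np.random.default_rng(seed)
    a = rng.gamma(shape=k_a, scale=mu_a / k_a, size=n_draws)
    b = rng.gamma(shape=k_b, scale=mu_b / k_b, size=n_draws)
    res = variance_homogeneity_test(a, b, method="levene")
    return VarianceTestResult("gamma_variance_ratio", res.statistic, res.p_value,
                              n_draws, n_draws)


# ---------------------------------------------------------------------------
# Interval-based drug recommendation
# ---------------------------------------------------------------------------

@dataclass
class RecommendationReport:
    recommended: str
    rationale: str
    ranking: list[str]                    # by point prediction ascending
    intervals: dict[str, PredictionInterval]
    high_risk: list[str] = field(default_factory=list)
    pairwise_tests: dict[str, VarianceTestResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "recommended": self.recommended,
            "rationale": self.rationale,
            "ranking": list(self.ranking),
            "high_risk": list(self.high_risk),
            "intervals": {
                d: {"point": iv.point, "lower": iv.lower, "upper": iv.upper,
                    "level": iv.level}
                for d, iv in self.intervals.items()
            },
            "pairwise_tests": {
                pair: {"method": t.method, "statistic": t.statistic,
                       "p_value": t.p_value}
                for pair, t in self.pairwise_tests.items()
            },
        }


def recommend_drug(
    candidates: Sequence[tuple[str, PredictionInterval]],
    rel_margin: float = 0.2,
    predictive_params: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> RecommendationReport:
    """Pick a drug from per-drug predictions with intervals at one level.

    Rule: rank by point prediction ascending (lower IC50 = more potent);
    among candidates whose points are within ``rel_margin`` (relative) of
    the most potent, prefer the shortest interval.  Candidates whose lower
    AND upper bounds exceed every competitor's are flagged aggressive /
    high-risk.  When gamma predictive parameters (mu, k) per drug are
    supplied, pairwise variance-homogeneity tests are attached.

    The outcome is invariant to candidate ordering.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidates")
    levels = {iv.level for _, iv in cands}
    if len(levels) > 1:
        raise ValueError(f"mismatched interval levels: {sorted(levels)}")
    by_point = sorted(cands, key=lambda c: (c[1].point, c[0]))
    ranking = [d for d, _ in by_point]
    intervals = dict(cands)

    if len(cands) == 1:
        return RecommendationReport(
            recommended=cands[0][0],
            rationale="single candidate; recommended unconditionally",
            ranking=ranking, intervals=intervals,
        )

    best_point = by_point[0][1].point
    comparable = [
        (d, iv) for d, iv in by_point
        if iv.point <= best_point * (1.0 + rel_margin)
    ]
    chosen, chosen_iv = min(comparable, key=lambda c: (c[1].width, c[0]))
    if len(comparable) > 1 and chosen != by_point[0][0]:
        rationale = (
            f"{chosen}: point prediction within {rel_margin:.0%} of the most "
            f"potent candidate and shortest interval "
            f"(width {chosen_iv.width:.3g}) among comparable candidates"
        )
    elif len(comparable) > 1:
        rationale = (
            f"{chosen}: lowest point prediction and shortest interval "
            f"among candidates within the {rel_margin:.0%} margin"
        )
    else:
        rationale = f"{chosen}: lowest point prediction (no comparable rival)"

    high_risk = []
    for d, iv in cands:
        others = [o for o in cands if o[0] != d]
        if all(iv.lower > o[1].lower and iv.upper > o[1].upper for o in others):
            high_risk.append(d)
            rationale += (
                f"; {d} flagged aggressive/high-risk (both bounds exceed "
                "every competitor's)"
            )

    tests: dict[str, VarianceTestResult] = {}
    if predictive_params:
        names = sorted(predictive_params)
        for i, da in enumerate(names):
            for db in names[i + 1:]:
                mu_a, k_a = predictive_params[da]
                mu_b, k_b = predictive_params[db]
                tests[f"{da}|{db}"] = gamma_variance_ratio_test(
                    mu_a, k_a, mu_b, k_b, seed=seed
                )

    return RecommendationReport(
        recommended=chosen, rationale=rationale, ranking=ranking,
        intervals=intervals, high_risk=high_risk, pairwise_tests=tests,
    )
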