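"""First selection layer: autoencoder connection-weight screening.

A single-hidden-layer tanh autoencoder is trained to reconstruct each
continuous feature block (RNA and CNV separately).  Feature importance is
then read off the trained weights with the Gedeon connection-weight scheme:

    P_ik = |W_ik| / sum_i* |W_i*k|          (input i → hidden unit k)
    P_kj = |V_kj| / sum_k* |V_k*j|          (hidden k → output j)
    Q_ij = sum_k P_ik P_kj                  (input i → output j)
    q_i  = sum_j Q_ij / sum_i* Q_i*j        (total contribution of input i)

Absolute weights are used throughout: signed weights make the shares
non-monotone in influence and can zero a denominator.  Each column of P sums
to one, so sum_i q_i = G exactly — an algebraic identity the code asserts.

Features are ranked by q and the top half retained (the cut fraction and
direction are configurable), then near-duplicates (|Pearson r| above a
threshold, default 0.8) are collapsed to the highest-contribution member of
each correlated component.  Binary mutation features bypass this layer and
are merged back untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_data import (
    CONTINUOUS_KINDS,
    FeatureTable,
    PipelineConfig,
    SelectionReport,
    logger,
)


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderModel:
    """Single-hidden-layer tanh autoencoder: x → tanh(x W_in + b1) W_out + b2."""

    w_in: np.ndarray           # (G, K)
    b_hidden: np.ndarray       # (K,)
    w_out: np.ndarray          # (K, G)
    b_out: np.ndarray          # (G,)
    feature_ids: list[str]
    epochs_trained: int
    final_loss: float
    col_mean: np.ndarray
    col_std: np.ndarray

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[1]

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        z = (x - self.col_mean) / self.col_std
        h = np.tanh(z @ self.w_in + self.b_hidden)
        return h @ self.w_out + self.b_out


def train_autoencoder(
    block: FeatureTable | np.ndarray,
    hidden: int | None = None,
    epochs: int = 200,
    lr: float = 0.01,
    seed: int = 0,
    feature_ids: list[str] | None = None,
) -> AutoencoderModel:
    """Train the reconstruction autoencoder on a complete continuous block.

    Columns are standardized internally; training is full-batch Adam on the
    mean squared reconstruction error, seeded for exact reproducibility.
    Hidden width defaults to ``min(64, G // 4)`` (at least 1) and must
    compress (K < G).
    """
    if isinstance(block, FeatureTable):
        if block.missing_mask.any():
            raise ValueError("autoencoder block must have no missing values")
        feature_ids = list(block.feature_ids)
        x = block.values
    else:
        x = np.asarray(block, dtype=float)
        feature_ids = list(feature_ids) if feature_ids is not None else [
            f"f{j}" for j in range(x.shape[1])
        ]
    if not np.isfinite(x).all():
        raise ValueError("non-finite inputs to autoencoder")
    n, g = x.shape
    if hidden is None:
        hidden = max(1, min(64, g // 4))
    if hidden >= g:
        raise ValueError(f"hidden width {hidden} must be < {g} inputs (no compression)")
    if epochs < 0:
        raise ValueError("epochs must be >= 0")

    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    z = (x - mean) / std

    rng = np.random.default_rng(seed)
    scale_in = 1.0 / math.sqrt(g)
    scale_hid = 1.0 / math.sqrt(hidden)
    w_in = rng.normal(0.0, scale_in, size=(g, hidden))
    b1 = np.zeros(hidden)
    w_out = rng.normal(0.0, scale_hid, size=(hidden, g))
    b2 = np.zeros(g)

    params = [w_in, b1, w_out, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    loss = float(np.mean(z**2))  # loss of the zero reconstruction
    if epochs == 0:
        logger.warning("autoencoder returned with untrained seeded weights (epochs=0)")
    for t in range(1, epochs + 1):
        h_pre = z @ w_in + b1
        h = np.tanh(h_pre)
        recon = h @ w_out + b2
        err = recon - z
        loss = float(np.mean(err**2))
        d_recon = 2.0 * err / err.size
        g_wout = h.T @ d_recon
        g_b2 = d_recon.sum(axis=0)
        d_h = d_recon @ w_out.T
        d_pre = d_h * (1.0 - h**2)
        g_win = z.T @ d_pre
        g_b1 = d_pre.sum(axis=0)
        for p, m_, v_, grad in zip(params, m_t, v_t, [g_win, g_b1, g_wout, g_b2]):
            m_ *= beta1
            m_ += (1 - beta1) * grad
            v_ *= beta2
            v_ += (1 - beta2) * grad**2
            m_hat = m_ / (1 - beta1**t)
            v_hat = v_ / (1 - beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    return AutoencoderModel(
        w_in=w_in, b_hidden=b1, w_out=w_out, b_out=b2,
        feature_ids=feature_ids, epochs_trained=epochs,
        final_loss=loss, col_mean=mean, col_std=std,
    )


# ---------------------------------------------------------------------------
# Connection-weight contributions
# ---------------------------------------------------------------------------

@dataclass
class ContributionTable:
    """Normalized connection-weight contributions of a trained autoencoder."""

    p_in: np.ndarray     # (G, K), columns sum to 1
    p_out: np.ndarray    # (K, G), columns sum to 1
    q_matrix: np.ndarray  # (G, G) input→output contributions
    q: np.ndarray        # (G,) total contribution per input; sums to G
    feature_ids: list[str]


def _column_shares(w_abs: np.ndarray, what: str) -> np.ndarray:
    """Normalize |weights| so each column sums to 1; all-zero columns stay 0."""
    col = w_abs.sum(axis=0)
    zero = col == 0.0
    if zero.any():
        logger.warning(
            "%d %s with all-zero weights contribute nothing", int(zero.sum()), what
        )
    return np.divide(w_abs, np.where(zero, 1.0, col), out=np.zeros_like(w_abs))


def input_contributions(model: AutoencoderModel) -> ContributionTable:
    """Propagate normalized absolute weights input → hidden → output."""
    p_in = _column_shares(np.abs(model.w_in), "hidden units")
    p_out = _column_shares(np.abs(model.w_out), "outputs")
    q_mat = p_in @ p_out
    col = q_mat.sum(axis=0)
    q_norm = np.divide(q_mat, np.where(col == 0.0, 1.0, col), out=np.zeros_like(q_mat))
    q = q_norm.sum(axis=1)
    return ContributionTable(
        p_in=p_in, p_out=p_out, q_matrix=q_mat, q=q, feature_ids=list(model.feature_ids)
    )


# ---------------------------------------------------------------------------
# Ranking cut and correlation dedup
# ---------------------------------------------------------------------------

def rank_and_cut(
    q: np.ndarray,
    feature_ids: list[str],
    keep_fraction: float = 0.5,
    direction: str = "top",
) -> SelectionReport:
    """Keep ``ceil(keep_fraction * G)`` features by contribution ranking.

    ``direction="top"`` (default) retains the highest-contribution features;
    ties are broken by original column order (stable sort).
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    q = np.asarray(q, dtype=float)
    g = q.size
    n_keep = math.ceil(keep_fraction * g)
    key = -q if direction == "top" else q
    order = np.argsort(key, kind="stable")
    kept_idx = sorted(order[:n_keep])
    kept = [feature_ids[i] for i in kept_idx]
    dropped = {
        feature_ids[i]: f"contribution rank below {direction} {keep_fraction:.0%} cut"
        for i in order[n_keep:]
    }
    return SelectionReport(
        layer=1, kept=kept, dropped=dropped,
        scores={fid: float(q[i]) for i, fid in enumerate(feature_ids)},
    )


def correlation_dedup(
    block: FeatureTable | np.ndarray,
    q: np.ndarray,
    threshold: float = 0.8,
    feature_ids: list[str] | None = None,
) -> SelectionReport:
    """Collapse highly correlated features to one representative each.

    Builds a graph with an edge where |Pearson r| > ``threshold`` (strict,
    on complete rows) and keeps, per connected component, the member with
    the highest contribution q (ties → lowest original index).  A constant
    feature has undefined correlations and forms its own component.
    """
    if isinstance(block, FeatureTable):
        feature_ids = list(block.feature_ids)
        x = np.where(block.missing_mask, np.nan, block.values)
    else:
        x = np.asarray(block, dtype=float)
        feature_ids = list(feature_ids) if feature_ids is not None else [
            f"f{j}" for j in range(x.shape[1])
        ]
    q = np.asarray(q, dtype=float)
    g = x.shape[1]
    if np.isnan(x).any():
        complete = ~np.isnan(x).any(axis=1)
        x = x[complete]
    std = x.std(axis=0)
    constant = std == 0.0
    if constant.any():
        logger.warning(
            "%d constant features have undefined correlations; kept as singletons",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(np.nan_to_num(r, nan=0.0))
    adj = np.abs(r) > threshold
    np.fill_diagonal(adj, False)
    adj[constant, :] = False
    adj[:, constant] = False
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    kept: list[int] = []
    dropped: dict[str, str] = {}
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        best = members[np.argmax(q[members])]  # argmax → lowest index on ties
        kept.append(best)
        for m_ in members:
            if m_ != best:
                dropped[feature_ids[m_]] = (
                    f"|r| > {threshold} with {feature_ids[best]} (component {c})"
                )
    kept.sort()
    return SelectionReport(
        layer=1,
        kept=[feature_ids[i] for i in kept],
        dropped=dropped,
        scores={fid: float(q[i]) for i, fid in enumerate(feature_ids)},
    )


# ---------------------------------------------------------------------------
# Full layer-1 screen
# ---------------------------------------------------------------------------

def screen_layer1(
    table: FeatureTable, config: PipelineConfig | None = None, seed: int | None = None
) -> tuple[FeatureTable, SelectionReport]:
    """Run the contribution screen per continuous kind and merge survivors.

    One autoencoder is trained per continuous kind (RNA, CNV); each block is
    ranked and cut, then deduplicated by correlation.  MUT (and FP) features
    bypass the screen and are merged back untouched.  A kind with fewer than
    two features is passed through with a warning.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    kept_ids: list[str] = []
    dropped: dict[str, str] = {}
    scores: dict[str, float] = {}

    for offset, kind in enumerate(CONTINUOUS_KINDS):
        idx = table.kind_indices(kind)
        if idx.size == 0:
            continue
        if idx.size < 2:
            logger.warning("kind %s has < 2 features; screening skipped", kind)
            kept_ids.extend(table.feature_ids[i] for i in idx)
            continue
        block = table.select_features(idx)
        model = train_autoencoder(
            block,
            hidden=config.ae_hidden,
            epochs=config.ae_epochs,
            lr=config.ae_lr,
            seed=seed + offset,
        )
        contrib = input_contributions(model)
        cut = rank_and_cut(
            contrib.q, block.feature_ids,
            keep_fraction=config.keep_fraction,
            direction=config.keep_direction,
        )
        scores.update(cut.scores)
        dropped.update(cut.dropped)
        sub = block.select_features(cut.kept)
        q_sub = np.array([contrib.q[block.feature_ids.index(f)] for f in cut.kept])
        dedup = correlation_dedup(sub, q_sub, threshold=config.corr_threshold)
        dropped.update(dedup.dropped)
        kept_ids.extend(dedup.kept)

    for kind in ("MUT", "FP"):
        kept_ids.extend(table.feature_ids[i] for i in table.kind_indices(kind))

    # preserve original column order in the output table
    kept_in_order = [f for f in table.feature_ids if f in set(kept_ids)]
    report = SelectionReport(layer=1, kept=kept_in_order, dropped=dropped, scores=scores)
    return table.select_features(kept_in_order), report
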