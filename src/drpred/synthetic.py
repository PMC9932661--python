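"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the shape of pharmacogenomic inputs: correlated
continuous expression/copy-number blocks, sparse binary mutation indicators,
binary fingerprint bits, and a strictly positive response drawn from a gamma
distribution whose mean is log-linear in a small set of informative
features:

    mu_i = exp(beta_0 + sum_j beta_j x_ij),   y_i ~ Gamma(k, scale=mu_i / k)

so that Var(y_i | x_i) = mu_i^2 / k.  Effect sizes default to |beta| in
[0.3, 1.0] with random signs: detectable but not trivial at the small
per-drug sample sizes (tens of cell lines) the method targets, while still
recoverable at larger n.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import FeatureTable, ResponseVector

DEFAULT_BLOCK_SIZE = 5


@dataclass
class GroundTruth:
    """What the generator knows: which features drive the response and how."""

    informative_ids: list[str]
    beta: dict[str, float]          # feature id → coefficient; "intercept" included
    shape_k: float
    correlation_blocks: list[list[str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_k <= 0:
            raise ValueError("shape_k must be positive")

    def mean_response(self, table: FeatureTable) -> np.ndarray:
        """exp(x beta) for each sample of ``table`` (informative columns only)."""
        eta = np.full(table.n_samples, self.beta.get("intercept", 0.0))
        for fid in self.informative_ids:
            j = table.feature_index(fid)
            col = np.nan_to_num(table.values[:, j], nan=0.0)
            eta = eta + self.beta[fid] * col
        return np.exp(eta)


def _correlated_block_matrix(
    rng: np.random.Generator, n: int, g: int, rho: float, block_size: int
) -> tuple[np.ndarray, list[list[int]]]:
    """Standard-normal features with pairwise correlation ``rho`` inside
    consecutive blocks of ``block_size`` columns."""
    x = np.empty((n, g))
    blocks: list[list[int]] = []
    for start in range(0, g, block_size):
        cols = list(range(start, min(start + block_size, g)))
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, len(cols)))
        x[:, cols] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        blocks.append(cols)
    return x, blocks


def simulate_dataset(
    n_samples: int,
    n_rna: int = 100,
    n_cnv: int = 50,
    n_mut: int = 20,
    n_fp: int = 0,
    n_informative: int = 5,
    shape_k: float = 5.0,
    block_rho: float = 0.5,
    seed: int = 0,
    beta_range: tuple[float, float] = (0.3, 1.0),
    intercept: float = 1.0,
    beta: dict[str, float] | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    mut_rate: float = 0.15,
    fp_rate: float = 0.3,
) -> tuple[FeatureTable, ResponseVector, GroundTruth]:
    """Simulate a feature table and gamma-distributed responses.

    Informative features are drawn from the continuous (RNA, then CNV)
    columns, one per correlation block so the signal is spread across
    blocks.  Passing ``beta`` (feature id → coefficient, optional
    ``"intercept"``) overrides the random coefficient draw.

    With ``n_informative=0`` the responses are i.i.d. Gamma with constant
    mean ``exp(intercept)``.
    """
    total = n_rna + n_cnv + n_mut + n_fp
    if total <= 0:
        raise ValueError("no features requested")
    n_cont = n_rna + n_cnv
    if n_informative > total:
        raise ValueError("n_informative exceeds total features")
    if n_informative > n_cont:
        raise ValueError("informative features are drawn from RNA/CNV columns only")
    if not 0.0 <= block_rho <= 1.0:
        raise ValueError("block_rho must be in [0, 1]")
    rng = np.random.default_rng(seed)

    feature_ids: list[str] = (
        [f"rna_g{i}" for i in range(n_rna)]
        + [f"cnv_g{i}" for i in range(n_cnv)]
        + [f"mut_g{i}" for i in range(n_mut)]
        + [f"fp_b{i}" for i in range(n_fp)]
    )
    kinds = np.asarray(
        ["RNA"] * n_rna + ["CNV"] * n_cnv + ["MUT"] * n_mut + ["FP"] * n_fp,
        dtype=object,
    )

    parts = []
    blocks_idx: list[list[int]] = []
    if n_rna:
        x_rna, b = _correlated_block_matrix(rng, n_samples, n_rna, block_rho, block_size)
        parts.append(x_rna)
        blocks_idx += b
    if n_cnv:
        x_cnv, b = _correlated_block_matrix(rng, n_samples, n_cnv, block_rho, block_size)
        parts.append(x_cnv)
        blocks_idx += [[n_rna + j for j in blk] for blk in b]
    if n_mut:
        parts.append(rng.binomial(1, mut_rate, size=(n_samples, n_mut)).astype(float))
    if n_fp:
        parts.append(rng.binomial(1, fp_rate, size=(n_samples, n_fp)).astype(float))
    values = np.concatenate(parts, axis=1) if parts else np.empty((n_samples, 0))

    # informative columns: first member of successive correlation blocks,
    # falling back to round-robin over continuous columns
    if beta is not None:
        coef = {k: float(v) for k, v in beta.items()}
        coef.setdefault("intercept", intercept)
        informative = [k for k in coef if k != "intercept"]
        unknown = set(informative) - set(feature_ids)
        if unknown:
            raise ValueError(f"beta refers to unknown features {sorted(unknown)}")
    else:
        leaders = [blk[0] for blk in blocks_idx]
        extras = [j for j in range(n_cont) if j not in leaders]
        chosen = (leaders + extras)[:n_informative]
        informative = [feature_ids[j] for j in chosen]
        mags = rng.uniform(beta_range[0], beta_range[1], size=n_informative)
        signs = rng.choice([-1.0, 1.0], size=n_informative)
        coef = {"intercept": intercept}
        coef.update({fid: float(m * s) for fid, m, s in zip(informative, mags, signs)})

    eta = np.full(n_samples, coef["intercept"])
    for fid in informative:
        eta = eta + coef[fid] * values[:, feature_ids.index(fid)]
    mu = np.exp(eta)
    y = rng.gamma(shape=shape_k, scale=mu / shape_k)

    table = FeatureTable(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        feature_ids=feature_ids,
        kinds=kinds,
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
    )
    response = ResponseVector(table.sample_ids, y, transform="none")
    truth = GroundTruth(
        informative_ids=list(informative),
        beta=coef,
        shape_k=float(shape_k),
        correlation_blocks=[[feature_ids[j] for j in blk] for blk in blocks_idx],
        seed=seed,
    )
    return table, response, truth


def inject_missing(
    table: FeatureTable,
    rate: float,
    kinds: tuple[str, ...] | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Mask a seeded random fraction of cells, restricted to ``kinds``.

    Emulates the missingness that arises when heterogeneous feature blocks
    are merged across sources.  Values outside the named kinds are untouched.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    cols = (
        np.arange(table.n_features)
        if kinds is None
        else np.flatnonzero(np.isin(table.kinds, list(kinds)))
    )
    hit = rng.random((table.n_samples, cols.size)) < rate
    values = table.values.copy()
    mask = table.missing_mask.copy()
    sub = values[:, cols]
    sub[hit] = np.nan
    values[:, cols] = sub
    mask[:, cols] = mask[:, cols] | hit
    return FeatureTable(
        sample_ids=table.sample_ids,
        feature_ids=table.feature_ids,
        kinds=table.kinds,
        values=values,
        missing_mask=mask,
    )
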