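"""Orchestration of the per-drug and combined prediction paths.

Per-drug path (genomic features only, labels untransformed):

    contribution screen (layer 1) → mRMR (layer 2, m=500)
    → boosted-tree selection (layer 3, cap 40) → gamma GLM (AIC family check)

Combined path (all drugs stacked as (cell line, drug) pairs, each pair
carrying its drug's fingerprint bits, labels log1p-transformed):

    stack + fingerprints → mRMR → boosted selection → GLM or ANN head

Stage reports chain: each stage's input feature list equals the previous
stage's kept list, and the run manifest records the config, seed and
per-stage dimensions.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ann as ann_mod
from . import glm as glm_mod
from .core_data import (
    FeatureTable,
    PipelineConfig,
    ResponseVector,
    SelectionReport,
    apply_transform,
    logger,
)
from .evaluate import CVReport, kfold_cv
from .layer1 import screen_layer1
from .layer2 import mrmr_select
from .layer3 import select_layer3


@dataclass
class FittedModel:
    """A fitted head plus the feature set it expects."""

    kind: str                               # "glm" | "ann"
    feature_ids: list[str]
    glm_fit: glm_mod.GLMFit | None = None
    mlp: ann_mod.MLPModel | None = None
    level: float = 0.95

    def predict(
        self, table: FeatureTable
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
        sub = table.select_features(self.feature_ids)
        if self.kind == "glm":
            return glm_mod.prediction_intervals(self.glm_fit, sub, level=self.level)
        point = ann_mod.predict_mlp(self.mlp, sub)
        return point, None, None


@dataclass
class PipelineRun:
    """Everything one pipeline invocation produced."""

    path: str                               # "per_drug" | "combined"
    config: PipelineConfig
    reports: list[SelectionReport]
    model: FittedModel
    cv: CVReport | None
    seed: int
    stage_timings: dict[str, float] = field(default_factory=dict)

    def dimension_chain(self) -> list[int]:
        dims = [len(self.reports[0].input_features)] if self.reports else []
        dims += [len(r.kept) for r in self.reports]
        return dims

    def manifest(self) -> dict:
        return {
            "path": self.path,
            "seed": self.seed,
            "config": self.config.to_yaml(),
            "dimension_chain": self.dimension_chain(),
            "reports": [r.to_dict() for r in self.reports],
            "model": {
                "kind": self.model.kind,
                "n_features": len(self.model.feature_ids),
                **({"glm": self.model.glm_fit.to_dict()} if self.model.glm_fit else {}),
            },
            "cv": self.cv.to_dict() if self.cv else None,
            "stage_timings": self.stage_timings,
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def _fit_head(
    table: FeatureTable, y: ResponseVector, config: PipelineConfig, head: str, seed: int
) -> FittedModel:
    if head == "glm":
        if config.glm_family == "auto":
            fit = glm_mod.select_family_by_aic(
                table, y, link=config.glm_link, max_iter=config.glm_max_iter
            )
        else:
            fit = glm_mod.fit_glm(
                table, y, family=config.glm_family, link=config.glm_link,
                max_iter=config.glm_max_iter,
            )
        return FittedModel(
            kind="glm", feature_ids=list(table.feature_ids),
            glm_fit=fit, level=config.interval_level,
        )
    if head == "ann":
        mlp = ann_mod.fit_mlp(
            table, y, widths=config.ann_widths, dropout_rate=config.ann_dropout,
            epochs=config.ann_epochs, batch_size=config.ann_batch_size,
            learning_rate=config.ann_lr, seed=seed,
        )
        return FittedModel(kind="ann", feature_ids=list(table.feature_ids), mlp=mlp)
    raise ValueError(f"unknown head {head!r}")


def fit_per_drug(
    table: FeatureTable,
    y: ResponseVector,
    config: PipelineConfig | None = None,
    head: str = "glm",
    seed: int | None = None,
) -> tuple[FittedModel, list[SelectionReport], dict[str, float]]:
    """Run the three selection layers then fit the head; returns the fitted
    model, the per-stage reports, and stage timings."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    reports: list[SelectionReport] = []
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    try:
        t1_table, rep1 = screen_layer1(table, config, seed=seed)
        reports.append(rep1)
        timings["layer1"] = time.perf_counter() - t0

        m = config.mrmr_m
        if m > t1_table.n_features:
            logger.warning(
                "mRMR m=%d exceeds %d candidates; keeping all", m, t1_table.n_features
            )
            m = t1_table.n_features
        t0 = time.perf_counter()
        t2_table, rep2 = mrmr_select(t1_table, y, m=m, bins=config.mi_bins)
        reports.append(rep2)
        timings["layer2"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        t3_table, rep3 = select_layer3(
            t2_table, y, rounds=config.boost_rounds, max_depth=config.boost_max_depth,
            lam=config.boost_lambda, gamma_penalty=config.boost_gamma,
            shrinkage=config.boost_shrinkage, cap=config.layer3_cap,
        )
        reports.append(rep3)
        timings["layer3"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        model = _fit_head(t3_table, y, config, head, seed)
        timings["head"] = time.perf_counter() - t0
    except Exception as exc:
        stage = ["layer1", "layer2", "layer3", "head"][len(reports)] \
            if len(reports) < 4 else "head"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return model, reports, timings


def run_per_drug(
    table: FeatureTable,
    y: ResponseVector,
    config: PipelineConfig | None = None,
    head: str = "glm",
    cross_validate: bool = False,
    seed: int | None = None,
) -> PipelineRun:
    """Full per-drug path; optionally ten-fold cross-validated.

    With ``config.selection_in_cv`` (default) every selection layer is refit
    inside each fold; otherwise selection runs once on all data and only the
    head is refit per fold (leakage, logged).
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    model, reports, timings = fit_per_drug(table, y, config, head=head, seed=seed)

    cv = None
    if cross_validate:
        if config.selection_in_cv:
            def spec(tr_table, tr_y, te_table):
                m, _, _ = fit_per_drug(tr_table, tr_y, config, head=head, seed=seed)
                return m.predict(te_table)
        else:
            logger.warning(
                "global-selection CV: selection layers saw the held-out folds"
            )
            selected = model.feature_ids

            def spec(tr_table, tr_y, te_table):
                m = _fit_head(
                    tr_table.select_features(selected), tr_y, config, head, seed
                )
                return m.predict(te_table)
        cv = kfold_cv(table, y, spec, k=config.cv_folds, seed=seed)

    return PipelineRun(
        path="per_drug", config=config, reports=reports, model=model,
        cv=cv, seed=seed, stage_timings=timings,
    )


# ---------------------------------------------------------------------------
# Combined path
# ---------------------------------------------------------------------------

def stack_drugs(
    tables: dict[str, FeatureTable],
    responses: dict[str, ResponseVector],
    fingerprints: dict[str, np.ndarray],
    transform: str = "log1p",
) -> tuple[FeatureTable, ResponseVector]:
    """Stack per-drug datasets into (cell line, drug) rows with FP bits.

    Every drug needs a fingerprint vector (equal widths); each stacked row
    appends its drug's bits as FP features.  Feature namespaces must agree
    across drugs.  The stacked labels get the stated transform (responses
    must be untransformed on input).
    """
    drugs = sorted(tables)
    if set(responses) != set(tables):
        raise ValueError("tables and responses must cover the same drugs")
    missing_fp = [d for d in drugs if d not in fingerprints]
    if missing_fp:
        raise ValueError(f"drugs without fingerprint block: {missing_fp}")
    widths = {len(np.ravel(fingerprints[d])) for d in drugs}
    if len(widths) != 1:
        raise ValueError(f"inconsistent fingerprint widths: {sorted(widths)}")
    n_bits = widths.pop()

    ref = tables[drugs[0]]
    feature_ids = list(ref.feature_ids)
    for d in drugs[1:]:
        if list(tables[d].feature_ids) != feature_ids:
            raise ValueError(f"feature namespace of {d} differs from {drugs[0]}")

    rows, masks, ids, raw_y = [], [], [], []
    for d in drugs:
        t, r = tables[d], responses[d]
        if r.transform != "none":
            raise ValueError("responses must be untransformed before stacking")
        fp = np.ravel(fingerprints[d]).astype(float)
        for i, s in enumerate(t.sample_ids):
            if s not in set(r.sample_ids):
                continue
            rows.append(np.concatenate([t.values[i], fp]))
            masks.append(np.concatenate([t.missing_mask[i], np.zeros(n_bits, bool)]))
            ids.append(f"{s}__{d}")
            raw_y.append(r.values[r.sample_ids.index(s)])

    all_ids = feature_ids + [f"fp_b{j}" for j in range(n_bits)]
    kinds = np.concatenate([ref.kinds, np.asarray(["FP"] * n_bits, dtype=object)])
    stacked = FeatureTable(
        sample_ids=ids, feature_ids=all_ids, kinds=kinds,
        values=np.vstack(rows), missing_mask=np.vstack(masks),
    )
    y = ResponseVector(ids, apply_transform(np.asarray(raw_y), transform), transform)
    return stacked, y


def drop_constant_features(table: FeatureTable) -> FeatureTable:
    """Remove zero-variance columns (e.g. constant fingerprint bits after
    stacking a single drug), with a logged warning."""
    with np.errstate(invalid="ignore"):
        std = np.nanstd(table.values, axis=0)
    keep = np.flatnonzero(~(std == 0.0) & ~np.isnan(std))
    n_drop = table.n_features - keep.size
    if n_drop:
        logger.warning("dropping %d zero-variance columns before modeling", n_drop)
    return table.select_features(keep)


def run_combined(
    tables: dict[str, FeatureTable],
    responses: dict[str, ResponseVector],
    fingerprints: dict[str, np.ndarray],
    config: PipelineConfig | None = None,
    head: str = "glm",
    cross_validate: bool = False,
    seed: int | None = None,
) -> PipelineRun:
    """Combined all-drugs path: stack, transform labels, mRMR → boosted
    selection → head.  Missing values created by stacking flow through the
    trees' native routing and the GLM-stage median imputation."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    stacked, y = stack_drugs(
        tables, responses, fingerprints, transform=config.combined_transform
    )
    stacked = drop_constant_features(stacked)
    reports: list[SelectionReport] = []
    timings: dict[str, float] = {}

    def _select(tbl: FeatureTable, yy: ResponseVector, collect: bool):
        m = min(config.mrmr_m, tbl.n_features)
        t0 = time.perf_counter()
        t2, rep2 = mrmr_select(tbl, yy, m=m, bins=config.mi_bins)
        if collect:
            reports.append(rep2)
            timings["mrmr"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        t3, rep3 = select_layer3(
            t2, yy, rounds=config.boost_rounds, max_depth=config.boost_max_depth,
            lam=config.boost_lambda, gamma_penalty=config.boost_gamma,
            shrinkage=config.boost_shrinkage, cap=config.layer3_cap,
        )
        if collect:
            reports.append(rep3)
            timings["boost"] = time.perf_counter() - t0
        return t3

    t3_table = _select(stacked, y, collect=True)
    t0 = time.perf_counter()
    model = _fit_head(t3_table, y, config, head, seed)
    timings["head"] = time.perf_counter() - t0

    cv = None
    if cross_validate:
        if config.selection_in_cv:
            def spec(tr_table, tr_y, te_table):
                sel = _select(tr_table, tr_y, collect=False)
                m = _fit_head(sel, tr_y, config, head, seed)
                return m.predict(te_table)
        else:
            logger.warning(
                "global-selection CV: selection layers saw the held-out folds"
            )
            selected = model.feature_ids

            def spec(tr_table, tr_y, te_table):
                m = _fit_head(
                    tr_table.select_features(selected), tr_y, config, head, seed
                )
                return m.predict(te_table)
        cv = kfold_cv(stacked, y, spec, k=config.cv_folds, seed=seed)

    return PipelineRun(
        path="combined", config=config, reports=reports, model=model,
        cv=cv, seed=seed, stage_timings=timings,
    )
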