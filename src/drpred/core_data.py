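"""Typed data model and delimited-text I/O for the drug-response pipeline.

The pipeline consumes two kinds of inputs: a samples × features matrix of
cell-line descriptors (continuous expression / copy-number values, binary
mutation indicators, binary molecular-fingerprint bits) and a strictly
positive response vector of drug IC50 values.  Feature kind is carried as a
per-column tag so that each selection layer can address the blocks it is
defined on.

Missing values are represented internally by an explicit boolean mask (the
stored value is NaN wherever the mask is set); on disk they are empty cells
or ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("drpred")

KINDS = ("RNA", "CNV", "MUT", "FP")
CONTINUOUS_KINDS = ("RNA", "CNV")
BINARY_KINDS = ("MUT", "FP")

#: default feature-id prefix → kind rule
DEFAULT_KIND_MAP: dict[str, str] = {
    "rna_": "RNA",
    "cnv_": "CNV",
    "mut_": "MUT",
    "fp_": "FP",
}

MISSING_STRINGS = {"", "NA", "NaN", "nan"}


class OptionalDependencyError(ImportError):
    """An optional dependency needed for this operation is not installed."""


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; ``verbose`` enables DEBUG level."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Samples × features matrix with per-feature kind tags and missing mask.

    ``values`` holds NaN wherever ``missing_mask`` is set; the mask is the
    authoritative record of missingness.  MUT and FP entries are validated to
    be exactly 0 or 1 where observed.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    kinds: np.ndarray           # shape (n_features,), entries in KINDS
    values: np.ndarray          # shape (n_samples, n_features), float
    missing_mask: np.ndarray    # same shape, bool

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.feature_ids = list(map(str, self.feature_ids))
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n, g = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != g:
            raise ValueError("id lists do not match value matrix shape")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if self.kinds.shape != (g,):
            raise ValueError("kinds length must equal feature count")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {sorted(dup_s)}")
        dup_f = _duplicates(self.feature_ids)
        if dup_f:
            raise ValueError(f"duplicate feature ids: {sorted(dup_f)}")
        bad_kind = set(self.kinds) - set(KINDS)
        if bad_kind:
            raise ValueError(f"unknown feature kinds: {sorted(bad_kind)}")
        # mask ⇔ NaN
        if not np.array_equal(np.isnan(self.values), self.missing_mask):
            raise ValueError("missing_mask must agree with NaN positions in values")
        # binary kinds hold exactly 0/1 where observed
        bin_cols = np.isin(self.kinds, BINARY_KINDS)
        if bin_cols.any():
            sub = self.values[:, bin_cols]
            obs = ~self.missing_mask[:, bin_cols]
            bad = obs & ~np.isin(sub, (0.0, 1.0))
            if bad.any():
                rows, cols = np.nonzero(bad)
                names = np.asarray(self.feature_ids)[bin_cols][cols]
                coords = [
                    f"({self.sample_ids[r]}, {f})" for r, f in zip(rows, names)
                ]
                raise ValueError(
                    "non-binary values in MUT/FP features "
                    f"{sorted(set(names))} at {coords[:10]}"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def kind_indices(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.kinds == kind)

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    # -- subsetting --------------------------------------------------------
    def select_features(self, which: Sequence[str] | Sequence[int] | np.ndarray) -> "FeatureTable":
        idx = self._feature_locs(which)
        return FeatureTable(
            sample_ids=self.sample_ids,
            feature_ids=[self.feature_ids[i] for i in idx],
            kinds=self.kinds[idx],
            values=self.values[:, idx],
            missing_mask=self.missing_mask[:, idx],
        )

    def select_samples(self, which: Sequence[str] | Sequence[int] | np.ndarray) -> "FeatureTable":
        which = list(which)
        if which and isinstance(which[0], str):
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in which], dtype=int)
        else:
            idx = np.asarray(which, dtype=int)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=self.feature_ids,
            kinds=self.kinds,
            values=self.values[idx],
            missing_mask=self.missing_mask[idx],
        )

    def _feature_locs(self, which) -> np.ndarray:
        which = list(which)
        if which and isinstance(which[0], str):
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            return np.array([pos[f] for f in which], dtype=int)
        return np.asarray(which, dtype=int)

    def block(self, kind: str) -> "FeatureTable":
        """Submatrix of a single feature kind."""
        return self.select_features(self.kind_indices(kind))

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep=sep, na_rep="NA")


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for it in items:
        (dups if it in seen else seen).add(it)
    return dups


def kinds_from_ids(feature_ids: Sequence[str], kind_map: Mapping[str, str] | None = None) -> np.ndarray:
    """Assign a kind to every feature id by longest matching prefix."""
    kind_map = dict(DEFAULT_KIND_MAP if kind_map is None else kind_map)
    prefixes = sorted(kind_map, key=len, reverse=True)
    kinds = []
    unmatched = []
    for fid in feature_ids:
        for p in prefixes:
            if fid.startswith(p):
                kinds.append(kind_map[p])
                break
        else:
            unmatched.append(fid)
    if unmatched:
        raise ValueError(
            f"cannot infer kind for feature ids {unmatched[:10]} "
            f"(known prefixes: {sorted(kind_map)})"
        )
    return np.asarray(kinds, dtype=object)


def read_feature_table(
    path: str | Path,
    kind_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> FeatureTable:
    """Read a delimited feature table (header of feature ids, id column first).

    Empty cells and ``NA`` are recorded in the missing mask.  Feature kinds
    are assigned by id prefix (``rna_``/``cnv_``/``mut_``/``fp_`` by default,
    overridable via ``kind_map``).
    """
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else None,
        engine="python" if sep is None else "c",
        index_col=0,
        na_values=sorted(MISSING_STRINGS),
        keep_default_na=False,
    )
    values = df.to_numpy(dtype=float)
    return FeatureTable(
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        kinds=kinds_from_ids([str(c) for c in df.columns], kind_map),
        values=values,
        missing_mask=np.isnan(values),
    )


# ---------------------------------------------------------------------------
# ResponseVector
# ---------------------------------------------------------------------------

TRANSFORMS = ("none", "log", "log1p")


@dataclass
class ResponseVector:
    """Per-sample drug response (IC50), with the label transform recorded.

    Raw IC50 values must be strictly positive.  ``log`` can yield values ≤ 0
    (IC50 ≤ 1); such a vector is valid for point regression but violates the
    gamma-family support — ``gamma_safe`` reports whether gamma fitting is
    admissible.
    """

    sample_ids: list[str]
    values: np.ndarray
    transform: str = "none"

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length mismatch")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def gamma_safe(self) -> bool:
        """True when all values are strictly positive (gamma support)."""
        return bool(np.all(self.values > 0))

    def select_samples(self, which: Sequence[str] | Sequence[int]) -> "ResponseVector":
        which = list(which)
        if which and isinstance(which[0], str):
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = [pos[s] for s in which]
        else:
            idx = [int(i) for i in which]
        return ResponseVector(
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx],
            transform=self.transform,
        )

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "response": self.values}).to_csv(
            path, sep=sep, index=False
        )


def apply_transform(raw: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return raw.astype(float)
    if transform == "log":
        return np.log(raw)
    if transform == "log1p":
        return np.log1p(raw)
    raise ValueError(f"unknown transform {transform!r}")


def read_response_table(
    path: str | Path, transform: str = "none", sep: str | None = None
) -> ResponseVector:
    """Read a two-column (sample id, IC50) file and apply the label transform.

    Raw IC50 values must be strictly positive; offenders are named in the
    error.  Alignment with a FeatureTable is by sample id (see ``align``).
    """
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else None,
        engine="python" if sep is None else "c",
    )
    if df.shape[1] < 2:
        raise ValueError("response table needs two columns: sample id, value")
    ids = [str(s) for s in df.iloc[:, 0]]
    raw = df.iloc[:, 1].to_numpy(dtype=float)
    bad = [ids[i] for i in np.flatnonzero(~(raw > 0))]
    if bad:
        raise ValueError(f"non-positive IC50 for samples {bad}")
    rv = ResponseVector(ids, apply_transform(raw, transform), transform)
    if not rv.gamma_safe():
        logger.warning(
            "response contains values <= 0 after %r transform; "
            "not admissible for gamma-family fitting", transform
        )
    return rv


def align(table: FeatureTable, response: ResponseVector) -> tuple[FeatureTable, ResponseVector]:
    """Inner join of a feature table and response on sample id.

    Order-insensitive: the result follows the table's sample order restricted
    to the shared ids.
    """
    shared = [s for s in table.sample_ids if s in set(response.sample_ids)]
    if not shared:
        raise ValueError("no shared sample ids between table and response")
    if len(shared) < table.n_samples or len(shared) < response.n:
        logger.warning(
            "alignment keeps %d of %d table / %d response samples",
            len(shared), table.n_samples, response.n,
        )
    return table.select_samples(shared), response.select_samples(shared)


# ---------------------------------------------------------------------------
# SelectionReport
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Record of one selection layer: ordered survivors, drops with reasons."""

    layer: int
    kept: list[str]
    dropped: dict[str, str]               # feature id → reason
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.dropped)
        if overlap:
            raise ValueError(f"features both kept and dropped: {sorted(overlap)}")

    @property
    def input_features(self) -> list[str]:
        return list(self.kept) + list(self.dropped)

    def to_dict(self) -> dict:
        return {
            "layer": self.layer,
            "kept": list(self.kept),
            "dropped": dict(self.dropped),
            "scores": {k: float(v) for k, v in self.scores.items()},
        }


# ---------------------------------------------------------------------------
# PipelineConfig
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every pipeline tunable in one serializable record.

    Defaults follow the method's stated configuration where one exists
    (50% contribution cut, 0.8 correlation threshold, 500 mRMR features,
    third-layer cap 40, ten folds, 95% intervals) and common practice
    elsewhere.
    """

    # layer 1 — contribution screen
    keep_fraction: float = 0.5
    keep_direction: str = "top"           # "top" | "bottom" half of the ranking
    corr_threshold: float = 0.8
    ae_hidden: int | None = None          # None → min(64, G // 4)
    ae_epochs: int = 200
    ae_lr: float = 0.01
    # layer 2 — mRMR
    mi_bins: int | None = None            # None → 10, or 5 when n < 100
    mrmr_m: int = 500
    # layer 3 — boosted selection
    boost_rounds: int = 50
    boost_max_depth: int = 4
    boost_lambda: float = 1.0
    boost_gamma: float = 0.0
    boost_shrinkage: float = 0.3
    layer3_cap: int = 40
    # regression heads
    glm_family: str = "auto"              # "auto" → AIC selection among the three
    glm_link: str = "log"
    glm_max_iter: int = 2000               # small-n fits are near-saturated
    ann_widths: tuple[int, ...] = (1000, 800, 500, 100)
    ann_dropout: float = 0.1
    ann_epochs: int = 200
    ann_batch_size: int = 32
    ann_lr: float = 0.01
    # evaluation
    cv_folds: int = 10
    interval_level: float = 0.95
    selection_in_cv: bool = True
    # misc
    combined_transform: str = "log1p"
    fp_bits: int = 256
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["ann_widths"] = list(d["ann_widths"])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text) or {}
        if "ann_widths" in d:
            d["ann_widths"] = tuple(d["ann_widths"])
        return cls(**d)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Fingerprint encoding (optional dependency)
# ---------------------------------------------------------------------------

def fingerprint_encode(smiles: str, n_bits: int = 256, radius: int = 2) -> np.ndarray:
    """Morgan circular fingerprint of a molecule folded to ``n_bits`` bits.

    Thin interface over RDKit; deterministic for fixed structure and
    settings.  The pipeline remains usable with precomputed FP blocks when
    RDKit is absent.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise OptionalDependencyError(
            "fingerprint_encode requires the optional dependency rdkit"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=float)
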