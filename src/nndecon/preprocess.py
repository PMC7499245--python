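"""Bulk expression preprocessing.

Normalization chain applied to a raw gene × sample expression matrix before
pathway compression: remove unexpressed / non-coding genes, quantile-normalize
samples against a geometric-mean reference distribution, clip extreme values,
log-transform, and rescale every gene row to the unit interval.

The chain is order-dependent; only the final unit scaling is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PreprocessConfig",
    "read_expression",
    "write_expression",
    "filter_genes",
    "quantile_normalize_geomean",
    "clip_quantiles",
    "log_unit_scale",
    "preprocess_pipeline",
]

VALID_STAGES = ("primary", "metastatic")


@dataclass
class ExpressionMatrix:
    """A gene × sample real matrix with per-sample annotations.

    ``values`` has one row per entry of ``gene_ids`` and one column per entry
    of ``sample_ids``.  ``stage`` and ``patient`` are parallel to
    ``sample_ids``; each patient may contribute at most one primary and one
    metastatic sample.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    stage: list = field(default_factory=list)
    patient: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if self.stage:
            bad = set(self.stage) - set(VALID_STAGES)
            if bad:
                raise ValueError(f"invalid stage labels: {sorted(bad)}")
            # at most one primary and one metastatic sample per patient
            seen = set()
            for p, s in zip(self.patient, self.stage):
                if (p, s) in seen:
                    raise ValueError(
                        f"patient {p!r} has more than one {s} sample"
                    )
                seen.add((p, s))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=np.asarray(values, dtype=float))

    def annotation(self) -> dict:
        """sample id → (patient, stage) mapping."""
        return {
            s: (p, st)
            for s, p, st in zip(self.sample_ids, self.patient, self.stage)
        }


@dataclass
class PreprocessConfig:
    """Knobs of the normalization chain.

    clip_low / clip_high are empirical quantiles pooled over all matrix
    entries (set ``clip_scope='gene'`` for per-row clipping);
    ``log_offset`` is the pseudocount added before the base-2 log;
    ``geomean_delta`` is the pseudocount inside the geometric mean so that
    ranks containing zeros stay finite.
    """

    clip_low: float = 0.025
    clip_high: float = 0.975
    log_offset: float = 1.0
    coding_gene_list: set | None = None
    clip_scope: str = "global"  # or "gene"
    geomean_delta: float = 1.0

    def __post_init__(self):
        if not self.clip_low < self.clip_high:
            raise ValueError("clip_low must be < clip_high")


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression(path, annotation_path) -> ExpressionMatrix:
    """Load a TSV/CSV matrix (genes in rows) plus a sample annotation table.

    The annotation table needs columns ``sample_id``, ``patient_id``,
    ``stage``.  Every sample column of the matrix must be annotated.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    dupes = _duplicates(list(df.index))
    if dupes:
        raise ValueError(f"duplicate gene ids in {path}: {sorted(dupes)}")
    ann = pd.read_csv(annotation_path, sep="\t")
    required = {"sample_id", "patient_id", "stage"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation file must have columns {sorted(required)}")
    ann = ann.set_index("sample_id")
    missing = [s for s in df.columns if s not in ann.index]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing}")
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        stage=[ann.loc[s, "stage"] for s in df.columns],
        patient=[ann.loc[s, "patient_id"] for s in df.columns],
    )


def write_expression(E: ExpressionMatrix, path) -> None:
    E.to_frame().to_csv(path, sep="\t", index_label="gene")


def filter_genes(E: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Drop all-zero gene rows and, if configured, non-coding genes."""
    config = config or PreprocessConfig()
    if np.any(E.values < 0):
        raise ValueError("expression values must be non-negative")
    keep = ~np.all(E.values == 0, axis=1)
    if config.coding_gene_list is not None:
        coding = np.array([g in config.coding_gene_list for g in E.gene_ids])
        keep &= coding
    if not keep.any():
        raise ValueError("no genes left after filtering")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(E.gene_ids, keep) if k],
        sample_ids=E.sample_ids,
        values=E.values[keep],
        stage=E.stage,
        patient=E.patient,
    )


def quantile_normalize_geomean(
    E: ExpressionMatrix, delta: float | None = None
) -> ExpressionMatrix:
    """Quantile normalization with a geometric-mean reference distribution.

    The reference value at rank r is the geometric mean, over samples, of each
    sample's r-th smallest value, computed as exp(mean(log(x + δ))) − δ.
    Every column is then replaced by the reference values in its own rank
    order; ties within a column receive the mean of their tied reference
    values.
    """
    if np.any(E.values < 0):
        raise ValueError("quantile normalization requires non-negative values")
    if E.n_samples < 2:
        raise ValueError("need at least 2 samples")
    delta = 1.0 if delta is None else delta
    X = E.values
    ref = np.exp(np.mean(np.log(np.sort(X, axis=0) + delta), axis=1)) - delta
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average reference values over tied entries
        for v in np.unique(col):
            tie = col == v
            if tie.sum() > 1:
                assigned[tie] = assigned[tie].mean()
        out[:, j] = assigned
    return E.with_values(out)


def clip_quantiles(E: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Winsorize extreme entries at the configured quantiles."""
    config = config or PreprocessConfig()
    X = E.values
    if config.clip_scope == "global":
        lo = np.quantile(X, config.clip_low)
        hi = np.quantile(X, config.clip_high)
        return E.with_values(np.clip(X, lo, hi))
    lo = np.quantile(X, config.clip_low, axis=1, keepdims=True)
    hi = np.quantile(X, config.clip_high, axis=1, keepdims=True)
    return E.with_values(np.clip(X, lo, hi))


def log_unit_scale(E: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """log2(x + offset), then map each gene row linearly onto [0, 1].

    Constant rows (no dynamic range) map to 0.5.
    """
    config = config or PreprocessConfig()
    X = E.values + config.log_offset
    if np.any(X <= 0):
        raise ValueError("value + log_offset must be positive for the log step")
    L = np.log2(X)
    lo = L.min(axis=1, keepdims=True)
    hi = L.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (L - lo) / span
    scaled[np.broadcast_to(span == 0, scaled.shape)] = 0.5
    return E.with_values(scaled)


def preprocess_pipeline(E: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Full chain: filter → quantile normalize → clip → log + unit scale."""
    config = config or PreprocessConfig()
    E = filter_genes(E, config)
    E = quantile_normalize_geomean(E, config.geomean_delta)
    E = clip_quantiles(E, config)
    return log_unit_scale(E, config)
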