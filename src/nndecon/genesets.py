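"""Compression of expression into gene-module / cancer-pathway signatures.

Builds the stacked signature matrix B = [B_M; B_P]: the module block B_M is
computed from the top-variance genes, the cancer-pathway block B_P from the
complementary (lower-variance) genes.  Each row is the per-sample sum of
member-gene expression, z-scored across samples.  Modules may be filtered by
fold enrichment (score relative to the geometric mean score of the
collection) before the block is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "GeneSet",
    "PathwayMatrix",
    "default_cancer_pathways",
    "read_gmt",
    "read_ease_scores",
    "select_top_variance_genes",
    "filter_enriched_modules",
    "build_block",
    "assemble_B",
    "write_pathway_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    genes: set
    category: str = "module"  # or "cancer_pathway"
    ease: float | None = None

    def __post_init__(self):
        self.genes = set(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class PathwayMatrix:
    """Stacked z-scored signature matrix: modules first, then pathways."""

    row_names: list
    module_count: int
    pathway_count: int
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.module_count + self.pathway_count:
            raise ValueError("row count must equal module_count + pathway_count")

    @property
    def module_block(self) -> np.ndarray:
        return self.values[: self.module_count]

    @property
    def pathway_block(self) -> np.ndarray:
        return self.values[self.module_count:]

    @property
    def pathway_names(self) -> list:
        return self.row_names[self.module_count:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_names, columns=self.sample_ids)


def default_cancer_pathways() -> list[GeneSet]:
    """The 24 cancer-signaling pathway names shipped with the package.

    The gene membership in the bundled GMT is a synthetic placeholder
    (names only reflect the intended KEGG cancer-pathway panel); replace it
    with curated gene sets for real analyses.
    """
    path = resources.files("nndecon") / "data" / "cancer_pathways_synthetic.gmt"
    return read_gmt(str(path), category="cancer_pathway")


def read_gmt(path, category: str = "module") -> list[GeneSet]:
    """Parse a GMT file: one set per line, name TAB description TAB genes..."""
    sets = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(
                    f"{path} line {lineno}: gene set {name!r} has no genes"
                )
            if name in names:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name=name, genes=set(genes), category=category))
    return sets


def read_ease_scores(path) -> dict:
    """Two-column TSV (set name, EASE-type score) → dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "ease"])
    return dict(zip(df["name"], df["ease"].astype(float)))


def select_top_variance_genes(E: ExpressionMatrix, n_top: int) -> list:
    """The n_top genes with largest across-sample variance.

    Ties are broken by lexicographic gene id so the selection is deterministic
    across platforms.  Returns all genes when n_top exceeds the gene count.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    var = E.values.var(axis=1)
    # sort by (-variance, gene id); stable and platform independent
    order = sorted(range(E.n_genes), key=lambda i: (-var[i], str(E.gene_ids[i])))
    return [E.gene_ids[i] for i in order[:n_top]]


def filter_enriched_modules(sets, threshold: float = 1.0) -> list[GeneSet]:
    """Keep sets whose fold enrichment ≥ threshold.

    Fold enrichment of a set is its EASE-type score divided by the geometric
    mean of scores over the whole collection.
    """
    sets = list(sets)
    for s in sets:
        if s.ease is None or s.ease <= 0:
            raise ValueError(f"gene set {s.name!r} lacks a positive ease score")
    geomean = float(np.exp(np.mean(np.log([s.ease for s in sets]))))
    return [s for s in sets if s.ease / geomean >= threshold]


def build_block(
    E: ExpressionMatrix,
    sets,
    gene_subset=None,
    ddof: int = 0,
    permissive: bool = False,
) -> np.ndarray:
    """Per-set sample sums over (set ∩ gene_subset), z-scored across samples.

    ``ddof=0`` (population std) is the default convention: a two-sample row
    with unequal sums z-scores to exactly (−1, +1).  Zero-variance rows become
    all zeros so row indices stay aligned with set names.  Sets with no member
    gene in the matrix raise, or are returned as zero rows under
    ``permissive=True``.
    """
    gene_idx = {g: i for i, g in enumerate(E.gene_ids)}
    allowed = set(E.gene_ids) if gene_subset is None else set(gene_subset)
    rows = []
    for s in sets:
        members = s.genes & allowed & gene_idx.keys()
        absent = s.genes - gene_idx.keys()
        if absent:
            logger.info("set %s: %d member genes absent from matrix", s.name, len(absent))
        if not members:
            if permissive:
                logger.warning("set %s has no usable genes; zero row emitted", s.name)
                rows.append(np.zeros(E.n_samples))
                continue
            raise ValueError(
                f"gene set {s.name!r} has no member gene in the allowed subset"
            )
        idx = [gene_idx[g] for g in sorted(members)]
        row = E.values[idx].sum(axis=0)
        sd = row.std(ddof=ddof)
        rows.append(np.zeros_like(row) if sd == 0 else (row - row.mean()) / sd)
    return np.vstack(rows)


def assemble_B(
    E: ExpressionMatrix,
    modules,
    pathways,
    n_top: int = 3000,
    ddof: int = 0,
    permissive: bool = False,
) -> PathwayMatrix:
    """Stack the module block (top-variance genes) over the pathway block
    (complement genes) into one z-scored signature matrix."""
    modules, pathways = list(modules), list(pathways)
    if not modules:
        raise ValueError("module collection is empty")
    if not pathways:
        raise ValueError("pathway collection is empty")
    top = select_top_variance_genes(E, n_top)
    complement = [g for g in E.gene_ids if g not in set(top)]
    BM = build_block(E, modules, gene_subset=top, ddof=ddof, permissive=permissive)
    BP = build_block(E, pathways, gene_subset=complement, ddof=ddof, permissive=permissive)
    return PathwayMatrix(
        row_names=[s.name for s in modules] + [s.name for s in pathways],
        module_count=len(modules),
        pathway_count=len(pathways),
        sample_ids=list(E.sample_ids),
        values=np.vstack([BM, BP]),
    )


def write_pathway_matrix(B: PathwayMatrix, path) -> None:
    df = B.to_frame()
    df.insert(0, "block", ["module"] * B.module_count + ["cancer_pathway"] * B.pathway_count)
    df.to_csv(path, sep="\t", index_label="name")
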