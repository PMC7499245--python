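import numpy as np
import pytest

from nndecon import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_expr():
    """6 genes × 4 samples, two patients with matched primary/metastatic."""
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=rng.uniform(0, 10, size=(6, 4)),
        stage=["primary", "metastatic", "primary", "metastatic"],
        patient=["p1", "p1", "p2", "p2"],
    )


def write_expr_files(tmp_path, values, gene_ids, sample_ids, patients, stages):
    """Write a matrix TSV + annotation TSV; return their paths."""
    expr = tmp_path / "expr.tsv"
    lines = ["gene\t" + "\t".join(sample_ids)]
    for g, row in zip(gene_ids, values):
        lines.append(g + "\t" + "\t".join(str(v) for v in row))
    expr.write_text("\n".join(lines) + "\n")
    annot = tmp_path / "annot.tsv"
    rows = ["sample_id\tpatient_id\tstage"]
    for s, p, st in zip(sample_ids, patients, stages):
        rows.append(f"{s}\t{p}\t{st}")
    annot.write_text("\n".join(rows) + "\n")
    return expr, annot
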