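import pytest

from heterotx import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A 400-gene two-trio experiment with ground truth (fixed seed)."""
    cfg = SimConfig(n_genes=400, seed=123)
    eset, truth = simulate(cfg)
    return cfg, eset, truth


@pytest.fixture()
def tiny_counts_files(tmp_path):
    """A 3-gene x 6-sample counts TSV plus a matching one-trio sheet."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene_id\tF1_WW_1\tF1_WW_2\tP1_WW_1\tP1_WW_2\tP2_WW_1\tP2_WW_2\n"
        "g1\t10\t12\t5\t6\t20\t18\n"
        "g2\t0\t0\t3\t4\t2\t1\n"
        "g3\t7\t8\t7\t9\t6\t8\n")
    sheet = tmp_path / "sheet.tsv"
    sheet.write_text(
        "sample_id\ttrio_id\trole\tcondition\treplicate\n"
        "F1_WW_1\tT\thybrid\tWW\t1\n"
        "F1_WW_2\tT\thybrid\tWW\t2\n"
        "P1_WW_1\tT\tparent1\tWW\t1\n"
        "P1_WW_2\tT\tparent1\tWW\t2\n"
        "P2_WW_1\tT\tparent2\tWW\t1\n"
        "P2_WW_2\tT\tparent2\tWW\t2\n")
    return counts, sheet
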