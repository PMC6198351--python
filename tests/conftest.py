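import warnings

import pytest

from apaswitch.core_io import RunConfig
from apaswitch.synthetic_data import SimulationConfig, simulate_experiment


@pytest.fixture(autouse=True)
def _quiet_annotation_warnings():
    """Nearest-feature and duplicate-length warnings are expected on dense
    synthetic layouts; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_experiment():
    """A 40-gene synthetic experiment shared across read-level tests."""
    cfg = SimulationConfig(n_genes=40, seed=9)
    genome, genes, known, truth, records = simulate_experiment(cfg)
    return cfg, genome, genes, known, truth, records


@pytest.fixture()
def run_config():
    return RunConfig()


def write_gtf_text(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def two_gene_gtf(tmp_path):
    """Hand-constructed two-gene GTF: a plus-strand gene whose CDS ends at
    1,000 with a 300-nt 3'UTR, and a minus-strand gene whose CDS starts
    (genomically) at 2,000 with UTR3 = [1700, 2000)."""
    attrs_a = 'gene_id "gA"; gene_biotype "protein_coding";'
    tx_a = 'gene_id "gA"; transcript_id "gA.t1";'
    attrs_b = 'gene_id "gB"; gene_biotype "protein_coding";'
    tx_b = 'gene_id "gB"; transcript_id "gB.t1";'
    lines = [
        f"chr1\ttest\tgene\t701\t1300\t.\t+\t.\t{attrs_a}",
        f"chr1\ttest\ttranscript\t701\t1300\t.\t+\t.\t{tx_a}",
        f"chr1\ttest\texon\t701\t1300\t.\t+\t.\t{tx_a}",
        f"chr1\ttest\tCDS\t701\t1000\t.\t+\t0\t{tx_a}",
        f"chr1\ttest\tgene\t1701\t2300\t.\t-\t.\t{attrs_b}",
        f"chr1\ttest\ttranscript\t1701\t2300\t.\t-\t.\t{tx_b}",
        f"chr1\ttest\texon\t1701\t2300\t.\t-\t.\t{tx_b}",
        f"chr1\ttest\tCDS\t2001\t2300\t.\t-\t0\t{tx_b}",
    ]
    return write_gtf_text(tmp_path / "genes.gtf", lines)
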