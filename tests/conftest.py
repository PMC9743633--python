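import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from archintro import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed-effect synthetic study shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_case=30, n_control=30, n_normal=15,
                           n_genes=12, gene_length_bp=20_000,
                           somatic_rate_modern=1.5e-5, intro_freq=0.3)
    return simulate_cohort(cfg)


def write_vcf(path: Path, body: str) -> Path:
    """Write a minimal single-FORMAT VCF fixture from a body of data lines."""
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1>\n"
        "##contig=<ID=chr2>\n"
        "##contig=<ID=chrX>\n"
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic site">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=SM,Number=1,Type=String,Description="Somatic flags">\n'
    )
    path.write_text(header + body)
    return path
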