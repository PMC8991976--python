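"""Shared fixtures: small simulated genotype panels and traits."""

import numpy as np
import pytest

import g2pbench as g
from g2pbench.genotype_io import GenotypeCall, GenotypeTable, SNPRecord


@pytest.fixture(scope="session")
def small_genome():
    return g.simulate_genome_map(2, 60, 5_000_000, seed=11)


@pytest.fixture(scope="session")
def small_table(small_genome):
    cfg = g.SimConfig(
        n_lines=300,
        maf_range=(0.15, 0.5),
        ld_block_span_bp=250_000,
        within_block_correlation=0.85,
        missing_rate=0.005,
        seed=12,
    )
    return g.simulate_genotypes(small_genome, cfg)


@pytest.fixture(scope="session")
def monogenic_trait(small_table):
    """Degenerate-penetrance codominant trait: perfectly predictable from its SNP."""
    causal = small_table.snps[30].id
    return g.TraitModel(
        "monogenic-categorical",
        [causal],
        penetrance=g.codominant_penetrance(),
        n_classes=3,
        name="flower_colour",
    )


@pytest.fixture(scope="session")
def monogenic_pheno(small_table, monogenic_trait):
    return g.simulate_categorical_trait(small_table, monogenic_trait, seed=13)


def make_table(calls, chrom="chr1", positions=None, line_prefix="L"):
    """Small literal GenotypeTable from an int array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    positions = positions or [1000 * (j + 1) for j in range(m)]
    snps = [SNPRecord(chrom, positions[j], f"s{j}", "A", "T") for j in range(m)]
    return GenotypeTable([f"{line_prefix}{i}" for i in range(n)], snps, calls)


@pytest.fixture
def tiny_table():
    R, H, A, M = (
        GenotypeCall.REF_HOM,
        GenotypeCall.HET,
        GenotypeCall.ALT_HOM,
        GenotypeCall.MISSING,
    )
    return make_table(
        [
            [R, H, A],
            [H, H, M],
            [A, H, R],
        ]
    )
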