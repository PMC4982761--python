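import numpy as np
import pytest

import readthru as rt


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down experiment used by cross-module integration tests."""
    return rt.SimulationConfig(
        n_genes=30, depth=3e5, chrom_length=1_000_000, seed=7
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    models, truth = rt.simulate_annotation(small_cfg)
    libs = [
        rt.simulate_library(models, truth, cond, rep, small_cfg)
        for cond in small_cfg.conditions
        for rep in (1, 2)
    ]
    return models, truth, libs


def mirror_models(models, genome_length):
    """Reflect every gene around the genome midpoint and flip strands."""
    out = []
    for m in models:
        exons = [(genome_length - e.end, genome_length - e.start) for e in m.exons]
        strand = "-" if m.span.strand == "+" else "+"
        out.append(rt.GeneModel.from_exons(m.gene_id, m.span.chrom, strand, exons))
    return out


def mirror_coverage(cov, genome_length):
    tags = {
        (chrom, "-" if s == "+" else "+"): genome_length - 1 - pos
        for (chrom, s), pos in cov.tags.items()
    }
    return rt.StrandedCoverage(cov.condition, cov.replicate, cov.library_size, tags)


def brute_force_count(positions, start, end):
    """Per-tag loop oracle for half-open interval counting."""
    return sum(1 for p in positions if start <= p < end)


@pytest.fixture(scope="session")
def mirror_helpers():
    return mirror_models, mirror_coverage
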