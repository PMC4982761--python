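import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import readthru as rt
from readthru.synthetic_data import ChipEnrichmentSpec, simulate_chip_track


def _single_gene_truth(fpkm, rho_ctrl, rho_pert, length=1000):
    model = rt.GeneModel.from_exons("g0", "chrS", "+", [(10_000, 10_000 + length)])
    truth = pd.DataFrame(
        {
            "gene_id": ["g0"], "tier": ["Low"], "body_length": [length],
            "fpkm_control": [fpkm], "fpkm_perturbed": [fpkm],
            "rho_control": [rho_ctrl], "rho_perturbed": [rho_pert],
            "affected": [rho_ctrl != rho_pert], "close_packed": [False],
            "neighbor_id": [""],
        }
    )
    return [model], truth


def test_annotation_determinism_and_empty():
    cfg = rt.SimulationConfig(n_genes=25, depth=1e5, chrom_length=900_000, seed=7)
    m1, t1 = rt.simulate_annotation(cfg)
    m2, t2 = rt.simulate_annotation(cfg)
    assert [m.span for m in m1] == [m.span for m in m2]
    pd.testing.assert_frame_equal(t1, t2)
    m0, t0 = rt.simulate_annotation(
        rt.SimulationConfig(n_genes=0, chrom_length=10_000)
    )
    assert m0 == [] and len(t0) == 0


def test_library_determinism():
    cfg = rt.SimulationConfig(n_genes=20, depth=1e5, chrom_length=700_000, seed=9)
    models, truth = rt.simulate_annotation(cfg)
    a = rt.simulate_library(models, truth, "control", 1, cfg)
    b = rt.simulate_library(models, truth, "control", 1, cfg)
    c = rt.simulate_library(models, truth, "control", 2, cfg)
    assert a.library_size == b.library_size
    for key in a.tags:
        assert np.array_equal(a.tags[key], b.tags[key])
    assert any(
        not np.array_equal(a.tags[k], c.tags.get(k, np.empty(0))) for k in a.tags
    )


def test_closely_spaced_constructive_guarantee():
    cfg = rt.SimulationConfig(
        n_genes=20, fraction_closely_spaced=1.0, depth=1e5,
        chrom_length=600_000, seed=2,
    )
    models, truth = rt.simulate_annotation(cfg)
    by_id = {m.gene_id: m for m in models}
    # every gene except the chromosome-terminal one is flagged
    assert truth["close_packed"].sum() == cfg.n_genes - 1
    for _, row in truth[truth["close_packed"]].iterrows():
        g = by_id[row["gene_id"]]
        nbr = by_id[row["neighbor_id"]]
        assert nbr.span.strand == g.span.strand
        w = rt.downstream_window(g, 5000)
        assert nbr.span.start < w.end and nbr.span.end > w.start


def test_fragment_count_poisson_mean():
    # expected count = FPKM * length_kb * depth/1e6 = 10 * 1 * 1 = 10
    cfg = rt.SimulationConfig(n_genes=1, depth=1e6, chrom_length=50_000, seed=0)
    models, truth = _single_gene_truth(10.0, 0.0, 0.0)
    counts = [
        rt.simulate_library(models, truth, "control", rep, cfg).n_tags
        for rep in range(1, 201)
    ]
    mean = np.mean(counts)
    se = np.sqrt(10.0 / 200)
    assert abs(mean - 10.0) < 3 * se


def test_zero_rho_places_no_tags_past_tts():
    cfg = rt.SimulationConfig(
        n_genes=15, rho0=0.0, fraction_closely_spaced=0.0,
        depth=5e5, chrom_length=600_000, seed=4,
    )
    models, truth = rt.simulate_annotation(cfg)
    cov = rt.simulate_library(models, truth, "perturbed", 1, cfg)
    q = rt.quantify_all(models, [cov], window_bp=5000)
    assert (q["rt_count"] == 0).all()


def test_past_tts_fraction_matches_closed_form():
    L, D, rho = 1000, 5000, 0.5
    g = rt.expected_past_tts_fraction(L, D)
    # independent numeric oracle for E[E/(L+E)], E ~ U(0, D]
    oracle, _ = integrate.quad(lambda e: (e / (L + e)) / D, 0, D)
    assert abs(g - oracle) < 1e-10

    cfg = rt.SimulationConfig(n_genes=1, depth=1e6, chrom_length=50_000, seed=0)
    models, truth = _single_gene_truth(1000.0, rho, rho, length=L)
    fracs = []
    for rep in range(1, 201):
        cov = rt.simulate_library(models, truth, "control", rep, cfg)
        q = rt.quantify_gene(models[0], cov, window_bp=D)
        fracs.append(q.rt_count / (q.rt_count + q.body_count))
    mean, se = np.mean(fracs), np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert abs(mean - rho * g) < 3 * se


def test_rho_fold_monotonicity():
    base = dict(n_genes=40, depth=1e6, chrom_length=1_200_000, seed=6)
    lo = rt.SimulationConfig(rho_fold=1.5, **base)
    hi = rt.SimulationConfig(rho_fold=3.0, **base)
    m_lo, t_lo = rt.simulate_annotation(lo)
    m_hi, t_hi = rt.simulate_annotation(hi)
    aff = t_lo["affected"]
    assert (t_hi.loc[aff, "rho_perturbed"] > t_lo.loc[aff, "rho_perturbed"]).all()
    assert (t_hi.loc[~aff, "rho_perturbed"] == t_lo.loc[~aff, "rho_perturbed"]).all()
    q_lo = rt.quantify_all(m_lo, [rt.simulate_library(m_lo, t_lo, "perturbed", 1, lo)])
    q_hi = rt.quantify_all(m_hi, [rt.simulate_library(m_hi, t_hi, "perturbed", 1, hi)])
    aff_ids = set(t_lo.loc[aff & (t_lo.tier != "No"), "gene_id"])
    s_lo = q_lo[q_lo.gene_id.isin(aff_ids)]["rt_count"].sum()
    s_hi = q_hi[q_hi.gene_id.isin(aff_ids)]["rt_count"].sum()
    assert s_hi > s_lo


def test_fragment_conservation(small_sim):
    _, _, libs = small_sim
    for cov in libs:
        assert cov.library_size == cov.n_tags


def test_infeasible_packing_raises():
    with pytest.raises(ValueError, match="chrom_length"):
        rt.simulate_annotation(
            rt.SimulationConfig(n_genes=100, chrom_length=50_000)
        )


def test_multi_exon_bodies_respect_exons():
    cfg = rt.SimulationConfig(
        n_genes=10, n_exons=3, rho0=0.0, fraction_closely_spaced=0.0,
        depth=5e5, chrom_length=500_000, seed=5,
    )
    models, truth = rt.simulate_annotation(cfg)
    cov = rt.simulate_library(models, truth, "control", 1, cfg)
    for m in models:
        exonic = sum(cov.count(m.span.chrom, m.span.strand, e.start, e.end)
                     for e in m.exons)
        span = cov.count(m.span.chrom, m.span.strand, m.span.start, m.span.end)
        assert exonic == span  # no tag falls in an intron


def test_chip_track_empty_and_deterministic():
    cfg = rt.SimulationConfig(n_genes=5, depth=1e4, chrom_length=200_000, seed=3)
    models, truth = rt.simulate_annotation(cfg)
    empty = simulate_chip_track(
        models, truth, ChipEnrichmentSpec(background_per_bp=0.0), 200_000, seed=1
    )
    assert empty.n_tags == 0
    spec = ChipEnrichmentSpec(background_per_bp=0.001, tss_height=0.5, tss_sigma=100)
    a = simulate_chip_track(models, truth, spec, 200_000, seed=1)
    b = simulate_chip_track(models, truth, spec, 200_000, seed=1)
    assert np.array_equal(a.positions("chrS", "+"), b.positions("chrS", "+"))
    with pytest.raises(ValueError):
        ChipEnrichmentSpec(tss_height=-1.0)


def test_chip_kernel_peaks_at_tss():
    cfg = rt.SimulationConfig(n_genes=5, depth=1e4, chrom_length=200_000, seed=3)
    models, truth = rt.simulate_annotation(cfg)
    expressed = truth.loc[truth.fpkm_control >= 10, "gene_id"]
    gene = next(m for m in models if m.gene_id in set(expressed))
    spec = ChipEnrichmentSpec(background_per_bp=0.0, tss_height=0.3, tss_sigma=100)
    hist = np.zeros(40)  # 40 x 50-bp bins centred on the TSS
    lo = gene.tss - 1000
    for seed in range(100):
        cov = simulate_chip_track(models, truth, spec, 200_000, seed=seed)
        pos = cov.positions("chrS", "+")
        sel = pos[(pos >= lo) & (pos < gene.tss + 1000)]
        hist += np.bincount((sel - lo) // 50, minlength=40)[:40]
    assert abs(int(np.argmax(hist)) - 20) <= 2
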