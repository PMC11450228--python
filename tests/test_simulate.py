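"""Generator correctness: coordinates, Hardy-Weinberg, planted structure."""

import numpy as np
import pytest
from scipy import stats

from fibreggp import (
    differential_expression,
    select_de_genes,
    simulate_annotation,
    simulate_coexpression,
    simulate_genotypes,
    simulate_phenotypes,
)
from fibreggp.simulate import SimulationTruth


class TestAnnotation:
    def test_degenerate_ranges_force_coordinates(self):
        ann = simulate_annotation(1, 1, gene_length_range=(1000, 1000),
                                  gap_range=(0, 0), seed=1)
        rec = ann.genes.iloc[0]
        assert (rec.start, rec.end) == (1, 1000)

    def test_seed_determinism(self):
        a = simulate_annotation(10, 2, seed=7)
        b = simulate_annotation(10, 2, seed=7)
        assert a.genes.equals(b.genes)

    def test_no_overlaps_by_interval_scan(self):
        ann = simulate_annotation(100, 2, gap_range=(500, 10_000), seed=3)
        for _, chrom_genes in ann.genes.groupby("chrom"):
            rows = chrom_genes.sort_values("start")[["start", "end"]].to_numpy()
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    # intervals [s1,e1], [s2,e2] must be disjoint
                    assert rows[i, 1] < rows[j, 0] or rows[j, 1] < rows[i, 0]

    @pytest.mark.parametrize("kwargs", [
        dict(n_genes=0), dict(gene_length_range=(0, 10)),
        dict(gene_length_range=(50, 10)), dict(gap_range=(-1, 5)),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            simulate_annotation(**{"n_genes": 5, "seed": 0, **kwargs})


class TestGenotypes:
    def test_symmetry_at_maf_half(self):
        ann = simulate_annotation(5, 1, seed=2)
        panel = simulate_genotypes(ann, 10_000, maf_range=(0.5, 0.5), seed=2)
        assert np.abs(panel.matrix.mean(axis=0)).max() < 0.05

    def test_allele_frequency_matches_drawn_maf(self):
        ann = simulate_annotation(10, 1, seed=4)
        panel = simulate_genotypes(ann, 5_000, seed=4)
        freq_hat = (panel.matrix.mean(axis=0) + 1.0) / 2.0
        assert np.abs(freq_hat - panel.maf).max() < 0.03

    def test_seed_determinism_bit_identical(self, annotation):
        a = simulate_genotypes(annotation, 50, seed=11)
        b = simulate_genotypes(annotation, 50, seed=11)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.snp_ids == b.snp_ids and np.array_equal(a.snp_pos, b.snp_pos)

    def test_maf_outside_range_rejected(self, annotation):
        with pytest.raises(ValueError):
            simulate_genotypes(annotation, 10, maf_range=(0.0, 0.5), seed=0)
        with pytest.raises(ValueError):
            simulate_genotypes(annotation, 10, maf_range=(0.1, 0.6), seed=0)

    def test_missingness_masked_and_codes_legal(self, annotation):
        panel = simulate_genotypes(annotation, 40, missing_rate=0.1, seed=12)
        assert 0.0 < panel.missing.mean() < 0.2
        assert np.isin(panel.matrix, (-1, 0, 1)).all()
        imputed = panel.imputed()
        assert np.isfinite(imputed).all()


class TestCoexpression:
    def test_no_planted_signal_gives_empty_truth(self, annotation):
        _, truth = simulate_coexpression(annotation, 2, 5, de_fraction=0.0,
                                         lfc_magnitude=0.0, seed=3)
        assert all(not v for v in truth.de_lfc.values())

    def test_within_module_correlation_exceeds_between(self):
        ann = simulate_annotation(150, 1, seed=11)
        expr, truth = simulate_coexpression(ann, n_modules=5, module_size=20,
                                            dispersion=0.05, seed=11)
        log = np.log2(expr.counts + 1.0)
        corr = np.corrcoef(log)
        gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
        module = np.full(len(expr.gene_ids), -1)
        for g, m in truth.module_of.items():
            module[gene_index[g]] = m
        within, between = [], []
        idx = np.flatnonzero(module >= 0)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                (within if module[i] == module[j] else between).append(abs(corr[i, j]))
        assert np.mean(within) > np.mean(between)

    def test_planted_de_recovered_by_de_analysis(self, expr_truth):
        expr, truth = expr_truth
        table = differential_expression(expr, 7, 25)
        hits = set(select_de_genes(table)["gene_id"])
        planted = truth.de_genes(7, 25)
        assert planted, "fixture should plant DE genes"
        sensitivity = sum(g in hits for g in planted) / len(planted)
        assert sensitivity >= 0.8

    def test_replication_required(self, annotation):
        with pytest.raises(ValueError):
            simulate_coexpression(annotation, 2, 5, n_reps=1, seed=0)

    def test_averaged_layout_has_two_reps_per_stage(self, annotation):
        expr, _ = simulate_coexpression(annotation, 2, 5, n_reps=4,
                                        replicate_layout="averaged", seed=5)
        for stage in np.unique(expr.stage):
            assert (expr.stage == stage).sum() == 2


class TestPhenotypes:
    def test_vanishing_h2_decouples_genotype(self, panel):
        truth = SimulationTruth()
        causal = panel.snp_ids[:10]
        pheno = simulate_phenotypes(panel, truth, causal, h2=1e-6, seed=1)
        x = panel.imputed()
        beta = np.array([truth.causal_effects.get(s, 0.0) for s in panel.snp_ids])
        r = stats.pearsonr(x @ beta, pheno["value"]).statistic
        assert abs(r) < 0.1

    def test_realized_h2_near_target(self):
        ann = simulate_annotation(60, 1, seed=21)
        panel = simulate_genotypes(ann, 2_000, seed=21)
        truth = SimulationTruth()
        causal = panel.snp_ids[::4][:30]
        pheno = simulate_phenotypes(panel, truth, causal, h2=0.5, seed=22)
        x = panel.imputed()
        beta = np.array([truth.causal_effects.get(s, 0.0) for s in panel.snp_ids])
        realized = (x @ beta).var() / pheno["value"].var()
        assert abs(realized - 0.5) < 0.05

    def test_no_year_effect_gives_unit_f_on_average(self):
        ann = simulate_annotation(20, 1, seed=31)
        panel = simulate_genotypes(ann, 200, seed=31)
        fstats = []
        for seed in range(50):
            truth = SimulationTruth()
            pheno = simulate_phenotypes(panel, truth, panel.snp_ids[:5], h2=0.3,
                                        sigma_year=0.0, sigma_exp=0.0, seed=seed)
            groups = [g["value"].to_numpy() for _, g in pheno.groupby("year")]
            fstats.append(stats.f_oneway(*groups).statistic)
        assert abs(np.mean(fstats) - 1.0) < 0.25

    def test_variance_decomposition_accounts_for_total(self):
        ann = simulate_annotation(60, 1, seed=41)
        panel = simulate_genotypes(ann, 2_500, seed=41)
        truth = SimulationTruth()
        pheno = simulate_phenotypes(panel, truth, panel.snp_ids[:20], h2=0.4,
                                    sigma_year=1.0, sigma_exp=0.5, seed=42)
        x = panel.imputed()
        beta = np.array([truth.causal_effects.get(s, 0.0) for s in panel.snp_ids])
        g = x @ beta
        year = pheno["year"].map(truth.year_effects).to_numpy()
        exper = pheno["experiment"].map(truth.experiment_effects).to_numpy()
        resid = pheno["value"].to_numpy() - g - year - exper
        total = pheno["value"].var()
        parts = g.var() + year.var() + exper.var() + resid.var()
        assert abs(parts - total) / total < 0.05

    def test_empty_causal_set_rejected(self, panel):
        with pytest.raises(ValueError):
            simulate_phenotypes(panel, SimulationTruth(), [], h2=0.5, seed=0)
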