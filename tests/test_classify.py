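"""Coverage loading, drop-ratio scoring, gene calls, contamination estimate."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histone3p import (
    ClassifierConfig,
    CoverageSet,
    FractionCoverage,
    SimulationConfig,
    classify_genes,
    coverage_set_from_arrays,
    estimate_contamination,
    load_coverage,
    score_site,
    simulate_inputs,
)
from histone3p.classify import ClassificationError, CoverageError

from _oracles import mean_of_ratios


def _track(values, fraction="pA_minus", phase="S", strand="+",
           library_size=1e6, chrom="chrS"):
    return FractionCoverage(
        fraction=fraction, phase=phase, strand=strand,
        values={chrom: np.asarray(values, dtype=float)},
        library_size=library_size,
    ).scale()


class TestLoadCoverage:
    def _manifest(self, tmp_path, rows):
        df = pd.DataFrame(rows, columns=["file", "fraction", "phase", "strand",
                                         "library_size"])
        p = tmp_path / "manifest.tsv"
        df.to_csv(p, sep="\t", index=False)
        return str(p)

    def test_per_million_scaling(self, tmp_path):
        """'chrS 0 10 4' at library size 2e6 scales to 2.0 over [0, 10)."""
        (tmp_path / "a.bedgraph").write_text("chrS\t0\t10\t4\n")
        cov = load_coverage(self._manifest(
            tmp_path, [("a.bedgraph", "pA_minus", "S", "+", 2e6)]))
        track = cov.require("pA_minus", "S", "+")
        assert np.allclose(track.values["chrS"][:10], 2.0)
        assert track.scaled

    def test_scaling_is_idempotent(self, tmp_path):
        (tmp_path / "a.bedgraph").write_text("chrS\t0\t10\t4\n")
        cov = load_coverage(self._manifest(
            tmp_path, [("a.bedgraph", "pA_minus", "S", "+", 2e6)]))
        track = cov.require("pA_minus", "S", "+").scale()
        assert np.allclose(track.values["chrS"][:10], 2.0)

    def test_library_size_linearity(self, tmp_path):
        (tmp_path / "a.bedgraph").write_text("chrS\t0\t10\t4\n")
        v = {}
        for size in (1e6, 2e6):
            cov = load_coverage(self._manifest(
                tmp_path, [("a.bedgraph", "pA_minus", "S", "+", size)]))
            v[size] = cov.require("pA_minus", "S", "+").values["chrS"][0]
        assert v[1e6] == 2 * v[2e6]

    def test_empty_file_gives_zero_track(self, tmp_path):
        (tmp_path / "a.bedgraph").write_text("")
        cov = load_coverage(self._manifest(
            tmp_path, [("a.bedgraph", "pA_minus", "S", "+", 1e6)]),
            chrom_sizes={"chrS": 50})
        assert not cov.require("pA_minus", "S", "+").values["chrS"].any()

    def test_overlapping_intervals_error_names_interval(self, tmp_path):
        (tmp_path / "a.bedgraph").write_text("chrS\t0\t10\t4\nchrS\t5\t15\t2\n")
        with pytest.raises(CoverageError, match="chrS:5-15"):
            load_coverage(self._manifest(
                tmp_path, [("a.bedgraph", "pA_minus", "S", "+", 1e6)]))

    def test_unknown_chromosome_error(self, tmp_path):
        (tmp_path / "a.bedgraph").write_text("chrX\t0\t10\t4\n")
        with pytest.raises(CoverageError, match="chrX"):
            load_coverage(self._manifest(
                tmp_path, [("a.bedgraph", "pA_minus", "S", "+", 1e6)]),
                chrom_sizes={"chrS": 50})


class TestScoreSite:
    def test_step_track_is_used(self):
        vals = np.concatenate([np.full(100, 10.0), np.zeros(100)])
        s = score_site(_track(vals), "chrS", 100, "+", ClassifierConfig())
        assert s.upstream_mean == 10.0 and s.downstream_mean == 0.0
        assert s.drop_ratio == pytest.approx(10.01 / 0.01)
        assert s.used

    def test_flat_track_not_used(self):
        s = score_site(_track(np.full(200, 10.0)), "chrS", 100, "+",
                       ClassifierConfig())
        assert s.drop_ratio == pytest.approx(1.0)
        assert not s.used

    def test_min_signal_floor_blocks_low_coverage(self):
        vals = np.concatenate([np.full(100, 0.5), np.zeros(100)])
        s = score_site(_track(vals), "chrS", 100, "+", ClassifierConfig())
        assert s.drop_ratio > 5 and not s.used

    def test_minus_strand_flanks_are_mirrored(self):
        vals = np.concatenate([np.zeros(100), np.full(100, 10.0)])
        s = score_site(_track(vals, strand="-"), "chrS", 100, "-",
                       ClassifierConfig())
        assert s.upstream_mean == 10.0 and s.used

    @given(up=st.floats(0, 100), down=st.floats(0, 100),
           thresholds=st.lists(st.floats(1.1, 100), min_size=2, max_size=2))
    @settings(max_examples=50)
    def test_raising_threshold_never_turns_usage_on(self, up, down, thresholds):
        lo, hi = sorted(thresholds)
        vals = np.concatenate([np.full(100, up), np.full(100, down)])
        s_lo = score_site(_track(vals), "chrS", 100, "+",
                          ClassifierConfig(drop_ratio_min=lo))
        s_hi = score_site(_track(vals), "chrS", 100, "+",
                          ClassifierConfig(drop_ratio_min=hi))
        assert not (s_hi.used and not s_lo.used)


@pytest.fixture(scope="module")
def clean():
    cfg = SimulationConfig(n_rd=3, n_ri=3, n_hybrid=3, nb_dispersion=0.0, seed=5)
    return simulate_inputs(cfg)


@pytest.fixture(scope="module")
def rd_clean():
    cfg = SimulationConfig(n_rd=6, n_ri=0, n_hybrid=0, nb_dispersion=0.0,
                           contamination=0.03, seed=2)
    genome, txs, truth, cov = simulate_inputs(cfg)
    calls = classify_genes(txs, genome, cov)
    return cov, calls


class TestGeneCalls:
    def test_planted_classes_recovered(self, clean):
        genome, txs, truth, cov = clean
        calls = {c.gene_id: c for c in classify_genes(txs, genome, cov)}
        for row in truth.itertuples():
            assert calls[row.gene_id].call == row.klass, row.gene_id

    def test_hybrid_has_both_evidence_flags(self, clean):
        genome, txs, truth, cov = clean
        calls = {c.gene_id: c for c in classify_genes(txs, genome, cov)}
        for row in truth.itertuples():
            c = calls[row.gene_id]
            if row.klass == "hybrid":
                assert c.sl_used_S_pAminus and c.pas_used_pAplus
            elif row.klass == "RD":
                assert c.sl_used_S_pAminus and not c.pas_used_pAplus
            else:
                assert c.pas_used_pAplus and not c.sl_used_S_pAminus

    def test_scaling_invariance(self, clean):
        """Multiplying raw coverage and library size by the same constant
        changes no call and no score."""
        genome, txs, truth, cov = clean
        cfg = SimulationConfig(n_rd=3, n_ri=3, n_hybrid=3, nb_dispersion=0.0, seed=5)
        from histone3p import simulate_coverage
        arrays = simulate_coverage(genome, truth, cfg)
        scaled_arrays = {k: 7.0 * v for k, v in arrays.items()}
        sizes = {k: 7.0 * v for k, v in cfg.library_sizes.items()}
        cov2 = coverage_set_from_arrays(scaled_arrays, sizes)
        a = classify_genes(txs, genome, cov)
        b = classify_genes(txs, genome, cov2)
        assert [(c.gene_id, c.call) for c in a] == [(c.gene_id, c.call) for c in b]
        for ca, cb in zip(a, b):
            for sa, sb in zip(ca.scores, cb.scores):
                assert sa.upstream_mean == pytest.approx(sb.upstream_mean)
                assert sa.drop_ratio == pytest.approx(sb.drop_ratio)

    def test_clean_recovery_robust_to_threshold(self, clean):
        genome, txs, truth, cov = clean
        want = dict(zip(truth.gene_id, truth.klass))
        for dr in (2, 50):
            calls = classify_genes(txs, genome, cov,
                                   ClassifierConfig(drop_ratio_min=dr))
            assert all(c.call == want[c.gene_id] for c in calls)

    def test_missing_required_track_raises(self, clean):
        genome, txs, truth, _ = clean
        empty = CoverageSet([])
        with pytest.raises(CoverageError, match="missing coverage track"):
            classify_genes(txs, genome, empty)


class TestContamination:
    def test_noise_free_recovery_is_exact(self, rd_clean):
        cov, calls = rd_clean
        est = estimate_contamination(cov, calls)
        assert est.fraction_hat == pytest.approx(0.03, abs=1e-12)
        assert est.n_genes == 6

    def test_zero_g1_track_gives_zero(self):
        cfg = SimulationConfig(n_rd=4, n_ri=0, n_hybrid=0, nb_dispersion=0.0,
                               contamination=0.0, seed=2)
        genome, txs, truth, cov = simulate_inputs(cfg)
        calls = classify_genes(txs, genome, cov)
        assert estimate_contamination(cov, calls).fraction_hat == 0.0

    def test_median_robust_to_one_aberrant_gene(self, rd_clean):
        """Inflating the G1 signal of a single gene leaves the median intact."""
        cov, calls = rd_clean
        chrom, lo, hi, strand = calls[0].sl_region
        g1 = cov.require("pA_minus", "G1", strand)
        original = g1.values[chrom][lo:hi].copy()
        g1.values[chrom][lo:hi] = 500.0
        try:
            est = estimate_contamination(cov, calls)
            assert est.fraction_hat == pytest.approx(0.03, abs=1e-9)
        finally:
            g1.values[chrom][lo:hi] = original

    def test_too_few_rd_genes_is_an_error(self):
        cfg = SimulationConfig(n_rd=2, n_ri=0, n_hybrid=0, nb_dispersion=0.0, seed=2)
        genome, txs, truth, cov = simulate_inputs(cfg)
        calls = classify_genes(txs, genome, cov)
        with pytest.raises(ClassificationError, match="need >= 3"):
            estimate_contamination(cov, calls)

    def test_noisy_recovery_matches_independent_estimator(self):
        """Negative-binomial noise at planted 3%, 20 RD genes: the median
        estimator lands within sampling error of both the truth and an
        independent mean-of-ratios estimate."""
        cfg = SimulationConfig(n_rd=20, n_ri=0, n_hybrid=0, seed=13)
        genome, txs, truth, cov = simulate_inputs(cfg)
        calls = classify_genes(txs, genome, cov)
        est = estimate_contamination(cov, calls)
        assert est.fraction_hat == pytest.approx(0.03, abs=0.01)
        s = cov.require("pA_minus", "S", "+")  # strand handled per gene below
        s_means, g1_means = [], []
        for c in calls:
            chrom, lo, hi, strand = c.sl_region
            s_means.append(cov.require("pA_minus", "S", strand).mean(chrom, lo, hi))
            g1_means.append(cov.require("pA_minus", "G1", strand).mean(chrom, lo, hi))
        assert est.fraction_hat == pytest.approx(
            mean_of_ratios(s_means, g1_means), abs=0.01)
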