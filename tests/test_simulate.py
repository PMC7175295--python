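"""Generative properties of the bio-panning simulator."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

import biopanml as bp
from biopanml.clonotypes import shannon_entropy
from biopanml.simulate import ConfigurationError, expected_frequencies


class TestRepertoire:
    @pytest.mark.parametrize("fraction,expected", [(0.0, False), (1.0, True)])
    def test_degenerate_binder_fraction(self, fraction, expected):
        cfg = bp.SimulationConfig(n_clonotypes=100, binder_fraction=fraction,
                                  seed=0, read_depth=(100,) * 5)
        truth = bp.simulate_repertoire(cfg)
        assert (truth.table["is_binder"] == expected).all()

    def test_binder_count_within_binomial_band(self):
        # n=1000, p=0.23: the binder count should land inside the central
        # 99% binomial interval 230 +/- 2.576*sqrt(1000*0.23*0.77)
        cfg = bp.SimulationConfig(n_clonotypes=1000, binder_fraction=0.23,
                                  seed=42, read_depth=(100,) * 5)
        truth = bp.simulate_repertoire(cfg)
        count = int(truth.table["is_binder"].sum())
        half = 2.576 * np.sqrt(1000 * 0.23 * 0.77)
        assert 230 - half <= count <= 230 + half

    def test_unique_cdr3s_and_frequency_normalization(self):
        cfg = bp.SimulationConfig(n_clonotypes=500, seed=3,
                                  read_depth=(100,) * 5)
        truth = bp.simulate_repertoire(cfg)
        assert truth.table["cdr3_aa"].is_unique
        assert np.isclose(truth.table["initial_frequency"].sum(), 1.0)
        assert (truth.table["capture_strength"] > 0).all()

    def test_binders_stochastically_stronger(self):
        cfg = bp.SimulationConfig(n_clonotypes=2000, binder_fraction=0.5,
                                  seed=1, read_depth=(100,) * 5)
        t = bp.simulate_repertoire(cfg).table
        assert (t.loc[t.is_binder, "capture_strength"].median()
                > t.loc[~t.is_binder, "capture_strength"].median())

    def test_deterministic_given_seed(self):
        cfg = bp.SimulationConfig(n_clonotypes=100, seed=9,
                                  read_depth=(100,) * 5)
        a = bp.simulate_repertoire(cfg).table
        b = bp.simulate_repertoire(cfg).table
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_distribution_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            bp.SimulationConfig(affinity_law={"name": "cauchy"})
        with pytest.raises(ConfigurationError):
            bp.SimulationConfig(binder_fraction=1.5)
        with pytest.raises(ConfigurationError):
            bp.SimulationConfig(wash_stringency=(0, 1), read_depth=(10,) * 5)


class TestPanning:
    def test_two_clonotype_tilt_normalization(self):
        # p=[0.5,0.5], s=[1.0,0.5], w=1 -> expected p'=[2/3,1/3]
        table = pd.DataFrame({
            "chain": "H", "cdr3_aa": ["AAAA", "CCCC"],
            "is_binder": [True, False],
            "capture_strength": [1.0, 0.5],
            "initial_frequency": [0.5, 0.5],
        })
        truth = bp.SimulationTruth(table)
        cfg = bp.SimulationConfig(n_clonotypes=2, seed=0,
                                  wash_stringency=(0.0, 1.0),
                                  read_depth=(100, 100))
        exp = expected_frequencies(truth, cfg)
        assert np.allclose(exp["p1"], [2 / 3, 1 / 3])

    def test_counts_sum_to_read_depth(self, small_campaign):
        cfg, truth, counts = small_campaign
        for r, depth in enumerate(cfg.read_depth):
            assert counts[f"r{r}"].sum() == depth

    def test_neutral_selection_keeps_expected_frequencies(self):
        # with all w_r = 0 the per-round frequency is an unbiased estimate
        # of the initial frequency: average over 100 seeds
        base = dict(n_clonotypes=20, binder_fraction=0.2,
                    wash_stringency=(0.0,) * 5, read_depth=(2000,) * 5)
        cfg0 = bp.SimulationConfig(seed=0, **base)
        truth = bp.simulate_repertoire(cfg0)
        freqs = []
        for seed in range(100):
            cfg = bp.SimulationConfig(seed=seed, **base)
            counts = bp.simulate_panning(truth, cfg)
            freqs.append(counts["r4"].to_numpy() / cfg.read_depth[4])
        mean_freq = np.mean(freqs, axis=0)
        init = truth.table["initial_frequency"].to_numpy()
        assert np.allclose(mean_freq, init, atol=4 * np.sqrt(init / 2000 / 100))

    def test_binder_frequency_increases_under_strong_selection(self):
        # strong selection (w=2, binders ~10x stronger): the mean binder
        # frequency strictly increases over rounds, averaged over 100 seeds
        base = dict(n_clonotypes=50, binder_fraction=0.3,
                    wash_stringency=(0.0, 2.0, 2.0, 2.0, 2.0),
                    read_depth=(2000,) * 5)
        shares = np.zeros(5)
        for seed in range(100):
            cfg = bp.SimulationConfig(seed=seed, **base)
            truth = bp.simulate_repertoire(cfg)
            counts = bp.simulate_panning(truth, cfg)
            binder = truth.table["is_binder"].to_numpy()
            for r in range(5):
                shares[r] += counts.loc[binder, f"r{r}"].sum() / 2000
        shares /= 100
        assert np.all(np.diff(shares) > 0)

    def test_entropy_of_expected_frequencies_falls_with_enrichment(self):
        # Repeated tilting toward the same capture strengths concentrates
        # the distribution, so diversity falls overall and strictly once
        # enrichment dominates. (A single weak tilt can transiently raise
        # entropy when the initially dominant clones happen to be weak
        # binders, so strict per-step monotonicity is not asserted.)
        cfg = bp.SimulationConfig(n_clonotypes=200, seed=5,
                                  read_depth=(1000,) * 5)
        truth = bp.simulate_repertoire(cfg)
        exp = expected_frequencies(truth, cfg)
        ent = [shannon_entropy(exp[f"p{r}"].to_numpy()) for r in range(5)]
        assert ent[-1] < ent[0]
        assert all(a > b for a, b in zip(ent[1:], ent[2:]))

    def test_deterministic_given_seed(self, small_campaign):
        cfg, truth, counts = small_campaign
        again = bp.simulate_panning(truth, cfg)
        pd.testing.assert_frame_equal(counts, again)


class TestReads:
    def test_noiseless_round_trip_recovers_cdr3_multiset(self, small_campaign):
        cfg, truth, counts = small_campaign
        reads = bp.simulate_reads(truth, counts, cfg)
        fcfg = bp.default_filter_config("H")
        for r in range(5):
            got, stats = bp.filter_and_extract(reads[r], fcfg)
            want = Counter({c: int(n) for c, n in
                            zip(counts["cdr3_aa"], counts[f"r{r}"]) if n > 0})
            assert Counter(got) == want
            assert stats.passed == cfg.read_depth[r]

    def test_read_multiplicities_match_counts(self):
        cfg = bp.SimulationConfig(n_clonotypes=1, binder_fraction=0.0, seed=0,
                                  read_depth=(3, 0, 2),
                                  wash_stringency=(0.0, 0.0, 0.0),
                                  read_error_rate=0.0)
        truth = bp.simulate_repertoire(cfg)
        counts = pd.DataFrame({"cdr3_aa": truth.table["cdr3_aa"], "chain": "H",
                               "r0": [3], "r1": [0], "r2": [2]})
        reads = bp.simulate_reads(truth, counts, cfg)
        assert [len(reads[r]) for r in range(3)] == [3, 0, 2]

    def test_extraction_failure_rate_bounded_at_low_error_rate(self):
        cfg = bp.SimulationConfig(n_clonotypes=100, seed=11,
                                  read_depth=(10000,),
                                  wash_stringency=(0.0,),
                                  read_error_rate=0.001)
        truth = bp.simulate_repertoire(cfg)
        counts = bp.simulate_panning(truth, cfg)
        reads = bp.simulate_reads(truth, counts, cfg)
        _, stats = bp.filter_and_extract(reads[0], bp.default_filter_config("H"))
        assert stats.total == 10000
        assert (stats.total - stats.passed) / stats.total < 0.05

    def test_light_chain_reads_use_light_anchors(self):
        cfg = bp.SimulationConfig(n_clonotypes=20, seed=2, chain="L",
                                  read_depth=(200,), wash_stringency=(0.0,),
                                  read_error_rate=0.0)
        truth = bp.simulate_repertoire(cfg)
        counts = bp.simulate_panning(truth, cfg)
        reads = bp.simulate_reads(truth, counts, cfg)
        got, stats = bp.filter_and_extract(reads[0],
                                           bp.default_filter_config("L"))
        assert stats.passed == 200
        assert set(got) <= set(truth.table["cdr3_aa"])

    def test_byte_identical_fastq_given_seed(self, small_campaign, tmp_path):
        cfg, truth, counts = small_campaign
        from biopanml.simulate import write_reads_fastq

        for name in ("a", "b"):
            reads = bp.simulate_reads(truth, counts, cfg)
            write_reads_fastq(reads, tmp_path / name)
        for r in range(5):
            assert ((tmp_path / "a" / f"round{r}.fastq").read_bytes()
                    == (tmp_path / "b" / f"round{r}.fastq").read_bytes())


class TestElisaSimulation:
    def _paired(self, cfg):
        th, tl = bp.simulate_paired_repertoire(cfg)
        truth = bp.SimulationTruth(
            pd.concat([th.table, tl.table], ignore_index=True))
        clones = [(f"C{i}", h, l) for i, (h, l) in enumerate(
            zip(th.table["cdr3_aa"], tl.table["cdr3_aa"]))]
        return th, truth, clones

    def test_noiseless_binder_ratio_and_background(self):
        cfg = bp.SimulationConfig(n_clonotypes=10, binder_fraction=0.5, seed=4,
                                  read_depth=(100,) * 5)
        th, truth, clones = self._paired(cfg)
        recs = bp.simulate_elisa(clones, truth, noise_sd=0.0, seed=0,
                                 binder_mean=2.0, anti_tag_mean=1.0)
        for rec, binder in zip(recs, th.table["is_binder"]):
            a, b = bp.relative_absorbances(rec)
            if binder:
                assert a == pytest.approx(2.0)
            else:
                assert a == pytest.approx(b)  # non-binder draws the blocked law

    def test_default_noise_recovery_rate(self):
        # with the default separation, reactivity calling recovers >= 95%
        # of true binder labels on 200 clones
        cfg = bp.SimulationConfig(n_clonotypes=200, binder_fraction=0.23,
                                  seed=8, read_depth=(100,) * 5)
        th, truth, clones = self._paired(cfg)
        recs = bp.simulate_elisa(clones, truth, seed=8)
        calls = bp.call_reactive(recs)
        called = np.array([c.label == "AR" for c in calls])
        assert (called == th.table["is_binder"].to_numpy()).mean() >= 0.95

    def test_unknown_clone_rejected(self):
        cfg = bp.SimulationConfig(n_clonotypes=5, seed=0, read_depth=(10,) * 5)
        truth = bp.simulate_repertoire(cfg)
        with pytest.raises(ValueError, match="not in truth"):
            bp.simulate_elisa([("C0", "NOTACDR3", None)], truth)
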