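"""Tests of the synthetic study-data generator: determinism, planted
structure, and agreement between emitted files and their truth tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from evsmallrna._io import read_fasta
from evsmallrna.synthetic import (ConfigError, SimConfig, _nb_draw, simulate_counts,
                                  simulate_ct_table, simulate_reference,
                                  synthesize_reads)


def _all_bytes(directory: Path) -> dict[str, bytes]:
    return {p.name: p.read_bytes() for p in sorted(Path(directory).glob("*"))}


class TestConfig:
    @pytest.mark.parametrize("override", [
        {"class_composition": {"cell": {"miRNA": 0.9}, "ev": {"miRNA": 1.0}}},
        {"adapter": "AGXT"},
        {"classes": (("miRNA", 10, 0, 25),)},
        {"classes": (("miRNA", 10, 25, 18),)},
        {"nb_dispersion": -1.0},
        {"qual_low_prob": 1.5},
    ])
    def test_invalid_configs_rejected(self, override):
        base = SimConfig().to_dict()
        base.update(override)
        with pytest.raises(ConfigError):
            SimConfig.from_dict(base)

    def test_yaml_round_trip(self, tmp_path, small_config):
        path = small_config.to_yaml(tmp_path / "cfg.yaml")
        assert SimConfig.from_yaml(path) == small_config


class TestSimulateReference:
    def test_same_seed_gives_identical_bytes(self, tmp_path, small_config):
        simulate_reference(small_config, tmp_path / "a")
        simulate_reference(small_config, tmp_path / "b")
        assert _all_bytes(tmp_path / "a") == _all_bytes(tmp_path / "b")

    def test_zero_duplicate_rate_means_no_repeats(self, tmp_path, small_config):
        cfg = SimConfig.from_dict({**small_config.to_dict(), "duplicate_rate": 0.0})
        sources, _ = simulate_reference(cfg, tmp_path)
        seqs = [s for path, *_ in sources for _, s in read_fasta(path)]
        assert len(seqs) == len(set(seqs))

    def test_duplicates_planted_verbatim_across_sources(self, tmp_path, small_config):
        sources, features = simulate_reference(small_config, tmp_path)
        beta = [s.upper().replace("U", "T")
                for path, _, src, _ in sources if src == "db_beta"
                for _, s in read_fasta(path)]
        n_expected = round(small_config.duplicate_rate * len(features))
        assert len(beta) == n_expected > 0
        assert set(beta) <= set(features.sequence)

    def test_lengths_respect_class_ranges(self, tmp_path):
        cfg = SimConfig(classes=(("miRNA", 10, 18, 25),),
                        class_composition={"cell": {"miRNA": 1.0}, "ev": {"miRNA": 1.0}},
                        n_features_enriched=0, n_features_depleted=0)
        _, features = simulate_reference(cfg, tmp_path)
        assert len(features) == 10
        assert features.sequence.str.len().between(18, 25).all()
        assert (features.sequence.str.len() == features.length).all()

    def test_some_sequences_exceed_twice_read_length(self, tmp_path):
        cfg = SimConfig(seed=3)
        _, features = simulate_reference(cfg, tmp_path)
        assert (features.length > 2 * cfg.read_length).any()


class TestSimulateCounts:
    def test_poisson_limit_variance_over_mean(self):
        # dispersion -> 0 makes counts Poisson: variance/mean -> 1
        rng = np.random.default_rng(5)
        draws = _nb_draw(rng, np.full(10_000, 50.0), 1e-15)
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.05)
        draws_nb = _nb_draw(rng, np.full(10_000, 50.0), 0.2)
        # NB at alpha=0.2: Var/mean = 1 + alpha*mu = 11
        assert draws_nb.var() / draws_nb.mean() == pytest.approx(11.0, rel=0.15)

    def test_planted_lfc_recovered_in_expectation(self, tmp_path, equal_composition):
        # many replicates, low noise: empirical EV/cell mean of a planted
        # four-fold feature approaches 4 (up to the global renormalization)
        cfg = SimConfig(seed=9, classes=(("miRNA", 50, 18, 25),),
                        class_composition={"cell": {"miRNA": 1.0}, "ev": {"miRNA": 1.0}},
                        n_features_enriched=1, n_features_depleted=0,
                        lfc_magnitude=2.0, nb_dispersion=0.02,
                        n_replicates=100, library_size=10_000, depth_sigma=0.0)
        truth, counts, cond = simulate_counts(cfg, simulate_reference(cfg, tmp_path)[1])
        ev = [s for s, c in cond.items() if c == "ev"]
        cell = [s for s, c in cond.items() if c == "cell"]
        planted = truth[truth.planted].feature_id.iloc[0]
        others = truth[~truth.planted].feature_id
        ratio = counts.loc[planted, ev].mean() / counts.loc[planted, cell].mean()
        bulk = (counts.loc[others, ev].mean(axis=None)
                / counts.loc[others, cell].mean(axis=None))
        assert ratio / bulk == pytest.approx(4.0, rel=0.15)

    def test_unplanted_features_have_zero_true_lfc(self, tmp_path, small_config):
        truth, _, _ = simulate_counts(small_config,
                                      simulate_reference(small_config, tmp_path)[1])
        assert (truth.loc[~truth.planted, "true_log2fc"] == 0).all()
        assert (truth.planted.sum()
                == small_config.n_features_enriched + small_config.n_features_depleted)
        assert (truth.filter(like="expected_mean") >= 0).all().all()


@pytest.fixture(scope="module")
def library(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("reads")
    _, features = simulate_reference(small_config, outdir / "ref")
    truth, counts, cond = simulate_counts(small_config, features)
    fastqs = synthesize_reads(small_config, counts, features, outdir / "fq")
    return small_config, features, counts, fastqs, outdir


class TestSynthesizeReads:
    def test_read_count_conservation(self, library):
        cfg, _, counts, fastqs, _ = library
        for sample, path in fastqs.items():
            n_reads = sum(1 for _ in open(path)) // 4
            assert n_reads == counts[sample].sum()

    def test_determinism_byte_identical_fastq(self, tmp_path, small_config):
        _, features = simulate_reference(small_config, tmp_path / "r")
        _, counts, _ = simulate_counts(small_config, features)
        a = synthesize_reads(small_config, counts, features, tmp_path / "a")
        b = synthesize_reads(small_config, counts, features, tmp_path / "b")
        for sample in a:
            assert Path(a[sample]).read_bytes() == Path(b[sample]).read_bytes()

    def test_reads_match_truth_features(self, library):
        cfg, features, _, fastqs, outdir = library
        seq_of = dict(zip(features.feature_id, features.sequence))
        sample = next(iter(fastqs))
        truth = pd.read_csv(outdir / "fq" / f"{sample}.reads.truth.tsv",
                            sep="\t", comment="#")
        feat_of = dict(zip(truth.read_id, truth.feature_id))
        from evsmallrna.curation import iter_fastq
        checked = 0
        for read_id, seq, qual in iter_fastq(fastqs[sample]):
            feat = seq_of[feat_of[read_id]]
            frag = feat[:cfg.read_length]
            assert seq.startswith(frag[:min(len(frag), len(seq))])
            assert len(seq) == len(qual) <= cfg.read_length
            checked += 1
        assert checked == len(truth)

    def test_adapter_fraction_matches_short_feature_fraction(self, tmp_path,
                                                             equal_composition):
        # without poly-A tails, a read carries adapter sequence exactly when
        # its feature is shorter than the read length
        cfg = SimConfig(seed=21,
                        classes=(("miRNA", 40, 18, 25), ("snoRNA", 20, 60, 100),
                                 ("piRNA", 20, 26, 32)),
                        class_composition=equal_composition,
                        n_features_enriched=0, n_features_depleted=0,
                        polya_prob=0.0, qual_low_prob=0.0, library_size=5_000)
        _, features = simulate_reference(cfg, tmp_path / "r")
        _, counts, _ = simulate_counts(cfg, features)
        fastqs = synthesize_reads(cfg, counts, features, tmp_path / "fq")
        seq_of = dict(zip(features.feature_id, features.sequence))
        from evsmallrna.curation import iter_fastq
        for sample, path in fastqs.items():
            truth = pd.read_csv(tmp_path / "fq" / f"{sample}.reads.truth.tsv",
                                sep="\t", comment="#")
            feat_of = dict(zip(truth.read_id, truth.feature_id))
            n_short = n_with_adapter = 0
            for rid, seq, _ in iter_fastq(path):
                feat = seq_of[feat_of[rid]]
                if len(feat) < cfg.read_length:
                    n_short += 1
                    assert seq == (feat + cfg.adapter)[:cfg.read_length]
                else:
                    assert seq == feat[:cfg.read_length]
                n_with_adapter += seq != feat[:cfg.read_length]
            # reads carry adapter bases exactly when the feature is shorter
            # than the read length
            assert n_with_adapter == n_short > 0

    def test_low_quality_fraction_binomial(self, library):
        cfg, _, counts, fastqs, _ = library
        from evsmallrna.curation import iter_fastq
        n = fail = 0
        for path in fastqs.values():
            for _, _, qual in iter_fastq(path):
                n += 1
                fail += qual[0] == "#"
        p = cfg.qual_low_prob
        sd = (n * p * (1 - p)) ** 0.5
        assert abs(fail - n * p) <= 3 * sd

    def test_emitted_class_composition_within_three_binomial_sd(self, tmp_path):
        # at 1e5 reads/sample and near-Poisson counts, per-class read totals
        # track the configured composition within 3 binomial SD
        cfg = SimConfig(seed=17, nb_dispersion=1e-3, library_size=100_000,
                        n_replicates=1, qual_low_prob=0.0,
                        n_features_enriched=0, n_features_depleted=0)
        _, features = simulate_reference(cfg, tmp_path)
        truth, counts, cond = simulate_counts(cfg, features)
        class_of = dict(zip(features.feature_id, features.rna_class))
        for sample, condition in cond.items():
            by_class = counts[sample].groupby(class_of).sum()
            total = by_class.sum()
            for cls, frac in cfg.class_composition[condition].items():
                sd = (total * frac * (1 - frac)) ** 0.5
                assert abs(by_class.get(cls, 0) - total * frac) <= 3 * sd, \
                    (sample, cls)


class TestSimulateCtTable:
    def test_small_groups_rejected(self):
        with pytest.raises(ConfigError):
            simulate_ct_table(n_per_group=(1, 5))

    def test_zero_shift_zero_expected_group_difference(self):
        t = simulate_ct_table(target_shifts_log2={"miR-X": 0.0}, sigma=0.0,
                              n_per_group=(30, 30), seed=4)
        from evsmallrna.qpcr import aggregate_ct, delta_ct, forty_minus_dct
        dct, _ = delta_ct(aggregate_ct(t), ("miR-20a-5p", "miR-28-5p"))
        rel = forty_minus_dct(dct.dct)
        diff = rel[dct.group == "PCa"].mean() - rel[dct.group == "BPH"].mean()
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_unit_shift_gives_unit_40mdct_difference(self):
        t = simulate_ct_table(target_shifts_log2={"miR-X": 1.0}, sigma=0.0,
                              n_per_group=(10, 10), seed=4)
        from evsmallrna.qpcr import aggregate_ct, delta_ct, forty_minus_dct
        dct, _ = delta_ct(aggregate_ct(t), ("miR-20a-5p", "miR-28-5p"))
        rel = forty_minus_dct(dct.dct)
        diff = rel[dct.group == "PCa"].mean() - rel[dct.group == "BPH"].mean()
        assert diff == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_shift_separates_groups_perfectly(self):
        from evsmallrna.qpcr import aggregate_ct, delta_ct, forty_minus_dct, group_compare
        t = simulate_ct_table(target_shifts_log2={"miR-X": 3.0}, sigma=0.0,
                              n_per_group=(3, 3), seed=8)
        dct, _ = delta_ct(aggregate_ct(t), ("miR-20a-5p", "miR-28-5p"))
        rel = forty_minus_dct(dct.dct.to_numpy())
        res = group_compare(rel, dct.group.to_numpy())
        # complete separation of 3 vs 3: the exact two-sided Mann-Whitney p
        assert res["p"] == pytest.approx(0.1)
        assert min(rel[dct.group.to_numpy() == "PCa"]) > \
            max(rel[dct.group.to_numpy() == "BPH"])

    def test_determinism(self):
        a = simulate_ct_table(target_shifts_log2={"miR-X": 1.0}, seed=3)
        b = simulate_ct_table(target_shifts_log2={"miR-X": 1.0}, seed=3)
        pd.testing.assert_frame_equal(a, b)
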