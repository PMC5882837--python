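"""Generator contracts: determinism, reference invariants, and the count
model's moments and planted structure."""

import numpy as np
import pytest

from mirvar import simulate
from mirvar.simulate import PlantedEffect, SimConfig
from mirvar.variability import covariation_score
from mirvar import normalize as norm


class TestReference:
    def test_default_partition_is_singletons(self, tiny_reference):
        assert len(tiny_reference.clusters) == 3
        assert all(len(v) == 1 for v in tiny_reference.clusters.values())
        assert len(tiny_reference.matures) == 6

    def test_declared_cluster_of_all_three(self):
        cfg = SimConfig(n_hairpins=3, cluster_assignment={0: "c", 1: "c", 2: "c"}, rng_seed=7)
        ref = simulate.make_reference(cfg)
        assert list(ref.clusters) == ["c"]
        assert len(ref.clusters["c"]) == 3

    def test_same_seed_identical_references(self, tiny_config, tiny_reference):
        again = simulate.make_reference(tiny_config)
        assert [h for h in again.hairpins] == [h for h in tiny_reference.hairpins]

    def test_sequences_distinct_and_sized(self, tiny_reference):
        seqs = list(tiny_reference.sequences.values())
        assert len(set(seqs)) == len(seqs)
        assert all(20 <= len(s) <= 24 for s in seqs)

    def test_partner_links_are_mutual(self, tiny_reference):
        for name in tiny_reference.matures:
            partner = tiny_reference.partner_of(name)
            assert partner is not None
            assert tiny_reference.partner_of(partner) == name

    def test_nonpositive_hairpins_rejected(self):
        with pytest.raises(simulate.ConfigurationError):
            SimConfig(n_hairpins=0)

    def test_roundtrip_through_fasta_and_sidecar(self, tiny_reference, tmp_path):
        simulate.write_reference(tiny_reference, tmp_path / "r.fa", tmp_path / "r.tsv")
        back = simulate.read_reference(tmp_path / "r.fa", tmp_path / "r.tsv")
        assert back.sequences == tiny_reference.sequences
        assert back.clusters == tiny_reference.clusters


class TestCounts:
    def test_noise_free_limit_equals_rounded_baseline(self, tiny_reference, tiny_config):
        cfg = SimConfig(
            n_groups=2,
            n_hairpins=3,
            dispersion=0.0,
            depth_multipliers=[1.0] * 12,
            rng_seed=7,
        )
        baselines = simulate.draw_baselines(tiny_reference, cfg)
        cm = simulate.simulate_counts(tiny_reference, cfg, baselines)
        expected = np.rint(baselines.to_numpy())
        assert (cm.counts.to_numpy() == expected[:, None]).all()

    def test_planted_fce_recovered_in_the_mean(self, tiny_reference):
        # law of large numbers over thousands of replicate columns
        target = tiny_reference.matures[0]
        cfg = SimConfig(
            n_groups=2,
            n_replicates=2000,
            n_hairpins=3,
            depth_log_sd=0.0,
            dispersion=0.05,
            planted_effects={target: PlantedEffect(groups=("C-HF",), fce=0.5)},
            rng_seed=7,
        )
        cm = simulate.simulate_counts(tiny_reference, cfg)
        a = cm.counts.loc[target, cm.groups == "C-C"].mean()
        b = cm.counts.loc[target, cm.groups == "C-HF"].mean()
        assert b / a == pytest.approx(0.5, rel=0.05)
        # partner moves identically at attenuation 1 (the default)
        partner = tiny_reference.partner_of(target)
        pa = cm.counts.loc[partner, cm.groups == "C-C"].mean()
        pb = cm.counts.loc[partner, cm.groups == "C-HF"].mean()
        assert pb / pa == pytest.approx(0.5, rel=0.05)

    def test_moments_match_nb_model(self):
        cfg = SimConfig(
            n_groups=1,
            n_replicates=10_000,
            n_hairpins=1,
            baseline_log_mean=np.log(500.0),
            baseline_log_sd=0.0,
            depth_log_sd=0.0,
            dispersion=0.1,
            rng_seed=11,
        )
        ref = simulate.make_reference(cfg)
        cm = simulate.simulate_counts(ref, cfg)
        mu = 500.0
        var = mu + 0.1 * mu * mu
        row = cm.counts.iloc[0].to_numpy()
        assert row.mean() == pytest.approx(mu, rel=0.03)
        assert row.var(ddof=1) == pytest.approx(var, rel=0.1)

    def test_shared_cluster_factor_produces_covariation(self):
        # background hairpins anchor the size factors so normalization
        # cannot absorb the cluster's shared factor
        cfg = SimConfig(
            n_groups=1,
            n_replicates=300,
            n_hairpins=12,
            cluster_assignment={0: "hv", 1: "hv"},
            hypervariable_clusters={"hv": 1.0},
            baseline_log_mean=np.log(300.0),
            depth_log_sd=0.0,
            rng_seed=13,
        )
        ref = simulate.make_reference(cfg)
        cm = norm.normalize(simulate.simulate_counts(ref, cfg), scope="global")
        members = ref.cluster_members("hv")
        score, n_pairs = covariation_score(cm, members, "C-C")
        assert n_pairs == 6
        assert score > 0.9

    def test_seed_fixes_every_byte(self, tiny_config, tiny_reference):
        c1 = simulate.simulate_counts(tiny_reference, tiny_config)
        c2 = simulate.simulate_counts(tiny_reference, tiny_config)
        assert c1.counts.equals(c2.counts)
        other = SimConfig(**{**tiny_config.__dict__, "rng_seed": 8})
        c3 = simulate.simulate_counts(simulate.make_reference(other), other)
        assert not c1.counts.equals(c3.counts)

    def test_unknown_planted_name_rejected(self, tiny_reference):
        cfg = SimConfig(
            n_groups=2,
            n_hairpins=3,
            planted_effects={"nope-5p": PlantedEffect(groups=("C-C",), fce=2.0)},
            rng_seed=7,
        )
        with pytest.raises(simulate.ReferenceError):
            simulate.simulate_counts(tiny_reference, cfg)


class TestReads:
    def test_multiplicity_matches_count_cells(self, tiny_reference, tiny_config):
        cm = simulate.simulate_counts(tiny_reference, tiny_config)
        reads = simulate.simulate_reads(cm, tiny_reference, config=tiny_config)
        lib = cm.counts.columns[0]
        target = tiny_reference.matures[0]
        seq = tiny_reference.sequences[target]
        hits = sum(1 for _, s, _ in reads[lib] if s.startswith(seq))
        assert hits == cm.counts.loc[target, lib]

    def test_no_junk_means_mirna_sized_inserts(self, tiny_reference, tiny_config):
        cm = simulate.simulate_counts(tiny_reference, tiny_config)
        barcodes = simulate.default_barcodes(list(cm.counts.columns))
        reads = simulate.simulate_reads(cm, tiny_reference, barcodes=barcodes, config=tiny_config)
        for lib, recs in reads.items():
            tail = barcodes[lib] + tiny_config.adapter3
            assert all(20 <= len(s) - len(tail) <= 24 for _, s, _ in recs)
            assert all(q == "I" * len(s) for _, s, q in recs)

    def test_junk_fraction_spikes_short_inserts(self, tiny_reference):
        cfg = SimConfig(n_groups=2, n_hairpins=3, junk_fraction=0.2, rng_seed=7)
        cm = simulate.simulate_counts(tiny_reference, cfg)
        barcodes = simulate.default_barcodes(list(cm.counts.columns))
        reads = simulate.simulate_reads(cm, tiny_reference, barcodes=barcodes, config=cfg)
        lib = cm.counts.columns[0]
        tail = barcodes[lib] + cfg.adapter3
        n_total = cm.counts[lib].sum()
        short = sum(1 for _, s, _ in reads[lib] if len(s) - len(tail) < 15)
        assert short == round(0.2 * n_total)

    def test_duplicate_barcodes_rejected(self, tiny_reference, tiny_config):
        cm = simulate.simulate_counts(tiny_reference, tiny_config)
        bad = {lib: "ACGTACGTACG" for lib in cm.counts.columns}
        with pytest.raises(simulate.ConfigurationError):
            simulate.simulate_reads(cm, tiny_reference, barcodes=bad, config=tiny_config)
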