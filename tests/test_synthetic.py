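"""Synthetic benchmark generator: taxonomy, composition, mimicry, pairs."""

import numpy as np
import pytest
from scipy import stats

from siamphage.errors import (ConfigurationError, DataError,
                              SamplingInfeasibleError)
from siamphage.records import RANKS
from siamphage.synthetic import (SyntheticConfig, build_pair_dataset,
                                 generate_dataset, generate_host_genome,
                                 generate_phage_genome, generate_profiles,
                                 generate_taxonomy, kmer_frequency,
                                 nearest_composition_host, read_pair_table,
                                 write_pair_table)


def _cfg(**kw):
    defaults = dict(n_phyla=2, children_per_node=1, hosts_per_genus=1,
                    phages_per_host=1, host_length=3000, phage_length=3000,
                    mimicry_strength=0.9, seed=0)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestTaxonomy:
    def test_one_child_per_node_gives_one_genus_per_phylum(self):
        lineages = generate_taxonomy(_cfg(n_phyla=2, children_per_node=1))
        assert len(lineages) == 2
        for rank in RANKS:
            assert len({l.name_at(rank) for l in lineages}) == 2

    def test_branching_two_gives_sixteen_genera_in_one_phylum(self):
        lineages = generate_taxonomy(_cfg(n_phyla=1, children_per_node=2))
        assert len(lineages) == 16
        assert len({l.phylum for l in lineages}) == 1
        assert len({l.genus for l in lineages}) == 16

    def test_deterministic(self):
        cfg = _cfg(n_phyla=3, children_per_node=2)
        assert generate_taxonomy(cfg) == generate_taxonomy(cfg)

    def test_tree_consistency_no_rank_crossing(self):
        """Two lineages sharing a name at a fine rank share all coarser
        ranks (checked over a branching taxonomy)."""
        lineages = generate_taxonomy(_cfg(n_phyla=2, children_per_node=3))
        for i, a in enumerate(lineages):
            for b in lineages[i + 1:]:
                for fine_idx, rank in enumerate(RANKS[:-1]):
                    if a.name_at(rank) == b.name_at(rank):
                        for coarser in RANKS[fine_idx + 1:]:
                            assert a.name_at(coarser) == b.name_at(coarser)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(n_phyla=0)
        with pytest.raises(ConfigurationError):
            _cfg(mimicry_strength=1.5)


class TestHostGenomes:
    def test_length_and_alphabet(self):
        cfg = _cfg(host_length=2000)
        (lineage,) = generate_taxonomy(_cfg(n_phyla=1))
        profiles = generate_profiles(cfg)
        rec = generate_host_genome(lineage, profiles, cfg, id="h0")
        assert len(rec.sequence) == 2000
        assert set(rec.sequence) <= set("ACGT")
        assert rec.lineage == lineage

    def test_unknown_lineage_rejected(self):
        cfg = _cfg()
        lineages = generate_taxonomy(_cfg(n_phyla=2))
        profiles = generate_profiles(_cfg(n_phyla=1))
        with pytest.raises(DataError):
            generate_host_genome(lineages[1], profiles, cfg, id="h0")

    def test_degenerate_profile_gives_constant_sequence(self):
        from siamphage.synthetic import CompositionProfile
        w = np.zeros(64)
        w[0] = 1.0  # all mass on AAA
        profiles_all_a = {"genX": CompositionProfile(w)}
        lineage = generate_taxonomy(_cfg(n_phyla=1))[0]
        profiles_all_a[lineage.genus] = profiles_all_a.pop("genX")
        rec = generate_host_genome(lineage, profiles_all_a, _cfg(host_length=500),
                                   id="h0")
        assert rec.sequence == "A" * 500

    def test_empirical_3mer_frequency_tracks_profile(self):
        """A 100 kb genome's observed trimer frequencies correlate strongly
        with the generating clade profile."""
        cfg = _cfg(host_length=100_000)
        lineage = generate_taxonomy(cfg)[0]
        profiles = generate_profiles(cfg)
        rec = generate_host_genome(lineage, profiles, cfg, id="h0")
        freq = kmer_frequency(rec.sequence, 3)
        r = np.corrcoef(freq, profiles[lineage.genus].kmer_weights)[0, 1]
        assert r > 0.9

    def test_determinism_given_config(self):
        cfg = _cfg()
        lineage = generate_taxonomy(cfg)[0]
        profiles = generate_profiles(cfg)
        a = generate_host_genome(lineage, profiles, cfg, id="h0")
        b = generate_host_genome(lineage, profiles, cfg, id="h0")
        assert a.sequence == b.sequence


class TestPhageMimicry:
    @staticmethod
    def _phage(mimicry, length, seed=0):
        cfg = _cfg(mimicry_strength=mimicry, host_length=3000,
                   phage_length=length, seed=seed)
        lineage = generate_taxonomy(cfg)[0]
        profiles = generate_profiles(cfg)
        host = generate_host_genome(lineage, profiles, cfg, id="h0")
        return generate_phage_genome(host, profiles, cfg, id="p0"), \
            profiles[lineage.genus], host

    def test_zero_mimicry_is_uniform(self):
        """With no mimicry the phage trimer counts pass a chi-square
        goodness-of-fit test against the uniform distribution."""
        phage, _, _ = self._phage(0.0, 50_000)
        # overlapping k-mers are dependent; count disjoint windows instead
        seq = phage.sequence
        counts = np.zeros(64)
        for i in range(0, len(seq) - 3, 3):
            w = seq[i:i + 3]
            idx = sum("ACGT".index(c) * 4 ** (2 - j) for j, c in enumerate(w))
            counts[idx] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_full_mimicry_matches_host_profile(self):
        phage, profile, _ = self._phage(1.0, 50_000)
        freq = kmer_frequency(phage.sequence, 3)
        r = np.corrcoef(freq, profile.kmer_weights)[0, 1]
        assert r > 0.9

    def test_length_contract_and_ground_truth(self):
        phage, _, host = self._phage(0.5, 1234)
        assert len(phage.sequence) == 1234
        assert phage.true_host_id == host.id
        assert phage.lineage == host.lineage


class TestPairDataset:
    @staticmethod
    def _dataset(n_phyla=3, hosts_per_genus=2, phages_per_host=1, **kw):
        cfg = _cfg(n_phyla=n_phyla, hosts_per_genus=hosts_per_genus,
                   phages_per_host=phages_per_host, host_length=300,
                   phage_length=300, **kw)
        return generate_dataset(cfg)

    def test_one_positive_and_n_negatives_per_phage(self):
        hosts, phages = self._dataset()
        pairs = build_pair_dataset(phages, hosts, negatives_per_positive=1, seed=0)
        positives = [p for p in pairs if p.label == 1]
        negatives = [p for p in pairs if p.label == 0]
        assert len(positives) == len(phages)
        assert len(negatives) == len(phages)

    def test_negatives_exclude_true_host_phylum(self):
        hosts, phages = self._dataset(n_phyla=4, phages_per_host=2)
        pairs = build_pair_dataset(phages, hosts, negatives_per_positive=2, seed=1)
        host_by_id = {h.id: h for h in hosts}
        phage_by_id = {p.id: p for p in phages}
        for pair in pairs:
            if pair.label == 0:
                true_phylum = phage_by_id[pair.phage_id].lineage.phylum
                assert host_by_id[pair.host_id].lineage.phylum != true_phylum

    def test_no_duplicate_pairs(self):
        hosts, phages = self._dataset(n_phyla=4, phages_per_host=2)
        pairs = build_pair_dataset(phages, hosts, negatives_per_positive=3, seed=2)
        assert len({(p.phage_id, p.host_id) for p in pairs}) == len(pairs)

    def test_single_phylum_is_infeasible(self):
        hosts, phages = self._dataset(n_phyla=1)
        with pytest.raises(SamplingInfeasibleError):
            build_pair_dataset(phages, hosts, negatives_per_positive=1, seed=0)

    def test_deterministic_given_seed(self):
        hosts, phages = self._dataset()
        a = build_pair_dataset(phages, hosts, 1, seed=9)
        b = build_pair_dataset(phages, hosts, 1, seed=9)
        assert a == b

    def test_table_round_trip(self, tmp_path):
        hosts, phages = self._dataset()
        pairs = build_pair_dataset(phages, hosts, 1, seed=0)
        write_pair_table(pairs, tmp_path / "pairs.tsv")
        assert read_pair_table(tmp_path / "pairs.tsv") == pairs


class TestSignalRecoverability:
    def test_nearest_profile_baseline_recovers_phylum(self):
        """With mimicry 0.7 at 50 kb, the naive cosine baseline must place
        >80% of phages in the right phylum: the planted signal is learnable
        before any neural training is involved."""
        cfg = _cfg(n_phyla=4, children_per_node=1, hosts_per_genus=1,
                   phages_per_host=2, host_length=50_000, phage_length=50_000,
                   mimicry_strength=0.7, seed=3)
        hosts, phages = generate_dataset(cfg)
        host_by_id = {h.id: h for h in hosts}
        hits = 0
        for phage in phages:
            chosen = nearest_composition_host(phage, hosts)
            if host_by_id[chosen].lineage.phylum == phage.lineage.phylum:
                hits += 1
        assert hits / len(phages) > 0.8
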