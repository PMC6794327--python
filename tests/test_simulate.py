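"""Generator guarantees: determinism, feasibility, and realised-vs-spec
tolerances that every downstream recovery test relies on."""

import math

import numpy as np
import pytest

from genostream import io as gio
from genostream.io import extract_proteins
from genostream.metrics import gc_content
from genostream.simulate import (
    FeasibilityError,
    GenomeSpec,
    evolve_genome,
    generate_genome,
    generate_metagenome,
    generate_pangenome,
    generate_protein_family,
    generate_profile_cohort,
)


class TestDeterminism:
    def test_same_spec_same_seed_byte_identical(self, tmp_path):
        spec = GenomeSpec(genome_id="d", size_bp=40_000, gc=0.45, seed=5,
                          n_paralog_families=1, n_rrna=1)
        for run in ("a", "b"):
            genome, proteins, _ = generate_genome(spec)
            gio.write_genome_fasta(tmp_path / f"{run}.fna", genome)
            gio.write_gff3(tmp_path / f"{run}.gff3", genome)
            gio.write_proteins_fasta(tmp_path / f"{run}.faa", proteins)
        for ext in (".fna", ".gff3", ".faa"):
            assert (tmp_path / f"a{ext}").read_bytes() \
                == (tmp_path / f"b{ext}").read_bytes()

    def test_different_seed_differs(self):
        g1, _, _ = generate_genome(GenomeSpec(size_bp=30_000, seed=1))
        g2, _, _ = generate_genome(GenomeSpec(size_bp=30_000, seed=2))
        assert g1.replicons[0].sequence != g2.replicons[0].sequence


class TestRealisedVsSpec:
    def test_gc_within_half_point_at_one_megabase(self):
        genome, _, truth = generate_genome(
            GenomeSpec(genome_id="big", size_bp=1_000_000, gc=0.35, seed=7))
        assert truth["n_cds"] >= 500
        assert gc_content(genome) == pytest.approx(35.0, abs=0.5)

    def test_mean_cds_close_to_lognormal_mean(self, metric_genome):
        _, _, truth = metric_genome
        spec = truth["spec"]
        expected = 3.0 * (math.exp(spec["cds_len_log_mu"]
                                   + spec["cds_len_log_sigma"] ** 2 / 2) / 3)
        assert abs(truth["mean_cds_bp"] - expected) / expected < 0.05

    def test_translations_match_annotation_exactly(self, metric_genome):
        genome, proteins, _ = metric_genome
        extracted = extract_proteins(genome).as_dict()
        assert extracted == proteins.as_dict()

    def test_planted_overlaps_share_exactly_one_bp(self, metric_genome):
        genome, _, truth = metric_genome
        feats = {f.feature_id: f for f in genome.features}
        assert truth["overlap_pairs"]
        for a, b in truth["overlap_pairs"]:
            fa, fb = feats[a], feats[b]
            assert min(fa.end, fb.end) - max(fa.start, fb.start) == 1

    def test_infeasible_gc_with_at_rich_bias_is_reported(self):
        # lysine/phenylalanine-only proteomes force AT-rich codons
        bias = {aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        bias["K"] = 0.5
        bias["F"] = 0.5
        with pytest.raises(FeasibilityError, match="GC target"):
            generate_genome(GenomeSpec(size_bp=30_000, gc=0.9, aa_freqs=bias))

    def test_oversubscribed_genome_is_rejected(self):
        with pytest.raises(FeasibilityError, match="too small"):
            GenomeSpec(size_bp=5_000, n_paralog_families=10,
                       paralog_family_size=5).validate()

    def test_bad_stop_bias_rejected(self):
        with pytest.raises(FeasibilityError):
            GenomeSpec(stop_bias=(0.5, 0.5, 0.5)).validate()


class TestEvolve:
    def test_zero_divergence_is_identity(self, small_genome):
        genome, _, _ = small_genome
        evolved, truth = evolve_genome(genome, 0.0, seed=3)
        assert evolved.replicons[0].sequence == genome.replicons[0].sequence
        assert truth["n_substitutions"] == 0

    def test_substitution_count_matches_rate(self, small_genome):
        genome, _, _ = small_genome
        d = 0.05
        evolved, truth = evolve_genome(genome, d, seed=3)
        n = genome.genome_size
        half = 2.576 * math.sqrt(n * d * (1 - d))
        assert abs(truth["n_substitutions"] - n * d) <= half

    def test_gene_loss_preserves_surviving_frames(self, small_genome):
        genome, proteins, _ = small_genome
        evolved, truth = evolve_genome(genome, 0.0, gene_loss_fraction=0.2,
                                       seed=9)
        survivors = extract_proteins(evolved).as_dict()
        original = proteins.as_dict()
        for pid, seq in survivors.items():
            assert original[pid] == seq
        assert set(truth["lost_genes"]).isdisjoint(survivors)

    def test_gene_gain_adds_new_cds(self, small_genome):
        genome, _, _ = small_genome
        evolved, truth = evolve_genome(genome, 0.0, gene_gain_count=3, seed=9)
        assert len(truth["gained_genes"]) == 3
        gained = set(truth["gained_genes"])
        prots = extract_proteins(evolved).as_dict()
        assert gained <= set(prots)

    def test_out_of_range_divergence_rejected(self, small_genome):
        genome, _, _ = small_genome
        with pytest.raises(ValueError):
            evolve_genome(genome, 0.5)


class TestMetagenome:
    def test_source_counts_follow_abundances(self, small_genome):
        genome, _, _ = small_genome
        rs, truth = generate_metagenome([(genome, 0.3)], 2000, seed=5)
        planted = truth["reads_per_source"][genome.genome_id]
        half = 2.576 * math.sqrt(2000 * 0.3 * 0.7)
        assert abs(planted - 600) <= half
        assert len(rs) == 2000
        assert rs.total_bp == 2000 * 100

    def test_bad_abundances_rejected(self, small_genome):
        genome, _, _ = small_genome
        with pytest.raises(ValueError):
            generate_metagenome([(genome, 1.2)], 100)

    def test_read_longer_than_replicon_rejected(self, small_genome):
        genome, _, _ = small_genome
        with pytest.raises(ValueError):
            generate_metagenome([(genome, 0.5)], 10, read_len=10 ** 6)


class TestFamiliesAndCohorts:
    def test_zero_divergence_family_is_identical(self):
        members, _, _ = generate_protein_family(100, 4, 0.0, 0, seed=1)
        assert len({s for _, s in members}) == 1

    def test_pangenome_truth_bookkeeping(self):
        proteomes, truth = generate_pangenome(3, n_core=5, n_accessory=4,
                                              seed=2)
        assert truth["pan_families"] == 9
        core = [f for f, d in truth["families"].items() if d["core"]]
        assert len(core) == 5
        for fam, d in truth["families"].items():
            assert 1 <= len(d["genomes"]) <= 3
            if d["core"]:
                assert len(d["genomes"]) == 3

    def test_profile_cohort_is_deterministic(self):
        a, _ = generate_profile_cohort(10, seed=3)
        b, _ = generate_profile_cohort(10, seed=3)
        assert a == b
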