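"""Synthetic-genome and MA-simulation behaviour against known truth."""

import numpy as np
import pytest

from mawgs import (
    ExperimentDesign,
    GenomeSpec,
    TruthRates,
    generate_genome,
    inject_artifacts,
    simulate_ma_lines,
)
from mawgs.annotate import CODON_AA, build_site_inventory
from mawgs.core import ConfigurationError, SizingError
from mawgs import io as mio


def small_design(n_control=10, n_treatment=0):
    return ExperimentDesign(
        n_lines_control=n_control, n_lines_treatment=n_treatment
    )


class TestGenerateGenome:
    def test_deterministic_byte_identical(self, tmp_path):
        spec = GenomeSpec(n_chromosomes=2, chrom_length=5000, n_genes=4, seed=7)
        a = generate_genome(spec)
        b = generate_genome(GenomeSpec(n_chromosomes=2, chrom_length=5000,
                                       n_genes=4, seed=7))
        mio.write_fasta(a.sequences, tmp_path / "a.fa")
        mio.write_fasta(b.sequences, tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert a.genes == b.genes

    def test_gc_content_within_tolerance(self):
        ref = generate_genome(
            GenomeSpec(n_chromosomes=1, chrom_length=100_000, gc_content=0.36,
                       n_genes=20, seed=3)
        )
        seq = ref.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.36) < 0.02

    def test_no_genes_means_all_intergenic(self):
        ref = generate_genome(
            GenomeSpec(n_chromosomes=1, chrom_length=2000, n_genes=0, seed=1)
        )
        inv = build_site_inventory(ref)
        assert inv.sites_by_region["CDS"] == 0
        assert inv.sites_by_region["intron"] == 0
        assert inv.sites_by_region["intergenic"] == inv.analyzable_sites_total

    def test_cds_structure_valid(self, toy_ref):
        for g in toy_ref.genes:
            cds = g.coding_sequence(toy_ref.sequences)
            assert len(cds) % 3 == 0
            assert cds[:3] == "ATG"
            assert CODON_AA[cds[-3:]] == "*"
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert all(CODON_AA[c] != "*" for c in internal)

    def test_features_do_not_overlap(self, toy_ref):
        by_chrom = {}
        for g in toy_ref.genes:
            by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_planted_ssrs_present_in_sequence(self, toy_ref):
        for t in toy_ref.ssr_tracts:
            tract = toy_ref.sequences[t.chromosome][t.start - 1 : t.end]
            assert tract == t.motif * t.n_copies

    def test_infeasible_spec_raises_sizing_error(self):
        with pytest.raises(SizingError, match="chrom_length"):
            generate_genome(
                GenomeSpec(n_chromosomes=1, chrom_length=1000, n_genes=5,
                           mean_cds_length=900, seed=0)
            )


class TestSimulateLines:
    def test_zero_rates_give_zero_mutations(self, toy_ref):
        truth = TruthRates(bps_rate_per_site_per_division=0.0,
                           indel_rate_per_site_per_division=0.0)
        sim = simulate_ma_lines(toy_ref, truth, small_design(5, 5), seed=1)
        assert all(len(v) == 0 for v in sim.mutations.values())
        assert len(sim.truth_table) == 0

    def test_poisson_mean_matches_rate_sites_divisions(self, toy_ref):
        # 200 lines at 1e-9 per site per division, 1e6 sites, 1000 divisions
        # => one expected mutation per line
        truth = TruthRates(bps_rate_per_site_per_division=1e-9,
                           indel_rate_per_site_per_division=0.0)
        sim = simulate_ma_lines(
            toy_ref, truth, small_design(200), seed=9, sites_per_line=1_000_000
        )
        counts = [len(sim.mutations[m.line_id]) for m in sim.lines]
        mean = np.mean(counts)
        se = np.sqrt(1.0 / 200)  # Poisson(1) standard error of the mean
        assert abs(mean - 1.0) <= 3 * se

    def test_deterministic_and_stable_under_added_lines(self, toy_ref):
        truth = TruthRates(bps_rate_per_site_per_division=2e-7)
        a = simulate_ma_lines(toy_ref, truth, small_design(6), seed=4)
        b = simulate_ma_lines(toy_ref, truth, small_design(6), seed=4)
        assert a.mutations == b.mutations
        # appending lines must not perturb earlier lines' draws
        c = simulate_ma_lines(toy_ref, truth, small_design(8), seed=4)
        for m in a.lines:
            assert c.mutations[m.line_id] == a.mutations[m.line_id]

    def test_truth_table_conserves_vcf_records(self, toy_ref, tmp_path):
        truth = TruthRates(bps_rate_per_site_per_division=2e-7,
                           indel_rate_per_site_per_division=5e-8)
        sim = simulate_ma_lines(toy_ref, truth, small_design(8), seed=2)
        sim.write(tmp_path)
        by_line = mio.read_vcf_dir(tmp_path / "vcf")
        truth_counts = sim.truth_table.groupby("line_id").size().to_dict()
        for m in sim.lines:
            assert len(by_line[m.line_id]) == truth_counts.get(m.line_id, 0)

    def test_written_ref_alleles_match_reference(self, toy_ref, tmp_path):
        truth = TruthRates(bps_rate_per_site_per_division=2e-7,
                           indel_rate_per_site_per_division=5e-8)
        sim = simulate_ma_lines(toy_ref, truth, small_design(8), seed=6)
        for recs in sim.mutations.values():
            for r in recs:
                seq = toy_ref.sequences[r.chromosome]
                assert seq[r.position - 1 : r.position - 1 + len(r.ref_allele)] \
                    == r.ref_allele

    def test_substitution_identities_follow_spectrum_weights(self, toy_ref):
        # an all-or-nothing spectrum: every substitution must be G:C->A:T
        weights = {c: 0.0 for c in
                   ("A:T->G:C", "A:T->T:A", "A:T->C:G", "G:C->C:G", "G:C->T:A")}
        weights["G:C->A:T"] = 1.0
        truth = TruthRates(bps_rate_per_site_per_division=3e-7,
                           indel_rate_per_site_per_division=0.0,
                           spectrum_weights=weights)
        sim = simulate_ma_lines(toy_ref, truth, small_design(10), seed=8)
        from mawgs.annotate import spectrum_class_of
        classes = {spectrum_class_of(r.ref_allele, r.alt_allele)
                   for recs in sim.mutations.values() for r in recs}
        assert classes == {"G:C->A:T"}


class TestInjectArtifacts:
    def _sim(self, toy_ref, n=12):
        truth = TruthRates(bps_rate_per_site_per_division=1e-7)
        return simulate_ma_lines(toy_ref, truth, small_design(n), seed=3)

    def test_noop_leaves_experiment_unchanged(self, toy_ref):
        sim = self._sim(toy_ref)
        out = inject_artifacts(sim, 0, 0, seed=1)
        assert out.mutations == sim.mutations
        assert [m.mean_depth for m in out.lines] == [m.mean_depth for m in sim.lines]

    def test_shared_mutation_lands_identically_in_both_dishmates(self, toy_ref):
        sim = self._sim(toy_ref)
        out = inject_artifacts(sim, 2, 0, seed=1)
        shared = out.truth_table[out.truth_table.origin == "shared_artifact"]
        assert len(shared) == 4  # two per dish pair
        for (_, pos), grp in shared.groupby(["chromosome", "position"]):
            assert len(grp) == 2
            assert grp.ref_allele.nunique() == 1
            assert grp.alt_allele.nunique() == 1
            lines = set(grp.line_id)
            dish = {m.dish_id for m in out.lines if m.line_id in lines}
            assert len(dish) == 1

    def test_low_depth_lines_marked_below_floor(self, toy_ref):
        sim = self._sim(toy_ref)
        out = inject_artifacts(sim, 0, 3, seed=2)
        low = [m for m in out.lines if m.mean_depth < 30]
        assert len(low) == 3

    def test_requesting_too_many_pairs_raises(self, toy_ref):
        sim = self._sim(toy_ref, n=4)  # two dishes
        with pytest.raises(ConfigurationError, match="two-line dishes"):
            inject_artifacts(sim, 3, 0, seed=1)
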