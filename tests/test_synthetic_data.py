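"""Generator contracts: genome geometry, site planting, read simulation,
nucleoside tables."""

import numpy as np
import pytest
from scipy import stats

from bacm6a import ms_quant as ms
from bacm6a import peaks as pk
from bacm6a import synthetic_data as syn
from bacm6a.gene_context import ContextLabel


class TestGenerateGenome:
    def test_gene_count_and_total_length_bounds(self):
        g = syn.generate_genome(
            10, gene_len_range=(900, 1500), intergenic_range=(100, 300), seed=1
        )
        assert len(g.genes) == 10
        assert 10 * 900 + 9 * 100 <= len(g) <= 10 * 1500 + 9 * 300 + 2 * 300

    def test_single_minimal_gene(self):
        g = syn.generate_genome(
            1, gene_len_range=(300, 300), intergenic_range=(0, 0), seed=7
        )
        assert len(g.genes) == 1 and len(g.genes[0]) == 300
        assert len(g) == 300

    def test_deterministic_for_fixed_seed(self):
        a = syn.generate_genome(5, seed=42)
        b = syn.generate_genome(5, seed=42)
        assert a.sequence == b.sequence
        assert [(x.start, x.end, x.strand) for x in a.genes] == [
            (x.start, x.end, x.strand) for x in b.genes
        ]

    def test_genes_non_overlapping_in_bounds_alternating(self):
        g = syn.generate_genome(8, seed=3)
        for prev, cur in zip(g.genes, g.genes[1:]):
            assert prev.end <= cur.start
        assert all(0 <= x.start < x.end <= len(g) for x in g.genes)
        assert [x.strand for x in g.genes] == ["+", "-"] * 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=0),
            dict(n_genes=2, gene_len_range=(100, 200)),
            dict(n_genes=2, intergenic_range=(-5, 10)),
            dict(n_genes=2, gc_fraction=0.0),
        ],
    )
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            syn.generate_genome(**kwargs)

    def test_gc_fraction_controls_composition(self):
        g = syn.generate_genome(10, gc_fraction=0.7, seed=2)
        gc_obs = (g.sequence.count("G") + g.sequence.count("C")) / len(g)
        assert abs(gc_obs - 0.7) < 0.02


class TestPlantSites:
    def test_context_counts_multinomial(self):
        genome = syn.generate_genome(40, seed=11)
        sites = syn.plant_sites(
            genome, 100, context_mix=(0.15, 0.72, 0.13), motif="TGCCAG", seed=3
        )
        counts = {lab: 0 for lab in ContextLabel}
        for s in sites:
            counts[s.context_label] += 1
        for lab, p in zip(
            (ContextLabel.OVERLAP_START, ContextLabel.INSIDE, ContextLabel.OVERLAP_END),
            (0.15, 0.72, 0.13),
        ):
            sigma = np.sqrt(100 * p * (1 - p))
            assert abs(counts[lab] - 100 * p) <= 3 * sigma
        # reproducible with the same seed
        genome2 = syn.generate_genome(40, seed=11)
        sites2 = syn.plant_sites(
            genome2, 100, context_mix=(0.15, 0.72, 0.13), motif="TGCCAG", seed=3
        )
        assert [s.position for s in sites] == [s.position for s in sites2]

    def test_all_inside_far_from_boundaries(self):
        genome = syn.generate_genome(10, seed=4)
        sites = syn.plant_sites(genome, 20, context_mix=(0, 1, 0), seed=5)
        for s in sites:
            g = genome.gene(s.gene_id)
            assert s.context_label is ContextLabel.INSIDE
            assert s.position - g.start >= 100
            assert g.end - 1 - s.position >= 100

    def test_motif_without_adenine_rejected(self):
        genome = syn.generate_genome(5, seed=6)
        with pytest.raises(ValueError):
            syn.plant_sites(genome, 5, motif="TTTTTT", seed=1)

    def test_capacity_error_when_genome_too_small(self):
        genome = syn.generate_genome(
            1, gene_len_range=(300, 300), intergenic_range=(0, 0), seed=1
        )
        with pytest.raises(syn.CapacityError):
            syn.plant_sites(genome, 50, seed=1)

    def test_planting_soundness(self, default_sim):
        """The genome window holds the motif (sense strand) for every site."""
        genome = default_sim.genome
        for s in default_sim.sites:
            window = genome.sequence[s.window_start : s.window_start + 6]
            expect = s.motif if s.strand == "+" else syn.reverse_complement(s.motif)
            assert window == expect
            g = genome.gene(s.gene_id)
            assert g.start <= s.position < g.end

    def test_sites_spaced_within_genes(self, default_sim):
        by_gene = {}
        for s in default_sim.sites:
            by_gene.setdefault(s.gene_id, []).append(s.position)
        for positions in by_gene.values():
            positions.sort()
            assert all(b - a >= 200 for a, b in zip(positions, positions[1:]))


class TestSimulateReads:
    def test_null_ip_matches_input_per_gene(self):
        genome = syn.generate_genome(10, seed=1)
        sites = syn.plant_sites(genome, 20, seed=3)
        ip, inp = syn.simulate_reads(
            genome, sites, 50_000, enrichment_factor=1.0, seed=5
        )
        def densities(rs):
            return np.array(
                [
                    ((rs.starts >= g.start) & (rs.starts < g.end)).sum() / len(g)
                    for g in genome.genes
                ]
            )
        _, p = stats.ks_2samp(densities(ip), densities(inp))
        assert p > 0.01

    def test_enriched_coverage_at_sites(self, default_sim):
        cov = pk.build_coverage(default_sim.ip).depth
        genic = np.concatenate(
            [cov[g.start : g.end] for g in default_sim.genome.genes]
        )
        median = np.median(genic)
        site_means = [
            cov[max(0, s.position - 25) : s.position + 25].mean()
            for s in default_sim.sites
        ]
        assert np.mean(site_means) >= 3 * median

    def test_zero_reads_gives_empty_sets(self):
        genome = syn.generate_genome(3, seed=2)
        ip, inp = syn.simulate_reads(genome, [], 0, seed=1)
        assert len(ip) == 0 and len(inp) == 0

    def test_enrichment_below_one_rejected(self):
        genome = syn.generate_genome(3, seed=2)
        with pytest.raises(ValueError):
            syn.simulate_reads(genome, [], 100, enrichment_factor=0.5, seed=1)

    def test_reads_in_bounds_and_min_length(self, default_sim):
        for rs in (default_sim.ip, default_sim.input):
            assert rs.starts.min() >= 0
            assert (rs.starts + rs.lengths).max() <= len(default_sim.genome)
            assert rs.lengths.min() >= 20

    def test_ip_strand_follows_gene(self, default_sim):
        genome = default_sim.genome
        ip = default_sim.ip
        idx = np.random.default_rng(0).choice(len(ip), 200, replace=False)
        for i in idx:
            mid = ip.starts[i] + ip.lengths[i] // 2
            owners = [g for g in genome.genes if g.start <= mid < g.end]
            if owners:
                assert ip.strands[i] == owners[0].strand

    def test_determinism(self):
        genome = syn.generate_genome(4, seed=9)
        sites = syn.plant_sites(genome, 5, seed=9)
        a = syn.simulate_reads(genome, sites, 5000, seed=13)
        b = syn.simulate_reads(genome, sites, 5000, seed=13)
        for x, y in zip(a, b):
            assert np.array_equal(x.starts, y.starts)
            assert np.array_equal(x.lengths, y.lengths)
            assert np.array_equal(x.strands, y.strands)


class TestSimulateNucleosideTable:
    def test_noise_free_roundtrip(self):
        ref = ms.ReferenceRatio(R=1.30)
        table = syn.simulate_nucleoside_table(
            0.002, rrna_contam_frac=0.05, R=1.30, cv=0.0, n_reps=3, seed=1
        )
        for m in table:
            assert ms.corrected_ratio(m, ref).value == pytest.approx(
                0.002, rel=1e-12
            )

    def test_no_contamination_means_no_m62a(self):
        table = syn.simulate_nucleoside_table(
            0.002, rrna_contam_frac=0.0, cv=0.0, n_reps=2, seed=1
        )
        assert all(m.quantity_m62A == 0 for m in table)

    def test_monte_carlo_recovery_with_noise(self):
        ref = ms.ReferenceRatio(R=1.30)
        table = syn.simulate_nucleoside_table(
            0.002, rrna_contam_frac=0.10, R=1.30, cv=0.05, n_reps=100, seed=11
        )
        values = np.array([ms.corrected_ratio(m, ref).value for m in table])
        sem = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - 0.002) <= 2 * sem

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_nucleoside_table(0.002, R=0.0)

    def test_deterministic_per_seed(self):
        a = syn.simulate_nucleoside_table(0.002, cv=0.1, n_reps=5, seed=21)
        b = syn.simulate_nucleoside_table(0.002, cv=0.1, n_reps=5, seed=21)
        assert [(m.quantity_A, m.quantity_m6A, m.quantity_m62A) for m in a] == [
            (m.quantity_A, m.quantity_m6A, m.quantity_m62A) for m in b
        ]
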