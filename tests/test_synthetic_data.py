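import numpy as np
import pytest

from erv_charter.dating import age_2ltr, p_distance
from erv_charter.locus_mining import mine_loci, seed_extend_search
from erv_charter.structure_annot import align_global, region_completeness
from erv_charter.synthetic_data import (
    analytic_region_completeness,
    apply_truncation,
    genes_to_gff3,
    implant_provirus,
    make_gene_annotation,
    make_reference,
    make_solo_ltr,
    make_trnas,
    scaled_layout,
    simulate_genome,
)


class TestMakeReference:
    def test_same_seed_reproduces_identical_sequence(self):
        assert make_reference(3, 1500).sequence == make_reference(3, 1500).sequence

    def test_scaled_length_1000_gives_68nt_ltrs(self):
        ref = make_reference(5, 1000)
        assert ref.ltr_length == 68  # 587/8608 of 1000
        assert ref.region_length("three_ltr") == 68

    def test_ltr_copies_identical_at_age_zero(self):
        ref = make_reference(5, 2000)
        assert ref.region_sequence("five_ltr") == ref.region_sequence("three_ltr")

    def test_scaled_layout_preserves_region_order(self):
        layout = scaled_layout(1000)
        starts = [layout[l][0] for l in
                  ("five_ltr", "gag", "pro", "pol", "env", "three_ltr")]
        assert starts == sorted(starts)


class TestImplantProvirus:
    def test_age_zero_insert_is_identical_copy(self, toy_reference, rng):
        host = "A" * 1000
        seq, truth = implant_provirus(host, toy_reference, 500, 0.0, rng=rng)
        inserted = seq[truth.interval.start : truth.interval.end]
        assert inserted == toy_reference.sequence
        assert age_2ltr(p_distance(
            toy_reference.region_sequence("five_ltr"),
            inserted[-toy_reference.ltr_length:],
        )) == 0.0

    def test_target_site_duplication_flanks_insert(self, toy_reference, rng):
        host = "".join("ACGT"[i % 4] for i in range(1000))
        tsd = host[500:505]
        seq, truth = implant_provirus(
            host, toy_reference, 500, 0.0, tsd_len=5, rng=rng
        )
        assert seq[truth.interval.start - 5 : truth.interval.start] == tsd
        assert seq[truth.interval.end : truth.interval.end + 5] == tsd

    def test_overlap_with_existing_element_rejected(self, toy_reference, rng):
        host = "A" * 10_000
        seq, truth = implant_provirus(host, toy_reference, 3000, 1.0, rng=rng)
        with pytest.raises(ValueError, match="overlaps"):
            implant_provirus(
                seq, toy_reference, truth.interval.start + 10, 1.0,
                rng=rng, existing=[truth],
            )

    def test_mean_2ltr_age_estimate_tracks_truth(self, full_reference):
        """50 replicates at tau = 10: mean estimated age within 10%."""
        estimates = []
        for i in range(50):
            rng = np.random.default_rng(1000 + i)
            seq, truth = implant_provirus(
                "A" * 200, full_reference, 100, 10.0, rng=rng
            )
            elem = seq[truth.interval.start : truth.interval.end]
            d = p_distance(
                elem[: full_reference.ltr_length],
                elem[-full_reference.ltr_length :],
            )
            estimates.append(age_2ltr(d))
        assert np.mean(estimates) == pytest.approx(10.0, rel=0.10)


class TestMakeSoloLtr:
    def test_remaining_length_is_one_ltr(self, toy_reference, rng):
        seq, truth = implant_provirus("A" * 1000, toy_reference, 500, 2.0, rng=rng)
        seq2, solo = make_solo_ltr(seq, truth, toy_reference)
        assert solo.interval.length == toy_reference.ltr_length
        assert solo.element_class == "solo_ltr"
        assert len(seq2) == len(seq) - (
            toy_reference.total_length - toy_reference.ltr_length
        )

    def test_deleted_intervals_cover_internal_span_and_one_ltr(
        self, toy_reference, rng
    ):
        seq, truth = implant_provirus("A" * 1000, toy_reference, 500, 2.0, rng=rng)
        _, solo = make_solo_ltr(seq, truth, toy_reference)
        deleted = solo.deleted[-1]
        assert deleted[0] == toy_reference.regions["five_ltr"][1] + 1
        assert deleted[1] == toy_reference.total_length

    def test_solo_ltr_classified_by_miner(self, toy_reference, rng):
        host = "".join("ACGT"[i % 4] for i in range(12_000))
        seq, truth = implant_provirus(host, toy_reference, 6000, 10.0, rng=rng)
        seq, solo = make_solo_ltr(seq, truth, toy_reference)
        hits = seed_extend_search({"chr1": seq}, toy_reference.sequence)
        loci = mine_loci(hits, toy_reference)
        matching = [
            l for l in loci if l.interval.overlaps(solo.interval)
        ]
        assert len(matching) == 1
        assert matching[0].element_class == "solo_ltr"

    def test_non_provirus_rejected(self, toy_reference, rng):
        seq, truth = implant_provirus("A" * 1000, toy_reference, 500, 2.0, rng=rng)
        _, solo = make_solo_ltr(seq, truth, toy_reference)
        with pytest.raises(ValueError):
            make_solo_ltr(seq, solo, toy_reference)


class TestApplyTruncation:
    def test_full_pol_deletion_zeroes_pol_completeness(self, toy_reference, rng):
        seq, truth = implant_provirus("A" * 2000, toy_reference, 1000, 1.0, rng=rng)
        seq, trunc = apply_truncation(
            seq, truth, toy_reference, toy_reference.regions["pol"]
        )
        analytic = analytic_region_completeness(trunc, toy_reference)
        assert analytic["pol"] == 0.0
        elem = seq[trunc.interval.start : trunc.interval.end]
        rc = region_completeness(
            align_global(elem, toy_reference.sequence), toy_reference
        )
        assert rc.percent["pol"] == pytest.approx(0.0, abs=1.0)

    def test_half_env_deletion_matches_interval_arithmetic(self, toy_reference, rng):
        s, e = toy_reference.regions["env"]
        half = (s, s + (e - s + 1) // 2 - 1)
        seq, truth = implant_provirus("A" * 2000, toy_reference, 1000, 0.0, rng=rng)
        seq, trunc = apply_truncation(seq, truth, toy_reference, half)
        analytic = analytic_region_completeness(trunc, toy_reference)
        elem = seq[trunc.interval.start : trunc.interval.end]
        rc = region_completeness(
            align_global(elem, toy_reference.sequence), toy_reference
        )
        assert rc.percent["env"] == pytest.approx(analytic["env"], abs=1.0)
        assert analytic["env"] == pytest.approx(50.0, abs=1.0)

    def test_minus_strand_truncation_maps_through_orientation(
        self, toy_reference, rng
    ):
        seq, truth = implant_provirus(
            "A" * 2000, toy_reference, 1000, 0.0, rng=rng, strand="-"
        )
        seq, trunc = apply_truncation(
            seq, truth, toy_reference, toy_reference.regions["pol"]
        )
        from erv_charter.genome_io import reverse_complement

        elem = reverse_complement(
            seq[trunc.interval.start : trunc.interval.end]
        )
        rc = region_completeness(
            align_global(elem, toy_reference.sequence), toy_reference
        )
        assert rc.percent["pol"] == pytest.approx(0.0, abs=1.0)


class TestFullTruthRoundTrip:
    def test_mine_classify_recovers_planted_elements(self):
        """All planted elements found with the correct class (load <= 6%)."""
        correct = total = 0
        for seed in (1, 2, 3):
            sim = simulate_genome(seed)
            hits = seed_extend_search(sim.genome, sim.reference.sequence)
            loci = mine_loci(hits, sim.reference)
            for truth in sim.truths:
                total += 1
                matching = [
                    l for l in loci
                    if l.interval.overlaps(truth.interval)
                    and l.element_class == truth.element_class
                ]
                if matching:
                    correct += 1
        assert total == 21
        assert correct / total >= 0.95

    def test_solo_fraction_matches_plan_exactly(self, simulation):
        solo = sum(1 for t in simulation.truths if t.element_class == "solo_ltr")
        assert solo == 3 and len(simulation.truths) == 7

    def test_simulation_bit_reproducible(self):
        a, b = simulate_genome(4), simulate_genome(4)
        assert a.genome == b.genome
        assert a.truths == b.truths
        assert a.trnas == b.trnas


class TestGeneAnnotation:
    def test_same_seed_gives_identical_gff3_bytes(self):
        g1, _ = make_gene_annotation(5, 12, 500_000)
        g2, _ = make_gene_annotation(5, 12, 500_000)
        assert genes_to_gff3(g1) == genes_to_gff3(g2)

    def test_genes_do_not_overlap(self):
        genes, _ = make_gene_annotation(5, 15, 600_000)
        spans = sorted((g.body.start, g.body.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_single_gene_domain_bounded(self):
        from erv_charter.regulation import regulatory_domains

        genes, _ = make_gene_annotation(5, 1, 5_000_000)
        (dom,) = regulatory_domains(genes, chrom_lengths={"chr1": 5_000_000})
        assert dom.extended.length <= 2_000_000 + dom.basal.length

    def test_planted_set_ranks_first_in_ora(self):
        from erv_charter.regulation import associate_loci, ora_enrich, regulatory_domains
        from erv_charter.genome_io import GenomicInterval

        rng = np.random.default_rng(8)
        loci = [
            GenomicInterval("chr1", int(p), int(p) + 600)
            for p in rng.integers(10_000, 1_990_000, size=6)
        ]
        genes, sets = make_gene_annotation(8, 40, 2_000_000, loci=loci)
        assert "PLANTED" in sets
        domains = regulatory_domains(genes, chrom_lengths={"chr1": 2_000_000})
        gene_list = sorted({a.gene_id for a in associate_loci(loci, domains)})
        universe = [g.gene_id for g in genes]
        results = ora_enrich(gene_list, sets, universe)
        assert results[0].category == "PLANTED"
        assert results[0].fdr < 0.05

    def test_round_trip_through_gff3_reader(self, tmp_path):
        from erv_charter.genome_io import read_gff3

        genes, _ = make_gene_annotation(5, 8, 400_000)
        path = tmp_path / "toy.gff3"
        path.write_text(genes_to_gff3(genes))
        back = read_gff3(path)
        assert [g.gene_id for g in back] == [g.gene_id for g in genes]
        assert [g.body for g in back] == [g.body for g in genes]


def test_trna_set_reproducible_and_typed(toy_reference):
    t1 = make_trnas(2, toy_reference)
    t2 = make_trnas(2, toy_reference)
    assert t1 == t2
    assert "tRNA-Lys" in t1 and len(t1) == 20
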