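"""Synthetic-data generator: determinism, planted truth, round-trips."""

import numpy as np
import pytest

from lacfam import (
    classify_tandem,
    extract_promoters,
    filter_hmm_candidates,
    gene_metabolite_correlation,
    merge_similarity_candidates,
    scan_promoters,
)
from lacfam import io as lio
from lacfam.simulate import (
    CapacityError,
    SimConfig,
    SitePlacementError,
    SyntheticTruth,
    build_expression_fixture,
    build_family_fixture,
    build_metabolite_fixture,
    build_promoter_fixture,
    random_pwm,
    validate_fixture,
    write_fixture,
)


class TestFamilyFixture:
    def test_same_config_gives_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=5, n_family_genes=8, n_decoy_genes=3,
                        tandem_arrays=((2, 5000),), segmental_pairs=1,
                        chrom_length_bp=2_500_000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture(build_family_fixture(cfg), d1)
        write_fixture(build_family_fixture(cfg), d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name

    def test_empty_family_gives_decoys_only(self):
        cfg = SimConfig(seed=1, n_family_genes=0, n_decoy_genes=4)
        fix = build_family_fixture(cfg)
        t = fix.truth
        assert t.family_genes == [] and t.tandem_membership == {}
        assert t.segmental_pairs == set() and len(t.decoy_genes) == 4

    def test_overfull_config_raises_capacity_error(self):
        cfg = SimConfig(seed=1, n_chromosomes=1, chrom_length_bp=400_000,
                        n_family_genes=10, n_decoy_genes=0)
        with pytest.raises(CapacityError):
            build_family_fixture(cfg)

    def test_truth_ids_resolve(self, small_fixture):
        validate_fixture(small_fixture)

    def test_decoys_fail_identification_and_family_passes(self, small_fixture):
        fix = small_fixture
        cands = filter_hmm_candidates(fix.domain_hits)
        cands = merge_similarity_candidates(cands, fix.similarity_hits)
        genes = {fix.isoform_map[p] for p in cands}
        assert set(fix.truth.family_genes) <= genes
        assert not (set(fix.truth.decoy_genes) & genes)
        # partial decoys pass the evidence filters (and fail verification later)
        assert set(fix.truth.partial_decoy_genes) <= genes

    def test_planted_tandem_arrays_recovered_exactly(self, small_fixture):
        fix = small_fixture
        got = classify_tandem(set(fix.truth.family_genes), fix.models)
        assert got == fix.truth.tandem_membership

    def test_roundtrip_through_files(self, small_fixture, tmp_path):
        write_fixture(small_fixture, tmp_path)
        assert lio.read_fasta(tmp_path / "genome.fasta") == small_fixture.genome
        assert lio.read_fasta(tmp_path / "proteome.fasta") == small_fixture.proteome
        models = lio.read_gff3(tmp_path / "genes.gff3")
        assert sorted(models) == sorted(small_fixture.models)
        hits = lio.read_domain_hits(tmp_path / "domain_hits.tsv")
        assert sorted(h.protein_id for h in hits) == sorted(
            h.protein_id for h in small_fixture.domain_hits
        )
        truth = SyntheticTruth.from_dict(lio.read_json(tmp_path / "truth.json"))
        assert truth.to_dict() == small_fixture.truth.to_dict()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_family_genes=2, tandem_arrays=((3, 1000),))
        with pytest.raises(ValueError):
            SimConfig(planted_correlations=((0, 0, 1.5),), n_family_genes=1)
        with pytest.raises(ValueError):
            SimConfig(n_family_genes=-1)


class TestExpressionFixture:
    def test_early_peak_profiles_peak_before_veraison(self):
        fix = build_expression_fixture([f"g{i}" for i in range(30)], 9, 5, seed=2)
        for g, label in fix.peak_class.items():
            peak = int(fix.profiles.loc[g].idxmax())
            assert (peak < 5) == (label == "pre")

    def test_zero_noise_matrix_equals_profile_table(self):
        fix = build_expression_fixture(["a", "b"], 6, 3, seed=2, noise_sd=0.0)
        for sample, ann in fix.samples.iterrows():
            expect = fix.profiles[ann["stage"]]
            assert np.allclose(fix.values[sample], expect)

    def test_low_mean_fraction_exact_count(self):
        fix = build_expression_fixture([f"g{i}" for i in range(50)], 9, 5,
                                       seed=3, low_fraction=0.2)
        assert len(fix.low_mean_genes) == 10
        means = fix.values.mean(axis=1)
        assert set(means[means < 1.0].index) == fix.low_mean_genes

    def test_too_few_stages_or_bad_veraison_rejected(self):
        with pytest.raises(ValueError):
            build_expression_fixture(["a"], 1, 1, seed=0)
        with pytest.raises(ValueError):
            build_expression_fixture(["a"], 5, 9, seed=0)


class TestMetaboliteFixture:
    def test_r_one_no_noise_is_affine_image(self):
        ef = build_expression_fixture(["a"], 8, 4, seed=5)
        mf, resolved = build_metabolite_fixture(ef.values, [("a", 0, 1.0)], 3,
                                                seed=6, noise=False)
        edges = gene_metabolite_correlation(ef.values, mf)
        r = {(e.gene_id, e.metabolite_id): e.r for e in edges}
        assert r[("a", "M001")] == pytest.approx(1.0)

    def test_planted_zero_correlation_small_at_large_n(self):
        ef = build_expression_fixture(["a"], 1000, 500, seed=7, n_replicates=1)
        mf, _ = build_metabolite_fixture(ef.values, [("a", 0, 0.0)], 2, seed=8)
        edges = gene_metabolite_correlation(ef.values, mf)
        r = {(e.gene_id, e.metabolite_id): e.r for e in edges}
        assert abs(r[("a", "M001")]) < 0.1

    def test_planted_r_within_fisher_band(self):
        ef = build_expression_fixture(["a"], 300, 150, seed=9, n_replicates=1)
        mf, _ = build_metabolite_fixture(ef.values, [("a", 0, 0.9)], 2, seed=10)
        edges = gene_metabolite_correlation(ef.values, mf)
        r = {(e.gene_id, e.metabolite_id): e.r for e in edges}[("a", "M001")]
        half = 1.959963984540054 / np.sqrt(300 - 3)
        assert abs(np.arctanh(r) - np.arctanh(0.9)) <= half

    def test_out_of_range_r_rejected(self):
        ef = build_expression_fixture(["a"], 5, 3, seed=1)
        with pytest.raises(ValueError):
            build_metabolite_fixture(ef.values, [("a", 0, 1.2)], 2, seed=1)


class TestPromoterFixture:
    def test_planted_sites_recovered_by_scanner(self, small_fixture, rng):
        fix = small_fixture
        truth = SyntheticTruth(family_genes=list(fix.truth.family_genes))
        pwms = [random_pwm("MA", 12, rng), random_pwm("MB", 10, rng)]
        genome = build_promoter_fixture(
            pwms, fix.models, fix.genome, truth, seed=11,
            sites=[("MA", 0, 2), ("MB", 1, 1), ("MA", 2, 1)],
        )
        proms = extract_promoters(genome, fix.models)
        hits = scan_promoters(pwms, {g: p.sequence for g, p in proms.items()},
                              alpha=1e-5)
        found = {(h.motif_id, h.gene_id, h.offset, h.strand) for h in hits}
        planted = {(s.pwm_id, s.gene_id, s.offset, s.strand)
                   for s in truth.planted_sites}
        assert planted and planted <= found

    def test_minus_strand_site_recorded_and_scored(self, rng):
        # a '-'-strand planted site must surface with strand '-'
        from lacfam.simulate import build_family_fixture

        cfg = SimConfig(seed=23, n_family_genes=2, n_decoy_genes=0)
        fix = build_family_fixture(cfg)
        pwm = random_pwm("MC", 12, rng)
        for seed in range(40):
            fix.truth.planted_sites.clear()
            genome = build_promoter_fixture([pwm], fix.models, fix.genome,
                                            fix.truth, seed=seed,
                                            sites=[("MC", 0, 1)])
            if fix.truth.planted_sites[0].strand == "-":
                break
        else:
            pytest.fail("no minus-strand draw in 40 seeds")
        s = fix.truth.planted_sites[0]
        proms = extract_promoters(genome, fix.models)
        hits = scan_promoters([pwm], {s.gene_id: proms[s.gene_id].sequence},
                              alpha=1e-5)
        assert any(h.offset == s.offset and h.strand == "-" for h in hits)

    def test_background_only_promoters_silent_at_tiny_alpha(self, rng):
        cfg = SimConfig(seed=29, n_family_genes=3, n_decoy_genes=0)
        fix = build_family_fixture(cfg)
        pwm = random_pwm("MD", 12, rng)
        proms = extract_promoters(fix.genome, fix.models)
        # union bound: expected hits <= 2 * 3 * 1989 * 1e-9 << 0.01
        hits = scan_promoters([pwm], {g: p.sequence for g, p in proms.items()},
                              alpha=1e-9)
        assert hits == []

    def test_unplaceable_sites_raise(self, small_fixture, rng):
        pwm = random_pwm("ME", 1900, rng)  # nearly promoter-sized
        with pytest.raises(SitePlacementError):
            build_promoter_fixture(
                [pwm], small_fixture.models, small_fixture.genome,
                SyntheticTruth(family_genes=small_fixture.truth.family_genes),
                seed=1, sites=[("ME", 0, 3)],
            )
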