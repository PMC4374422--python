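"""Filter primitives and the eight discovery pipelines.

Hand-crafted micro-panels exercise each filter boundary; the synthetic
panel fixture provides truth-table recovery checks.
"""

import pytest

from polyarray.panel_io import (
    Gene,
    GeneModelSet,
    PanelConfig,
    PanelVariantTable,
    VariantObservation,
)
from polyarray.pipelines import (
    CATEGORY_PRECEDENCE,
    ConfigError,
    MarkerCandidate,
    PipelineConfig,
    at_gc_filter,
    discover_diallelic_snps,
    discover_diploid_parent_snps,
    discover_haplosnps,
    discover_indels,
    discover_msnps,
    find_codon_sites,
    flank_safety,
    genic_filter,
    presence_absence_filter,
    read_count_filter,
    spread_selection,
)


def make_table(n_files, observations):
    """observations: (file_idx, chrom, pos, ref, alt, vtype, count)."""
    config = PanelConfig(file_ids=[f"s{i}" for i in range(n_files)],
                         coverages=[20.0] * n_files)
    table = PanelVariantTable(config)
    for (i, chrom, pos, ref, alt, vtype, count) in observations:
        table.add(VariantObservation(
            f"s{i}", chrom, pos, ref, alt, vtype, count, count + 10))
    return table


CFG = PipelineConfig(exclude_unanchored=False)


class TestFilterPrimitives:
    @pytest.mark.parametrize("vtype,count_per_file,n_files,keep", [
        ("snp", 1, 2, False),   # 2 summed reads: below the SNP minimum
        ("snp", 1, 3, True),    # boundary: exactly 3
        ("ins", 1, 2, True),    # indel minimum is 2
        ("ins", 1, 1, False),
    ])
    def test_read_count_sums_across_files(self, vtype, count_per_file,
                                          n_files, keep):
        alt = "G" if vtype == "snp" else "ATT"
        table = make_table(4, [
            (i, "chr1", 50, "A", alt, vtype, count_per_file)
            for i in range(n_files)])
        site = table.sites[("chr1", 50)]
        assert read_count_filter(site, alt, vtype, CFG) is keep

    def test_presence_absence_keep_and_reasons(self):
        table = make_table(8, [(i, "chr1", 50, "A", "G", "snp", 5)
                               for i in range(2)])
        keep, reason = presence_absence_filter(table, "chr1", 50, "G", CFG)
        assert keep and reason == "ok"
        fixed = make_table(8, [(i, "chr1", 50, "A", "G", "snp", 5)
                               for i in range(8)])
        keep, reason = presence_absence_filter(fixed, "chr1", 50, "G", CFG)
        assert not keep and reason == "HSV-like"
        rare = make_table(8, [(0, "chr1", 50, "A", "G", "snp", 5)])
        keep, reason = presence_absence_filter(rare, "chr1", 50, "G", CFG)
        assert not keep and reason == "insufficient presence"

    def test_subpanel_too_small_is_config_error(self):
        table = make_table(3, [(0, "chr1", 50, "A", "G", "snp", 5)])
        with pytest.raises(ConfigError, match="subpanel"):
            presence_absence_filter(table, "chr1", 50, "G", CFG)

    @pytest.mark.parametrize("a,b,keep", [
        ("A", "T", False), ("G", "C", False), ("C", "G", False),
        ("A", "G", True), ("A", "C", True), ("C", "T", True),
        ("G", "T", True),
    ])
    def test_at_gc_filter(self, a, b, keep):
        assert at_gc_filter(a, b) is keep

    def test_at_gc_filter_rejects_indel_alleles(self):
        with pytest.raises(ValueError):
            at_gc_filter("A", "AT")

    def test_genic_filter_modes(self):
        gene = Gene("g1", "chr1", "+", 100, 850,
                    cds=((100, 400), (550, 850)), phases=(0, 0))
        models = GeneModelSet([gene])
        cds_cfg = PipelineConfig(genic_mode="CDS", exclude_unanchored=False)
        genic_cfg = PipelineConfig(genic_mode="genic",
                                   exclude_unanchored=False)
        assert genic_filter("chr1", 200, models, cds_cfg)       # in CDS
        assert not genic_filter("chr1", 450, models, cds_cfg)   # intron
        assert genic_filter("chr1", 450, models, genic_cfg)     # intron ok
        assert not genic_filter("chr1", 900, models, genic_cfg)  # intergenic
        assert genic_filter("chr1", 900, models, CFG)           # mode none

    def test_unanchored_contig_excluded(self):
        cfg = PipelineConfig(exclude_unanchored=True)
        assert not genic_filter("chrUn", 10, None, cfg)

    def test_flank_safety_window_boundaries(self):
        # nearest other variant 25 bp away on both sides: outside 24/24
        table = make_table(4, [
            (0, "chr1", 100, "A", "G", "snp", 5),
            (0, "chr1", 75, "C", "T", "snp", 5),
            (0, "chr1", 125, "C", "T", "snp", 5)])
        assert flank_safety(table, "chr1", 100, 24, 24) == "BothSafe"

    def test_flank_safety_downstream_violation(self):
        table = make_table(4, [
            (0, "chr1", 100, "A", "G", "snp", 5),
            (0, "chr1", 110, "C", "T", "snp", 5)])
        assert flank_safety(table, "chr1", 100, 24, 24) == "UpSafe-only"
        assert flank_safety(table, "chr1", 110, 24, 24) == "DownSafe-only"

    def test_flank_safety_destab_exception(self):
        table = make_table(4, [
            (0, "chr1", 100, "A", "G", "snp", 5),
            (0, "chr1", 104, "C", "T", "snp", 5)])
        assert flank_safety(table, "chr1", 100, 24, 24) == "UpSafe-only"
        assert flank_safety(table, "chr1", 100, 24, 24,
                            allowed_exception=104) == "BothSafe"


@pytest.fixture(scope="session")
def results(panel_table, reference, gene_models):
    config = PipelineConfig()
    return {
        "diallelic": discover_diallelic_snps(
            panel_table, config, reference, gene_models),
        "msnp": discover_msnps(panel_table, config, reference, gene_models),
        "indel": discover_indels(panel_table, config, reference,
                                 gene_models),
        "snp_snp": discover_haplosnps(panel_table, config, "snp_snp",
                                      reference),
        "indel_snp": discover_haplosnps(panel_table, config, "indel_snp",
                                        reference),
        "snp_in_insertion": discover_haplosnps(
            panel_table, config, "snp_in_insertion", reference),
    }


class TestTruthRecovery:
    """All planted constraint-satisfying markers are recovered; planted
    pure HSVs and decoys never leak into the candidate lists."""

    @pytest.mark.parametrize("category", [
        "diallelic", "msnp", "indel", "snp_snp", "indel_snp",
        "snp_in_insertion"])
    def test_planted_markers_recovered_exactly(self, panel, results,
                                               category):
        truth = panel.truth
        want = {
            (r.chrom, r.pos)
            for r in truth[(truth.category == category)
                           & truth.satisfies].itertuples()}
        have = {(c.chrom, c.pos) for c in results[category]}
        assert want, "fixture must plant this category"
        assert have == want

    def test_pure_hsvs_never_diallelic_candidates(self, panel, results):
        hsvs = {
            (r.chrom, r.pos)
            for r in panel.truth[
                panel.truth.kind.isin(["hsv_snp", "hsv_indel"])
            ].itertuples()}
        diallelic = {(c.chrom, c.pos) for c in results["diallelic"]}
        assert not hsvs & diallelic

    def test_at_gc_and_oversize_decoys_excluded(self, panel, results):
        truth = panel.truth
        decoys = {
            (r.chrom, r.pos)
            for r in truth[(truth.category == "none")
                           & truth.kind.str.startswith("marker")
                           ].itertuples()}
        assert decoys, "fixture must plant decoys"
        emitted = {(c.chrom, c.pos)
                   for cands in results.values() for c in cands}
        assert not decoys & emitted

    def test_haplosnp_distance_rules_hold(self, results):
        for c in results["snp_snp"]:
            assert 1 <= abs(c.destab.offset) <= 6
        for c in results["indel_snp"]:
            assert 1 <= abs(c.destab.offset) <= 14
            assert 4 <= len(c.destab.ref) - len(c.destab.alt) <= 6
        for c in results["snp_in_insertion"]:
            assert 3 <= len(c.destab.alt) - 1 <= 6

    def test_soundness_emitted_candidates_repass_filters(
            self, panel_table, results):
        config = PipelineConfig()
        for c in results["diallelic"]:
            site = panel_table.sites[(c.chrom, c.pos)]
            assert read_count_filter(site, c.marker_allele, "snp", config)
            assert presence_absence_filter(
                panel_table, c.chrom, c.pos, c.marker_allele, config)[0]
            assert at_gc_filter(*c.alleles)
            assert flank_safety(panel_table, c.chrom, c.pos, 24,
                                24) == "BothSafe"

    def test_min_present_monotonicity(self, panel_table):
        counts = []
        for mp in (2, 3, 4, 6):
            cfg = PipelineConfig(min_present=mp)
            counts.append(len(discover_diallelic_snps(panel_table, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_category_disjointness_after_spread(self, results, panel):
        allc = [c for cands in results.values() for c in cands]
        chosen = spread_selection(allc, panel.chrom_lengths, len(allc))
        coords = [(c.chrom, c.pos) for c in chosen]
        assert len(coords) == len(set(coords))


class TestHaplosnpRules:
    def _base_obs(self, marker_pos, destab_pos):
        obs = []
        for i in range(8):  # destab HSV present in all files
            obs.append((i, "chr1", destab_pos, "C", "T", "snp", 5))
        for i in range(3):  # marker in 3 of 8
            obs.append((i, "chr1", marker_pos, "A", "G", "snp", 5))
        return obs

    def test_snpsnp_offset_six_accepted_seven_rejected(self):
        near = make_table(8, self._base_obs(100, 106))
        far = make_table(8, self._base_obs(100, 107))
        assert len(discover_haplosnps(near, CFG, "snp_snp")) == 1
        assert len(discover_haplosnps(far, CFG, "snp_snp")) == 0

    def test_clean_window_rejects_third_variant(self):
        obs = self._base_obs(100, 104)
        obs.append((0, "chr1", 110, "G", "A", "snp", 5))
        table = make_table(8, obs)
        assert discover_haplosnps(table, CFG, "snp_snp") == []

    def test_coupling_violation_rejected(self):
        # marker present in a file that lacks the critical form
        obs = [(i, "chr1", 104, "C", "T", "snp", 5) for i in range(7)]
        obs += [(i, "chr1", 100, "A", "G", "snp", 5) for i in (0, 1, 7)]
        # destab absent from file 7 entirely: not fixed -> no destab at all
        table = make_table(8, obs)
        assert discover_haplosnps(table, CFG, "snp_snp") == []

    def test_indelsnp_size_range_enforced(self):
        def build(k):
            obs = [(i, "chr1", 104, "C" + "A" * k, "C", "del", 5)
                   for i in range(8)]
            obs += [(i, "chr1", 100, "A", "G", "snp", 5) for i in range(3)]
            return make_table(8, obs)
        assert len(discover_haplosnps(build(4), CFG, "indel_snp")) == 1
        assert len(discover_haplosnps(build(3), CFG, "indel_snp")) == 0
        assert len(discover_haplosnps(build(7), CFG, "indel_snp")) == 0

    def test_insertion_containment(self):
        # two 4-bp insertion forms differing at one internal base
        obs = []
        for i in range(8):
            obs.append((i, "chr1", 100, "A", "ACGTT", "ins", 5))
        for i in range(3):
            obs.append((i, "chr1", 100, "A", "CGTT", "ins", 5))
        # normalize: second form written unpadded on purpose? keep padded:
        obs = [(i, "chr1", 100, "A", "ACGTT", "ins", 5) for i in range(3, 8)]
        obs += [(i, "chr1", 100, "A", "ACATT", "ins", 5) for i in range(3)]
        table = make_table(8, obs)
        cands = discover_haplosnps(table, CFG, "snp_in_insertion")
        assert len(cands) == 1
        assert cands[0].alleles == ("G", "A")  # background vs marker base


class TestDiploidPipeline:
    def _tables(self, het=True, nearby_oct_variant=False):
        ro = 15 if het else 0
        dip = PanelVariantTable(
            PanelConfig(file_ids=["F1D"], coverages=[36.0]))
        dip.add(VariantObservation("F1D", "chr1", 100, "A", "G", "snp",
                                   12, 12 + ro))
        obs = []
        if nearby_oct_variant:
            obs.append((0, "chr1", 105, "C", "T", "snp", 5))
        octo = make_table(8, obs)
        return dip, octo

    def test_het_site_emitted(self):
        dip, octo = self._tables(het=True)
        assert len(discover_diploid_parent_snps(dip, octo, CFG)) == 1

    def test_hom_alt_site_excluded(self):
        dip, octo = self._tables(het=False)
        assert discover_diploid_parent_snps(dip, octo, CFG) == []

    def test_octoploid_variant_nearby_excluded(self):
        dip, octo = self._tables(het=True, nearby_oct_variant=True)
        assert discover_diploid_parent_snps(dip, octo, CFG) == []

    def test_recovery_on_synthetic_panel(self, panel, panel_table,
                                         diploid_table, reference):
        config = PipelineConfig()
        cands = discover_diploid_parent_snps(diploid_table, panel_table,
                                             config, reference)
        truth = panel.truth
        want = {(r.chrom, r.pos)
                for r in truth[truth.category == "diploid"].itertuples()}
        assert {(c.chrom, c.pos) for c in cands} == want


class TestCodonSites:
    def test_strand_aware_proline_third_positions(self):
        seq = ("T" * 10 + "ATGCCAGGT" + "T" * 11 + "TCCAGGCAT"
               + "T" * 11)
        reference = {"chr1": seq}
        genes = GeneModelSet([
            Gene("g+", "chr1", "+", 10, 19, cds=((10, 19),), phases=(0,)),
            # reverse-strand transcript reads ATG CCT GGA
            Gene("g-", "chr1", "-", 30, 39, cds=((30, 39),), phases=(0,)),
        ])
        empty = make_table(4, [])
        cands = find_codon_sites(reference, genes, empty, CFG)
        assert {(c.chrom, c.pos) for c in cands} == {("chr1", 15),
                                                    ("chr1", 33)}
        for c in cands:
            assert at_gc_filter(*c.alleles)

    def test_non_proline_codons_skipped(self):
        seq = "T" * 10 + "ATGACAGGT" + "T" * 20  # ACA is not proline
        genes = GeneModelSet([
            Gene("g", "chr1", "+", 10, 19, cds=((10, 19),), phases=(0,))])
        assert find_codon_sites({"chr1": seq}, genes, make_table(4, []),
                                CFG) == []

    def test_nearby_panel_variant_blocks_candidate(self):
        seq = "T" * 10 + "ATGCCAGGT" + "T" * 20
        genes = GeneModelSet([
            Gene("g", "chr1", "+", 10, 19, cds=((10, 19),), phases=(0,))])
        table = make_table(4, [(0, "chr1", 20, "T", "C", "snp", 5)])
        assert find_codon_sites({"chr1": seq}, genes, table, CFG) == []


def _cand(chrom, pos, category="diallelic_snp"):
    alleles = ("A", "G") if category != "msnp" else ("A", "C", "G")
    return MarkerCandidate(category=category, chrom=chrom, pos=pos,
                           alleles=alleles)


class TestSpreadSelection:
    def test_far_candidate_always_kept(self):
        cands = [_cand("chr1", p) for p in range(100, 110)]
        cands.append(_cand("chr1", 90_000))
        chosen = spread_selection(cands, {"chr1": 100_000}, 2)
        positions = {c.pos for c in chosen}
        assert 90_000 in positions and len(positions) == 2
        # brute-force max-min oracle for n=2: the two extremes
        assert positions == {100, 90_000}

    def test_target_at_least_n_keeps_all(self):
        cands = [_cand("chr1", p) for p in (10, 20, 30)]
        assert len(spread_selection(cands, {"chr1": 100}, 5)) == 3

    def test_duplicate_coordinate_resolved_by_precedence(self):
        a = _cand("chr1", 500, "diallelic_snp")
        b = _cand("chr1", 500, "msnp")
        chosen = spread_selection([a, b], {"chr1": 1000}, 10)
        assert len(chosen) == 1 and chosen[0].category == "msnp"
        assert CATEGORY_PRECEDENCE.index("msnp") < \
            CATEGORY_PRECEDENCE.index("diallelic_snp")

    def test_deterministic(self):
        cands = [_cand("chr1", p) for p in (5, 10, 40, 41, 90)]
        r1 = spread_selection(cands, {"chr1": 100}, 3)
        r2 = spread_selection(cands, {"chr1": 100}, 3)
        assert [(c.pos) for c in r1] == [(c.pos) for c in r2]
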