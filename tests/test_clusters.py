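"""Cluster geometry, the genotype caller, quality classes, HomRO and OTV."""

import numpy as np
import pandas as pd
import pytest

from polyarray.clusters import (
    ClusterCenterModel,
    QualityThresholds,
    call_genotypes,
    center,
    classify_quality,
    contrast_size,
    depth_vs_clustering,
    homro,
    otv_recall,
)
from polyarray.synthetic import generate_intensities, generate_pedigree

MODEL = ClusterCenterModel()  # all constants 100


def _dataset(genotypes, background=(0, 0), noise_sd=0.0, seed=1,
             marker="m1"):
    df = pd.DataFrame({
        "marker": marker,
        "sample": [f"s{i:03d}" for i in range(len(genotypes))],
        "genotype": list(genotypes),
    })
    return generate_intensities(df, MODEL, noise_sd, seed=seed,
                                background={marker: background})


def _octoploid_genotypes(n=300, seed=0):
    rng = np.random.default_rng(seed)
    return rng.choice(["AA", "AB", "BB"], size=n, p=[0.25, 0.5, 0.25])


class TestGeometry:
    # all nine dosage genotypes of an octoploid A/B locus
    @pytest.mark.parametrize("n_a", range(9))
    def test_center_matches_closed_form(self, n_a):
        n_b = 8 - n_a
        assert center(n_a, n_b, MODEL) == (100 * n_a + 100, 100 * n_b + 100)

    @pytest.mark.parametrize("ab,expected_contrast", [
        ((200, 200), 0.0),        # diploid heterozygote
        ((300, 300), 0.0),        # 4x AABB
        ((200, 800), -2.0),
        ((100, 900), np.log2(1 / 9)),
    ])
    def test_contrast_closed_form(self, ab, expected_contrast):
        c, s = contrast_size(*ab)
        assert c == pytest.approx(expected_contrast)
        assert s == pytest.approx((np.log2(ab[0]) + np.log2(ab[1])) / 2)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            contrast_size(0, 100)


class TestHomRO:
    def test_diploid_pattern_positive(self):
        # centers AA=(300,100), BB=(100,300)
        value, pattern = homro({"AA": np.log2(3.0), "BB": -np.log2(3.0)})
        assert value == pytest.approx(np.log2(3.0))
        assert pattern == "diploid_like"

    def test_octoploid_b_fixed_negative(self):
        value, pattern = homro({
            "AA": float(np.log2(300 / 700)),
            "BB": float(np.log2(100 / 900))})
        assert value == pytest.approx(-1.2224, abs=1e-3)
        assert pattern == "polyploid_like"

    def test_4x_aabb_at_zero_is_polyploid(self):
        value, pattern = homro({"AA": 0.0, "BB": float(np.log2(100 / 500))})
        assert value == 0.0 and pattern == "polyploid_like"

    def test_needs_a_homozygous_cluster(self):
        with pytest.raises(ValueError):
            homro({"AB": 0.0})

    @pytest.mark.parametrize("brightness", [40.0, 100.0, 250.0])
    def test_sign_invariants_across_model_intensities(self, brightness):
        m = ClusterCenterModel(brightness, brightness, 100.0)
        # simulated 2x locus: always diploid-like
        aa, bb = m.center(2, 0), m.center(0, 2)
        v2, p2 = homro({"AA": contrast_size(*aa)[0],
                        "BB": contrast_size(*bb)[0]})
        assert p2 == "diploid_like"
        # simulated 8x B-fixed locus: always polyploid-like
        aa8, bb8 = m.center(2, 6), m.center(0, 8)
        v8, p8 = homro({"AA": contrast_size(*aa8)[0],
                        "BB": contrast_size(*bb8)[0]})
        assert p8 == "polyploid_like"


class TestCaller:
    @pytest.mark.parametrize("background", [(0, 0), (0, 2), (0, 6)])
    def test_noise_free_calls_equal_truth(self, background):
        ds = _dataset(_octoploid_genotypes(), background)
        called = call_genotypes(ds)
        assert (called["call"] == called["genotype"]).all()

    @pytest.mark.parametrize("background", [(0, 0), (0, 6)])
    def test_noisy_calls_accuracy_99pct(self, background):
        ds = _dataset(_octoploid_genotypes(), background, noise_sd=0.05,
                      seed=2)
        called = call_genotypes(ds, confidence_threshold=0.15)
        mask = called["call"] != "NoCall"
        acc = (called.loc[mask, "call"] == called.loc[mask,
                                                      "genotype"]).mean()
        assert acc >= 0.99

    def test_stricter_confidence_never_reduces_nocalls(self):
        ds = _dataset(_octoploid_genotypes(), (0, 6), noise_sd=0.15, seed=3)
        loose = call_genotypes(ds, confidence_threshold=0.15)
        strict = call_genotypes(ds, confidence_threshold=0.01)
        assert (strict["call"] == "NoCall").sum() >= \
            (loose["call"] == "NoCall").sum()

    def test_single_cluster_dataset(self):
        ds = _dataset(["AA"] * 40)
        called = call_genotypes(ds)
        assert called["call"].nunique() == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            call_genotypes(pd.DataFrame(columns=["marker", "contrast",
                                                 "size"]))

    def test_low_size_homozygotes_not_misread_as_null(self):
        # 8x B-fixed BB cluster sits low in size but at extreme contrast
        ds = _dataset(_octoploid_genotypes(), (0, 6), noise_sd=0.05, seed=4)
        called = call_genotypes(ds)
        assert (called["call"] != "00").all()


class TestQualityClasses:
    def _called(self, genotypes, **kw):
        return call_genotypes(_dataset(genotypes, **kw),
                              confidence_threshold=0.15)

    def test_crbt_exactly_below_97pct(self):
        called = self._called(_octoploid_genotypes(100))
        bad = called.copy()
        bad.loc[bad.index[:4], "call"] = "NoCall"  # call rate 96%
        assert classify_quality(bad)[0].snp_class == "CRBT"
        ok = called.copy()
        ok.loc[ok.index[:3], "call"] = "NoCall"    # call rate 97%
        assert classify_quality(ok)[0].snp_class != "CRBT"

    def test_monomorphic_is_mhr(self):
        called = self._called(["AA"] * 50)
        assert classify_quality(called)[0].snp_class == "MHR"

    def test_two_clusters_is_nmh(self):
        called = self._called(["AA"] * 30 + ["AB"] * 30)
        assert classify_quality(called)[0].snp_class == "NMH"

    def test_three_clusters_is_phr(self):
        q = classify_quality(self._called(_octoploid_genotypes(100)))[0]
        assert q.snp_class == "PHR" and q.filtered_phr

    def test_null_cluster_is_otv(self):
        fam = generate_pedigree(["A0"], ["B0"], 80, seed=3)
        gts = ["A0", "B0"] + list(fam.progeny["m0001"])
        q = classify_quality(self._called(gts))[0]
        assert q.snp_class == "OTV"

    def test_nminorhom_boundary(self):
        gts = ["AA"] * 2 + ["AB"] * 49 + ["BB"] * 49
        q = classify_quality(self._called(gts))[0]
        assert "nMinorHom" in q.failed_filters and not q.filtered_phr
        gts = ["AA"] * 3 + ["AB"] * 49 + ["BB"] * 48
        q = classify_quality(self._called(gts))[0]
        assert "nMinorHom" not in q.failed_filters

    def test_discordant_replicates_fail_reproducibility(self):
        called = self._called(_octoploid_genotypes(100))
        pair = [(called.loc[0, "sample"], called.loc[1, "sample"])]
        if called.loc[0, "call"] == called.loc[1, "call"]:
            called.loc[1, "call"] = \
                "AA" if called.loc[1, "call"] != "AA" else "BB"
        q = classify_quality(called, replicate_map=pair)[0]
        assert "reproducibility" in q.failed_filters

    def test_concordant_replicates_pass(self):
        called = self._called(_octoploid_genotypes(100))
        same = called[called["call"] == "AB"]["sample"].iloc[:2]
        q = classify_quality(called,
                             replicate_map=[tuple(same)])[0]
        assert "reproducibility" not in q.failed_filters

    def test_unknown_replicate_sample_rejected(self):
        called = self._called(["AA"] * 10)
        with pytest.raises(ValueError, match="replicate"):
            classify_quality(called, replicate_map=[("nope", "s000")])

    def test_inflated_cluster_variance_flagged(self):
        ds = _dataset(_octoploid_genotypes(150), noise_sd=0.02, seed=5)
        called = call_genotypes(ds, confidence_threshold=0.5)
        het = called["call"] == "AB"
        rng = np.random.default_rng(6)
        called.loc[het, "size"] += rng.normal(0, 0.6, int(het.sum()))
        q = classify_quality(called)[0]
        assert any(f.endswith("varY") for f in q.failed_filters)

    def test_every_marker_lands_in_exactly_one_class(self):
        frames = [
            self._called(_octoploid_genotypes(60), marker="a"),
            self._called(["AA"] * 30, marker="b"),
            self._called(["AA"] * 20 + ["AB"] * 20, marker="c"),
        ]
        quality = classify_quality(pd.concat(frames, ignore_index=True))
        assert len(quality) == 3
        assert all(q.snp_class in ("PHR", "NMH", "OTV", "MHR", "CRBT",
                                   "Other") for q in quality)


class TestOtvRecall:
    def _family_calls(self, noise_sd=0.0):
        fam = generate_pedigree(["A0"], ["B0"], 80, seed=3)
        gts = ["A0", "B0"] + list(fam.progeny["m0001"])
        return call_genotypes(_dataset(gts, noise_sd=noise_sd, seed=7))

    def test_four_cluster_family_recoded(self):
        rec = otv_recall(self._family_calls())
        assert set(rec["call"]) == {"A0", "AB", "B0", "00"}

    def test_no_null_cluster_unchanged(self):
        called = call_genotypes(_dataset(_octoploid_genotypes(100)))
        rec = otv_recall(called)
        assert (rec["call"] == called["call"]).all()

    def test_all_null_degenerate_flagged(self):
        called = call_genotypes(_dataset(["AA"] * 10))
        called["call"] = "00"  # externally forced degenerate table
        rec = otv_recall(called)
        assert rec["otv_degenerate"].all()


class TestDepthVsClustering:
    def test_deletion_blocks_enrich_diploid_clustering_at_low_depth(self):
        depths = {f"m{i}": (16.0 if i < 50 else 32.0) for i in range(100)}
        patterns = {}
        for i in range(100):
            inside = i < 50  # markers in 2-subgenome deletion blocks
            patterns[f"m{i}"] = "diploid_like" if inside else \
                "polyploid_like"
        table = depth_vs_clustering(depths, patterns, bin_width=10)
        low = table[table.depth_bin == 10.0]["frac_diploid_like"].iloc[0]
        high = table[table.depth_bin == 30.0]["frac_diploid_like"].iloc[0]
        assert low > high

    def test_no_deletions_flat(self):
        depths = {f"m{i}": 32.0 for i in range(40)}
        patterns = {f"m{i}": "polyploid_like" for i in range(40)}
        table = depth_vs_clustering(depths, patterns)
        assert len(table) == 1 and table["frac_diploid_like"].iloc[0] == 0.0
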