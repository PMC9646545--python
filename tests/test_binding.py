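"""Coverage normalization, peak assignment, meta-profiles, and binding
classification."""

import numpy as np
import pandas as pd
import pytest

from thermomod.binding import (
    CoverageTrack,
    add_tss,
    assign_peaks,
    best_scores,
    binding_class_table,
    classify_binding,
    meta_profile,
    multi_tf_targets,
    normalize_coverage,
    score_by_condition,
)
from thermomod.clustering import wilcoxon_bonferroni


def bed6(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])


def bed5(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id", "score"])


@pytest.fixture()
def toy_genes():
    return bed6(
        [
            ("chr1", 2000, 3000, "gA", 0, "+"),   # TSS 2000
            ("chr1", 8000, 9000, "gB", 0, "-"),   # TSS 8999
            ("chr2", 5000, 6000, "gC", 0, "+"),   # TSS 5000
        ]
    )


class TestNormalizeCoverage:
    def test_constant_track_maps_to_one(self):
        track = CoverageTrack({"chr1": np.full(1000, 7.0)})
        out = normalize_coverage(track)
        np.testing.assert_allclose(out.arrays["chr1"], 1.0)

    def test_value_scaling_arithmetic(self):
        values = np.full(100, 2.0)
        values[10] = 6.0
        out = normalize_coverage(CoverageTrack({"chr1": values}))
        assert out.arrays["chr1"][10] == pytest.approx(6.0 / values.mean())

    def test_genome_mean_is_one_including_zero_positions(self):
        rng = np.random.default_rng(0)
        track = CoverageTrack(
            {"chr1": rng.poisson(3, 5000).astype(float), "chr2": np.zeros(5000)}
        )
        out = normalize_coverage(track)
        assert out.genome_mean == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_track_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_coverage(CoverageTrack({"chr1": np.zeros(10)}))


class TestAssignPeaks:
    def test_midpoint_at_tss_assigned(self, toy_genes):
        peaks = bed5([("chr1", 1950, 2051, "p1", 5.0)])  # midpoint 2000
        out = assign_peaks(peaks, toy_genes, window=500)
        assert out.iloc[0]["gene_id"] == "gA"
        assert out.iloc[0]["distance"] == 0

    @pytest.mark.parametrize("offset,assigned", [(500, True), (501, False)])
    def test_window_boundary_is_inclusive(self, toy_genes, offset, assigned):
        mid = 2000 + offset
        peaks = bed5([("chr1", mid - 50, mid + 50, "p1", 5.0)])
        out = assign_peaks(peaks, toy_genes, window=500)
        assert (len(out) == 1) == assigned

    def test_nearest_tss_wins_and_ties_break_lexicographically(self):
        genes = bed6(
            [
                ("chr1", 1000, 1500, "gB", 0, "+"),  # TSS 1000
                ("chr1", 1200, 1700, "gA", 0, "+"),  # TSS 1200
            ]
        )
        near = bed5([("chr1", 1140, 1141, "p1", 1.0)])  # 140 vs 60 -> gA
        assert assign_peaks(near, genes, window=500).iloc[0]["gene_id"] == "gA"
        tie = bed5([("chr1", 1100, 1101, "p2", 1.0)])   # 100 vs 100 -> gA
        assert assign_peaks(tie, genes, window=500).iloc[0]["gene_id"] == "gA"

    def test_minus_strand_tss_is_end_minus_one(self, toy_genes):
        peaks = bed5([("chr1", 8949, 9050, "p1", 2.0)])  # midpoint 8999
        out = assign_peaks(peaks, toy_genes, window=500)
        assert out.iloc[0]["gene_id"] == "gB"
        assert out.iloc[0]["distance"] == 0

    def test_unknown_chromosome_dropped(self, toy_genes):
        peaks = bed5([("chrX", 100, 200, "p1", 1.0)])
        assert assign_peaks(peaks, toy_genes).empty

    def test_invariant_to_peak_order(self, toy_genes):
        rng = np.random.default_rng(1)
        peaks = bed5(
            [
                ("chr1", int(p) - 50, int(p) + 50, f"p{i}", float(i))
                for i, p in enumerate(rng.integers(1500, 9500, 30))
            ]
        )
        a = assign_peaks(peaks, toy_genes).sort_values("peak_id").reset_index(drop=True)
        b = (
            assign_peaks(peaks.iloc[::-1], toy_genes)
            .sort_values("peak_id")
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(a, b)

    def test_round_trip_against_planted_targets(self, binding_data, sim_config):
        (genes_bed, _, peaks), truth = binding_data
        tf = sim_config.tfs[0]
        for cond in sim_config.binding_conditions:
            out = assign_peaks(peaks[tf][cond], genes_bed, window=sim_config.promoter_halfwidth)
            expected = {
                g
                for g, t in truth.binding_type[tf].items()
                if t == "type_II" or (t == "type_I" and cond == sim_config.specific_condition)
            }
            assert set(out["gene_id"]) == expected

    def test_best_score_is_max_over_peaks(self, toy_genes):
        peaks = bed5(
            [("chr1", 1950, 2051, "p1", 5.0), ("chr1", 2050, 2151, "p2", 9.0)]
        )
        scores = best_scores(assign_peaks(peaks, toy_genes))
        assert scores["gA"] == 9.0


class TestMetaProfile:
    def test_flat_normalized_track_gives_flat_curve(self, toy_genes):
        track = CoverageTrack(
            {"chr1": np.full(20000, 1.0), "chr2": np.full(20000, 1.0)}
        )
        prof = meta_profile(track, toy_genes, ["gA", "gB", "gC"], window=500)
        np.testing.assert_allclose(prof.mean, 1.0, atol=1e-6)
        assert prof.n_genes == 3
        assert prof.offsets[0] == -500 and prof.offsets[-1] == 500

    def test_planted_triangle_peaks_at_zero_offset(self):
        genes = bed6([("chr1", 5000, 6000, "gA", 0, "+")])
        arr = np.full(20000, 4.0)
        hw, h = 250, 12.0
        tri = h * (1 - np.abs(np.arange(-hw, hw + 1)) / hw)
        arr[5000 - hw: 5000 + hw + 1] += tri
        track = normalize_coverage(CoverageTrack({"chr1": arr}))
        prof = meta_profile(track, genes, ["gA"], window=500)
        mean_cov = arr.mean()
        assert prof.mean[500] == pytest.approx((4.0 + h) / mean_cov, rel=1e-9)
        assert prof.mean[0] == pytest.approx(4.0 / mean_cov, rel=1e-9)
        assert np.argmax(prof.mean) == 500

    def test_minus_strand_curve_is_orientation_corrected(self):
        # asymmetric bump 100 bp downstream of the TSS on the minus strand
        genes = bed6([("chr1", 5000, 6000, "gA", 0, "-")])  # TSS 5999
        arr = np.full(20000, 1.0)
        arr[5999 - 100] = 11.0  # genomic left of TSS = downstream for minus strand
        prof = meta_profile(CoverageTrack({"chr1": arr}), genes, ["gA"], window=500)
        assert prof.mean[500 + 100] == 11.0  # shows up at +100 (downstream)

    def test_close_neighbors_excluded(self):
        genes = bed6(
            [
                ("chr1", 5000, 5400, "gA", 0, "+"),
                ("chr1", 5450, 5850, "gB", 0, "+"),  # body inside gA's TSS window
                ("chr1", 15000, 15400, "gC", 0, "+"),
            ]
        )
        track = CoverageTrack({"chr1": np.full(20000, 1.0)})
        with pytest.raises(ValueError, match="2 excluded"):
            meta_profile(track, genes, ["gA", "gB"], window=500)
        prof = meta_profile(track, genes, ["gA", "gB", "gC"], window=500)
        assert prof.n_genes == 1 and prof.n_excluded == 2

    def test_normalized_peak_free_track_profiles_at_one(self, binding_data, sim_config):
        """Whole-genome genes on a peak-free (constant) track: curve of 1s."""
        (genes_bed, _, _), _ = binding_data
        chrom_len = sim_config.genome_length // sim_config.n_chromosomes
        track = normalize_coverage(
            CoverageTrack(
                {f"chr{i+1}": np.full(chrom_len, 3.3) for i in range(sim_config.n_chromosomes)}
            )
        )
        prof = meta_profile(track, genes_bed, list(genes_bed["gene_id"]), window=500)
        np.testing.assert_allclose(prof.mean, 1.0, atol=1e-6)
        assert prof.n_genes + prof.n_excluded == len(genes_bed)


class TestClassifyBinding:
    UNIVERSE = ["g1", "g2", "g3", "g4"]
    TARGETS = {
        "17C": {"g2", "g3"},
        "27C": {"g2"},
        "37C": {"g1", "g2"},
    }

    def test_class_definitions(self):
        cls = classify_binding(self.TARGETS, "37C", self.UNIVERSE)
        assert cls["g1"] == "type_I"    # bound at 37C only
        assert cls["g2"] == "type_II"   # bound everywhere
        assert cls["g3"] == "other"     # bound at 17C only
        assert cls["g4"] == "none"

    def test_classes_partition_the_universe(self):
        cls = classify_binding(self.TARGETS, "37C", self.UNIVERSE)
        assert cls.value_counts().sum() == len(self.UNIVERSE)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            classify_binding({"37C": {"g1"}}, "37C", self.UNIVERSE)

    def test_unknown_specific_condition_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            classify_binding(self.TARGETS, "42C", self.UNIVERSE)

    def test_contingency_table_counts(self):
        cls = classify_binding(self.TARGETS, "37C", self.UNIVERSE)
        clusters = pd.Series([1, 1, 2, 2], index=self.UNIVERSE)
        table = binding_class_table(cls, clusters)
        assert table.loc[1].sum() == 2 and table.loc[2].sum() == 1


class TestMultiTfTargets:
    def test_identical_sets(self):
        out = multi_tf_targets({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert out["common"] == {"g1", "g2"}
        assert out["specific"]["A"] == set() and out["specific"]["B"] == set()

    def test_disjoint_sets(self):
        out = multi_tf_targets({"A": {"g1"}, "B": {"g2"}})
        assert out["common"] == set()
        assert out["specific"] == {"A": {"g1"}, "B": {"g2"}}

    def test_three_tf_planted_round_trip(self):
        shared, only = {"s1", "s2"}, {"A": {"a1"}, "B": {"b1", "b2"}, "C": {"c1"}}
        sets = {t: shared | only[t] for t in only}
        sets["A"] |= {"ab"}
        sets["B"] |= {"ab"}  # bound by two of three: neither common nor specific
        out = multi_tf_targets(sets)
        assert out["common"] == shared
        assert {t: out["specific"][t] for t in only} == only

    def test_fewer_than_two_tfs_rejected(self):
        with pytest.raises(ValueError):
            multi_tf_targets({"A": {"g1"}})


class TestScoreByCondition:
    def test_uniform_scores_not_significant(self):
        targets = {
            "17C": pd.DataFrame({"gene_id": ["g1", "g2"], "peak_id": ["a", "b"],
                                 "score": [5.0, 5.0], "distance": [0, 0]}),
            "37C": pd.DataFrame({"gene_id": ["g1", "g3"], "peak_id": ["c", "d"],
                                 "score": [5.0, 5.0], "distance": [0, 0]}),
        }
        cls = classify_binding(
            {c: set(t["gene_id"]) for c, t in targets.items()}, "37C",
            ["g1", "g2", "g3"],
        )
        scores = score_by_condition(targets, cls)
        groups = {
            name: g["score"].to_numpy()
            for name, g in scores.groupby("class")
        }
        res = wilcoxon_bonferroni(groups, [("other", "type_II")])
        assert res.iloc[0]["stars"] == "ns"

    def test_specific_peaks_score_above_constitutive(self, binding_data, sim_config):
        (genes_bed, _, peaks), truth = binding_data
        tf = sim_config.tfs[0]
        cond = sim_config.specific_condition
        assigned = {
            c: assign_peaks(peaks[tf][c], genes_bed, window=500)
            for c in sim_config.binding_conditions
        }
        cls = classify_binding(
            {c: set(t["gene_id"]) for c, t in assigned.items()}, cond,
            sorted(truth.cluster_of),
        )
        scores = score_by_condition(assigned, cls)
        at_specific = scores[scores["condition"] == cond]
        med = at_specific.groupby("class")["score"].median()
        assert med["type_I"] > med["type_II"]
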