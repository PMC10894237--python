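"""Spike-in scaling, differential regions, and interval operations."""

import numpy as np
import pandas as pd
import pytest

from p3fscreen.spikein_chip import (
    aggregate_by_state,
    anchored_profile,
    apply_scaling,
    differential_regions,
    nearest_gene,
    spike_scale_factors,
)
from p3fscreen.synthetic_data import RegionSimSpec, simulate_region_counts


class TestSpikeScaling:
    def test_per_million_factors(self):
        totals = pd.Series({"a": 1_000_000, "b": 2_000_000})
        factors = spike_scale_factors(totals)
        assert factors["a"] == pytest.approx(1.0)
        assert factors["b"] == pytest.approx(0.5)
        # applying the factors equalizes spike-in signal across samples
        np.testing.assert_allclose(totals * factors, 1e6, rtol=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            spike_scale_factors(pd.Series({"a": 0}))

    def test_apply_scaling_columns(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [10, 20]})
        scaled = apply_scaling(counts, pd.Series({"a": 1.0, "b": 0.5}))
        np.testing.assert_allclose(scaled["a"], [10, 20])
        np.testing.assert_allclose(scaled["b"], [5, 10])

    def test_missing_factor_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [1]})
        with pytest.raises(KeyError):
            apply_scaling(counts, pd.Series({"a": 1.0}))

    def test_global_shift_survives_spike_scaling(self):
        # a uniform 2x treated shift with equal spike totals must persist
        spec = RegionSimSpec(n_regions=2000, frac_up=0.0, global_shift=2.0,
                             seed=11)
        _, counts, spike, labels, _ = simulate_region_counts(spec)
        scaled = apply_scaling(counts, spike_scale_factors(spike))
        treated = scaled[[s for s in scaled if labels[s] == "treated"]]
        control = scaled[[s for s in scaled if labels[s] == "control"]]
        ratio = treated.to_numpy().mean() / control.to_numpy().mean()
        assert ratio == pytest.approx(2.0, rel=0.1)


def two_condition_frame(t, c):
    scaled = pd.DataFrame(np.column_stack([t, c]),
                          columns=["t1", "t2", "t3", "c1", "c2", "c3"],
                          index=[f"r{i}" for i in range(len(t))])
    labels = pd.Series({"t1": "treated", "t2": "treated", "t3": "treated",
                        "c1": "control", "c2": "control", "c3": "control"})
    return scaled, labels


class TestDifferentialRegions:
    def test_identical_conditions_no_calls(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(100, (50, 3)).astype(float)
        scaled, labels = two_condition_frame(x, x)
        calls = differential_regions(scaled, labels)
        np.testing.assert_allclose(calls["log2fc"], 0.0)
        assert (calls["direction"] == "ns").all()

    def test_constant_region_p_one(self):
        scaled, labels = two_condition_frame(np.full((3, 3), 7.0),
                                             np.full((3, 3), 7.0))
        calls = differential_regions(scaled, labels)
        np.testing.assert_allclose(calls["p"], 1.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        scaled, labels = two_condition_frame(rng.poisson(200, (100, 3)),
                                             rng.poisson(100, (100, 3)))
        fwd = differential_regions(scaled, labels)
        swapped = labels.map({"treated": "control", "control": "treated"})
        rev = differential_regions(scaled, swapped)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(2)
        scaled, labels = two_condition_frame(rng.poisson(120, (300, 3)),
                                             rng.poisson(100, (300, 3)))
        calls = differential_regions(scaled, labels).sort_values("p")
        assert (calls["padj"] >= calls["p"] - 1e-12).all()
        assert calls["padj"].is_monotonic_increasing

    def test_too_few_replicates_rejected(self):
        scaled = pd.DataFrame(np.ones((5, 2)), columns=["t1", "c1"])
        labels = pd.Series({"t1": "treated", "c1": "control"})
        with pytest.raises(ValueError, match="replicates"):
            differential_regions(scaled, labels)

    def test_planted_regions_recovered(self):
        spec = RegionSimSpec(n_regions=1000, frac_up=0.1, seed=11)
        _, counts, spike, labels, truth = simulate_region_counts(spec)
        scaled = apply_scaling(counts, spike_scale_factors(spike))
        calls = differential_regions(scaled, labels)
        planted = truth.set_index("region")["planted_up"]
        recall = (calls.loc[planted, "direction"] == "up").mean()
        assert recall >= 0.8


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestNearestGene:
    def test_containment_distance_zero(self):
        out = nearest_gene(bed([("chr1", 140, 160, "pk")]),
                           bed([("chr1", 100, 200, "gA")]))
        assert out.loc[0, "gene"] == "gA"
        assert out.loc[0, "distance"] == 0

    def test_gap_arithmetic(self):
        out = nearest_gene(bed([("chr1", 150, 151, "pk")]),
                           bed([("chr1", 0, 100, "gA"),
                                ("chr1", 400, 500, "gB")]))
        assert out.loc[0, "gene"] == "gA"
        assert out.loc[0, "distance"] == -50  # gene upstream of the peak

    def test_equidistant_tie_leftmost(self):
        out = nearest_gene(bed([("chr1", 200, 210, "pk")]),
                           bed([("chr1", 100, 150, "gB"),
                                ("chr1", 260, 300, "gA")]))
        assert out.loc[0, "tie"]
        assert out.loc[0, "gene"] == "gB"

    def test_unassigned_chromosome(self):
        out = nearest_gene(bed([("chrX", 0, 10, "pk")]),
                           bed([("chr1", 0, 10, "gA")]))
        assert not out.loc[0, "assigned"]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            peaks = bed([("c", int(s), int(s) + int(rng.integers(1, 20)),
                          f"p{i}")
                         for i, s in enumerate(rng.integers(0, 500, 8))])
            genes = bed([("c", int(s), int(s) + int(rng.integers(1, 40)),
                          f"g{i}")
                         for i, s in enumerate(rng.integers(0, 500, 6))])
            out = nearest_gene(peaks, genes)
            for _, row in out.iterrows():
                pk = peaks[peaks["name"] == row["peak"]].iloc[0]
                dists = {}
                for _, g in genes.iterrows():
                    if g.start >= pk.end:
                        d = g.start - pk.end
                    elif pk.start >= g.end:
                        d = pk.start - g.end
                    else:
                        d = 0
                    dists[g["name"]] = d
                assert abs(row["distance"]) == min(dists.values())


class TestAnchoredProfile:
    def track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def anchors(self, rows, strand=None):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        if strand is not None:
            df["strand"] = strand
        return df

    def test_uniform_track(self):
        mat, means, missing = anchored_profile(
            self.track([("c", 0, 10_000, 2.5)]),
            self.anchors([("c", 5000, 5001)]), flank=100, n_bins=10)
        np.testing.assert_allclose(mat, 2.5)
        assert not missing.any()

    def test_impulse_at_center(self):
        mat, _, _ = anchored_profile(
            self.track([("c", 0, 10_000, 0.0), ("c", 4998, 5002, 10.0)]),
            self.anchors([("c", 5000, 5001)]), flank=100, n_bins=11)
        assert mat[0].argmax() == 5  # central bin

    def test_minus_strand_mirror(self):
        track = self.track([("c", 0, 5000, 0.0), ("c", 5000, 6000, 4.0)])
        plus, _, _ = anchored_profile(track, self.anchors([("c", 5000, 5001)],
                                                          strand="+"),
                                      flank=200, n_bins=8)
        minus, _, _ = anchored_profile(track, self.anchors([("c", 5000, 5001)],
                                                           strand="-"),
                                       flank=200, n_bins=8)
        np.testing.assert_allclose(minus[0], plus[0][::-1])

    def test_missing_signal_flagged_as_zero(self):
        mat, _, missing = anchored_profile(
            self.track([("c", 0, 50, 1.0)]),
            self.anchors([("c", 100, 101)]), flank=50, n_bins=4)
        assert missing[0]
        np.testing.assert_allclose(mat[0], 0.0)

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            anchored_profile(self.track([("c", 0, 10, 1.0)]),
                             self.anchors([]), flank=10, n_bins=2)


class TestAggregateByState:
    def seg(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    def bins(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])

    def test_single_state_everything(self):
        totals, fractions, unassigned = aggregate_by_state(
            self.bins([("c", 0, 100, 10), ("c", 100, 200, 5)]),
            self.seg([("c", 0, 1000, "E1")]))
        assert fractions["E1"] == pytest.approx(1.0)
        assert unassigned == 0.0

    def test_three_state_arithmetic(self):
        totals, fractions, _ = aggregate_by_state(
            self.bins([("c", 0, 100, 10), ("c", 100, 200, 30),
                       ("c", 200, 300, 60)]),
            self.seg([("c", 0, 100, "E1"), ("c", 100, 200, "E2"),
                      ("c", 200, 300, "E3")]))
        assert fractions["E1"] == pytest.approx(0.1)
        assert fractions["E2"] == pytest.approx(0.3)
        assert fractions["E3"] == pytest.approx(0.6)

    def test_signal_conserved(self):
        rng = np.random.default_rng(4)
        edges = np.arange(0, 1100, 100)
        bins = self.bins([("c", int(a), int(b), int(v)) for a, b, v in zip(
            edges[:-1], edges[1:], rng.integers(0, 50, 10))])
        seg = self.seg([("c", 0, 450, "E1"), ("c", 450, 700, "E2")])
        totals, _, unassigned = aggregate_by_state(bins, seg)
        assert totals.sum() + unassigned == pytest.approx(
            bins["count"].sum(), abs=1e-9)

    def test_overlapping_segmentation_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            aggregate_by_state(
                self.bins([("c", 0, 10, 1)]),
                self.seg([("c", 0, 100, "E1"), ("c", 50, 150, "E2")]))
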