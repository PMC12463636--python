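"""Gating chain: debris exclusion, pseudo-Ficoll gate, marker positivity,
fixed-radius clustering against a brute-force oracle, LOD and back-gating."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrdlite.fcs_io import ChannelInfo, Sample, TUBE1_SURFACE
from mrdlite.gating import (
    BlastCall,
    ClusterConfigError,
    Gate,
    GateError,
    GateResult,
    blast_event_indices,
    brute_force_components,
    default_gates,
    exclude_debris,
    find_blast_clusters,
    fixed_radius_components,
    marker_positive,
    pseudo_ficoll_gate,
)

TUBE1_NAMES = ["FSC", "SSC", "CD45", "CD19", "CD10", "CD34"]


def tube1_sample(events):
    chans = [ChannelInfo(nm, 1000.0 if nm in ("FSC", "SSC") else 100_000.0,
                         "linear" if nm in ("FSC", "SSC") else "log10")
             for nm in TUBE1_NAMES]
    return Sample("t", TUBE1_SURFACE, np.asarray(events, dtype=float), chans)


def place_events(n, fsc=300.0, ssc=100.0, cd45=1e3, cd19=1.0, cd10=1.0, cd34=1.0,
                 jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = np.tile([fsc, ssc, cd45, cd19, cd10, cd34], (n, 1)).astype(float)
    if jitter:
        base[:, 3:] *= 10 ** rng.normal(0, jitter, size=(n, 3))
    return base


class TestScatterGates:
    def test_debris_mostly_excluded_lymph_retained(self, marrow_5pct, gate_cfg):
        t1, _, truth = marrow_5pct
        res = exclude_debris(t1, config=gate_cfg)
        debris = truth.labels_tube1 == "RBC_DEBRIS"
        lymph = truth.labels_tube1 == "LYMPH"
        assert (~res.membership[debris]).mean() >= 0.95
        assert (~res.membership[lymph]).mean() <= 0.01

    def test_full_range_gate_retains_everything(self, marrow_5pct):
        t1, _, _ = marrow_5pct
        gate = Gate("all", "FSC", "SSC", rect=(0, 1e9, 0, 1e9))
        assert exclude_debris(t1, gate=gate).n_in == t1.n_events

    def test_empty_intersection_gate(self, marrow_5pct):
        t1, _, _ = marrow_5pct
        gate = Gate("none", "FSC", "SSC", rect=(2000, 3000, 2000, 3000))
        assert exclude_debris(t1, gate=gate).n_in == 0

    def test_gate_with_absent_channel_raises(self, marrow_5pct):
        t1, _, _ = marrow_5pct
        gate = Gate("bad", "NOPE", "SSC", rect=(0, 1, 0, 1))
        with pytest.raises(GateError, match="NOPE"):
            exclude_debris(t1, gate=gate)

    def test_pseudo_ficoll_removes_neutrophils_keeps_mononuclear(
            self, marrow_5pct, gate_cfg):
        t1, _, truth = marrow_5pct
        nd = exclude_debris(t1, config=gate_cfg)
        pf = pseudo_ficoll_gate(t1, nd, config=gate_cfg)
        labels = truth.labels_tube1
        neut = labels == "NEUT"
        mono = np.isin(labels, ["LYMPH", "MONO", "BLAST"])
        assert (~pf.membership[neut]).mean() >= 0.95
        assert pf.membership[mono].mean() >= 0.97

    def test_pseudo_ficoll_on_ficoll_prepared_sample(self, pop_cfg, gate_cfg):
        from mrdlite.synthetic_marrow import (FICOLL, apply_preparation,
                                              generate_tube_pair, make_sample_spec)
        spec = apply_preparation(
            make_sample_spec(0.05, n_events=50_000, preparation=FICOLL, seed=21,
                             config=pop_cfg), config=pop_cfg)
        t1, _, truth = generate_tube_pair(spec, config=pop_cfg)
        nd = exclude_debris(t1, config=gate_cfg)
        pf = pseudo_ficoll_gate(t1, nd, config=gate_cfg)
        assert pf.n_in / nd.n_in >= 0.97

    def test_zero_parent_gives_zero(self, marrow_5pct, gate_cfg):
        t1, _, _ = marrow_5pct
        empty = GateResult("empty", np.zeros(t1.n_events, dtype=bool))
        assert pseudo_ficoll_gate(t1, empty, config=gate_cfg).n_in == 0

    def test_chain_monotonicity(self, marrow_5pct, gate_cfg):
        t1, _, _ = marrow_5pct
        nd = exclude_debris(t1, config=gate_cfg)
        pf = pseudo_ficoll_gate(t1, nd, config=gate_cfg)
        assert not (pf.membership & ~nd.membership).any()
        assert pf.n_in <= nd.n_in <= t1.n_events

    def test_polygon_gate_matches_equivalent_rect(self, marrow_5pct):
        t1, _, _ = marrow_5pct
        rect = Gate("r", "FSC", "SSC", rect=(100, 600, 0, 300))
        poly = Gate("p", "FSC", "SSC",
                    vertices=((100, 0), (600, 0), (600, 300), (100, 300)))
        np.testing.assert_array_equal(rect.contains(t1), poly.contains(t1))

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GateError, match="collinear"):
            Gate("bad", "FSC", "SSC", vertices=((0, 0), (1, 1), (2, 2)))


class TestMarkerPositive:
    def test_floor_events_all_negative(self):
        s = tube1_sample(place_events(50, cd19=1.0))
        assert marker_positive(s, "CD19", 2.5).sum() == 0

    def test_blast_vs_lymph_cd10(self, marrow_5pct, gate_cfg):
        t1, _, truth = marrow_5pct
        pos = marker_positive(t1, "CD10", gate_cfg["thresholds"]["CD10"])
        blast = truth.labels_tube1 == "BLAST"
        lymph = truth.labels_tube1 == "LYMPH"
        assert pos[blast].mean() >= 0.99
        assert pos[lymph].mean() <= 0.005

    def test_threshold_boundary_is_negative(self):
        ev = place_events(3)
        ev[:, 3] = [10 ** 2.5, 10 ** 2.5 * 1.001, 10 ** 2.4]
        s = tube1_sample(ev)
        pos = marker_positive(s, "CD19", 2.5)
        assert pos.tolist() == [False, True, False]

    def test_quantile_mode_requires_reference(self, marrow_5pct):
        t1, _, _ = marrow_5pct
        with pytest.raises(ClusterConfigError, match="reference"):
            marker_positive(t1, "CD19", {"mode": "quantile", "q": 0.995})

    def test_quantile_mode_against_reference_population(self, marrow_5pct):
        t1, _, truth = marrow_5pct
        ref = truth.labels_tube1 == "LYMPH"
        pos = marker_positive(t1, "CD19", {"mode": "quantile", "q": 0.995,
                                           "reference": ref})
        # ~0.5% of the negative reference exceeds its own 99.5% quantile
        assert 0.001 <= pos[ref].mean() <= 0.01
        assert pos[truth.labels_tube1 == "BLAST"].mean() >= 0.99


class TestClustering:
    def test_brute_force_oracle_on_hand_placed_points(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([
            rng.normal([3.5, 3.5], 0.02, size=(12, 2)),   # tight cluster
            rng.normal([3.0, 2.8], 0.02, size=(9, 2)),    # second cluster
            rng.uniform(1.0, 4.5, size=(9, 2)),            # scattered singles
        ])
        fast = fixed_radius_components(pts, 0.15)
        slow = brute_force_components(pts, 0.15)
        # same partitions (labels may differ): compare co-membership matrices
        assert ((fast[:, None] == fast[None, :]) ==
                (slow[:, None] == slow[None, :])).all()

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 80),
           st.floats(0.05, 0.6))
    def test_partition_equivalence_random(self, seed, n, radius):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 3, size=(n, 2))
        fast = fixed_radius_components(pts, radius)
        slow = brute_force_components(pts, radius)
        assert ((fast[:, None] == fast[None, :]) ==
                (slow[:, None] == slow[None, :])).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal([3.2, 3.2], 0.3, size=(400, 2))
        labels = fixed_radius_components(pts, 0.1)
        perm = rng.permutation(len(pts))
        labels_p = fixed_radius_components(pts[perm], 0.1)
        co = labels[:, None] == labels[None, :]
        co_p = labels_p[:, None] == labels_p[None, :]
        assert (co[np.ix_(perm, perm)] == co_p).all()

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ClusterConfigError):
            fixed_radius_components(np.zeros((3, 2)), 0.0)


class TestBlastClusters:
    def _sample_with_cluster(self, n_cluster, gate_cfg, extra_noise=0):
        """n_cluster tightly co-located CD19+CD10+ events on a lymphocyte
        background."""
        rng = np.random.default_rng(4)
        bg = place_events(2000, cd19=10.0, cd10=10.0, jitter=0.2, seed=1)
        cl = place_events(n_cluster, cd19=10 ** 3.5, cd10=10 ** 3.5, jitter=0.01, seed=2)
        return tube1_sample(np.vstack([bg, cl]))

    def test_ten_event_cluster_is_called(self, gate_cfg):
        s = self._sample_with_cluster(10, gate_cfg)
        nd = exclude_debris(s, config=gate_cfg)
        pf = pseudo_ficoll_gate(s, nd, config=gate_cfg)
        calls = find_blast_clusters(s, pf, config=gate_cfg)
        assert len(calls) == 1
        assert calls[0].n_cluster == 10
        assert calls[0].phenotype == "CD19_CD10"
        assert calls[0].passed_backgate

    def test_nine_event_cluster_is_not_called(self, gate_cfg):
        s = self._sample_with_cluster(9, gate_cfg)
        nd = exclude_debris(s, config=gate_cfg)
        pf = pseudo_ficoll_gate(s, nd, config=gate_cfg)
        assert find_blast_clusters(s, pf, config=gate_cfg) == []

    def test_min_cluster_below_one_rejected(self, marrow_5pct, gate_cfg):
        t1, _, _ = marrow_5pct
        nd = exclude_debris(t1, config=gate_cfg)
        pf = pseudo_ficoll_gate(t1, nd, config=gate_cfg)
        with pytest.raises(ClusterConfigError):
            find_blast_clusters(t1, pf, min_cluster=0, config=gate_cfg)

    def test_backgate_rejects_cluster_in_debris_field(self, gate_cfg):
        """A marker-positive cluster sitting at debris scatter fails the
        back-gating check when the parent does not pre-exclude debris."""
        ev = np.vstack([
            place_events(500, cd19=10.0, cd10=10.0, jitter=0.2, seed=3),
            place_events(20, fsc=40.0, ssc=30.0, cd19=10 ** 3.5, cd10=10 ** 3.5,
                         jitter=0.01, seed=4),
        ])
        s = tube1_sample(ev)
        everything = GateResult("all", np.ones(s.n_events, dtype=bool))
        assert find_blast_clusters(s, everything, config=gate_cfg) == []
        # the same cluster at mononuclear scatter is called
        ev2 = ev.copy()
        ev2[500:, 0], ev2[500:, 1] = 300.0, 100.0
        s2 = tube1_sample(ev2)
        calls = find_blast_clusters(s2, everything, config=gate_cfg)
        assert len(calls) == 1 and calls[0].n_cluster == 20

    def test_reduces_to_double_positive_count(self, marrow_5pct, gate_cfg):
        """min_cluster=1 with infinite radius counts plain double positives."""
        import copy
        t1, _, _ = marrow_5pct
        cfg = copy.deepcopy(gate_cfg)
        cfg["cluster"]["radius"] = float("inf")
        cfg["cluster"]["backgate_min_fraction"] = 0.0
        nd = exclude_debris(t1, config=cfg)
        pf = pseudo_ficoll_gate(t1, nd, config=cfg)
        calls = find_blast_clusters(t1, pf, min_cluster=1, config=cfg)
        got = blast_event_indices(calls)
        thr = cfg["thresholds"]
        cd19 = marker_positive(t1, "CD19", thr["CD19"], pf)
        expected = np.flatnonzero(cd19 & (
            marker_positive(t1, "CD10", thr["CD10"], pf)
            | marker_positive(t1, "CD34", thr["CD34"], pf)))
        np.testing.assert_array_equal(got, expected)

    def test_blast_calls_confined_to_parent(self, marrow_5pct, gate_cfg):
        t1, _, _ = marrow_5pct
        nd = exclude_debris(t1, config=gate_cfg)
        pf = pseudo_ficoll_gate(t1, nd, config=gate_cfg)
        calls = find_blast_clusters(t1, pf, config=gate_cfg)
        assert calls, "expected a blast call in the 5% sample"
        idx = blast_event_indices(calls)
        assert pf.membership[idx].all()
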