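"""Fingerprint tables: burden arithmetic, frequency ordering, submatrices."""
import numpy as np
import pytest

from connanomaly.atlas import make_atlas
from connanomaly.detect import AnomalyMatrix, Direction, EdgeStatus
from connanomaly.fingerprints import (
    BurdenRow,
    burden_profile,
    burden_table,
    edge_frequency_table,
    network_submatrix,
    round_half_up,
)
from connanomaly.normative import (
    Modality,
    NormativeReference,
    Representation,
    edge_index_pairs,
    n_edges,
)

# Published per-region structural burden rows:
# (region, n_anomalies, n_subjects, n_low_variance, total_potential, percentage)
STRUCTURAL_BURDEN_ROWS = [
    ("R_8BL", 634, 21, 218, 4578, 13.85),
    ("L_pallidum", 592, 21, 204, 4284, 13.82),
    ("R_pallidum", 694, 21, 249, 5229, 13.27),
    ("R_ventralDC", 294, 21, 112, 2352, 12.50),
    ("R_9m", 543, 21, 211, 4431, 12.25),
    ("R_caudate", 362, 21, 148, 3108, 11.65),
    ("R_10v", 714, 21, 302, 6342, 11.26),
    ("L_ventralDC", 203, 21, 87, 1827, 11.11),
    ("Brain stem", 36, 21, 16, 336, 10.71),
    ("L_putamen", 225, 21, 104, 2184, 10.30),
    ("L_thalamus", 240, 21, 114, 2394, 10.03),
    ("L_8BM", 288, 21, 143, 3003, 9.59),
    ("R_thalamus", 207, 21, 103, 2163, 9.57),
    ("R_8BM", 338, 21, 175, 3675, 9.20),
    ("L_10v", 416, 21, 230, 4830, 8.61),
    ("R_p24", 560, 21, 333, 6993, 8.01),
    ("R_OFC", 462, 21, 276, 5796, 7.97),
    ("R_cerebellum", 108, 21, 65, 1365, 7.91),
    ("R_10pp", 301, 21, 184, 3864, 7.79),
    ("R_a24", 498, 21, 307, 6447, 7.72),
    ("L_caudate", 229, 21, 142, 2982, 7.68),
    ("L_TGd", 170, 21, 106, 2226, 7.64),
    ("R_accumbens", 417, 21, 261, 5481, 7.61),
]

# Published per-region functional burden rows (19 functional subjects).
FUNCTIONAL_BURDEN_ROWS = [
    ("L_8BM", 577, 19, 377, 7163, 8.06),
    ("R_PFt", 533, 19, 360, 6840, 7.79),
    ("R_V1", 540, 19, 374, 7106, 7.60),
    ("L_9-46d", 535, 19, 379, 7201, 7.43),
    ("L_10v", 500, 19, 378, 7182, 6.96),
    ("R_hippocampus", 453, 19, 370, 7030, 6.44),
    ("L_AAIC", 437, 19, 378, 7182, 6.08),
    ("R_8BL", 389, 19, 378, 7182, 5.42),
    ("R_13l", 384, 19, 374, 7106, 5.40),
    ("L_IFJa", 318, 19, 360, 6840, 4.65),
    ("R_VMV3", 327, 19, 373, 7087, 4.61),
    ("L_PIT", 306, 19, 360, 6840, 4.47),
    ("R_MIP", 314, 19, 371, 7049, 4.45),
    ("R_PHT", 290, 19, 345, 6555, 4.42),
    ("L_IFJp", 316, 19, 376, 7144, 4.42),
    ("L_9p", 310, 19, 371, 7049, 4.40),
    ("R_PIT", 303, 19, 367, 6973, 4.35),
    ("L_s32", 289, 19, 351, 6669, 4.33),
    ("R_p24", 304, 19, 374, 7106, 4.28),
    ("L_PHA1", 289, 19, 357, 6783, 4.26),
    ("L_V4t", 290, 19, 362, 6878, 4.22),
    ("R_PoI2", 264, 19, 334, 6346, 4.16),
    ("R_2", 282, 19, 359, 6821, 4.13),
]


@pytest.mark.parametrize("row", STRUCTURAL_BURDEN_ROWS + FUNCTIONAL_BURDEN_ROWS,
                         ids=lambda r: r[0])
def test_burden_arithmetic_full_table_sweep(row):
    """Every published burden row reproduces total potential and percentage."""
    region, n_anom, n_subj, n_lowvar, total, pct = row
    br = BurdenRow(region=region, n_anomalies=n_anom,
                   n_subjects_with_anomaly=n_subj,
                   n_low_variance=n_lowvar, n_subjects=n_subj)
    assert br.total_potential == total
    assert br.percentage == pct


def test_round_half_up():
    assert round_half_up(13.845, 2) == 13.85  # half goes up, not to even
    assert round_half_up(13.8449, 2) == 13.84


# ---------------------------------------------------------------------------
# random-instance machinery shared with the brute-force oracle


def random_instance(rng, n_regions, n_subjects, modality=Modality.STRUCTURAL):
    """Random reference masks + random per-subject edge statuses."""
    m = n_edges(n_regions)
    sigma = rng.uniform(0.5, 2.0, size=m)
    sigma[rng.random(m) < 0.1] = 0.0
    fraction = rng.choice([0.0, 1 / 3, 0.5])
    variances = rng.random(m)
    from connanomaly.normative import variance_exclusion_mask
    excluded = variance_exclusion_mask(variances, fraction)
    ref = NormativeReference(
        modality=modality, representation=Representation.RAW_COUNT,
        n_regions=n_regions, n_controls=5,
        mu=np.zeros(m), sigma=sigma,
        variance_rank=np.argsort(np.argsort(-variances)),
        excluded_mask=excluded, exclusion_fraction=fraction,
    )
    anomalies = []
    for s in range(n_subjects):
        status = np.full(m, EdgeStatus.NORMAL, dtype=np.int8)
        z = np.zeros(m)
        draw = rng.random(m)
        status[draw < 0.25] = EdgeStatus.ANOMALY_LOW
        status[(draw >= 0.25) & (draw < 0.4)] = EdgeStatus.ANOMALY_HIGH
        z[status == EdgeStatus.ANOMALY_LOW] = -4.0
        z[status == EdgeStatus.ANOMALY_HIGH] = 4.0
        status[ref.degenerate_mask] = EdgeStatus.DEGENERATE
        status[ref.excluded_mask] = EdgeStatus.EXCLUDED
        z[(status == EdgeStatus.EXCLUDED) | (status == EdgeStatus.DEGENERATE)] = np.nan
        anomalies.append(AnomalyMatrix(subject_id=f"s{s}", modality=modality,
                                       status=status, zscore=z, k_sigma=3.0,
                                       n_regions=n_regions))
    return ref, anomalies


def brute_force_burden(anomalies, atlas, ref, direction):
    """Triple loop over (region, subject, edge) incidences."""
    n = len(atlas)
    i_idx, j_idx = edge_index_pairs(n)
    admits = {
        Direction.LOW: {EdgeStatus.ANOMALY_LOW},
        Direction.HIGH: {EdgeStatus.ANOMALY_HIGH},
        Direction.BOTH: {EdgeStatus.ANOMALY_LOW, EdgeStatus.ANOMALY_HIGH},
    }[direction]
    rows = {}
    for r in range(n):
        incident = [e for e in range(len(i_idx)) if r in (i_idx[e], j_idx[e])]
        retained = [e for e in incident
                    if not ref.excluded_mask[e] and ref.sigma[e] > 0]
        n_anom = 0
        subj_with = 0
        for am in anomalies:
            hits = sum(1 for e in retained if EdgeStatus(am.status[e]) in admits)
            n_anom += hits
            subj_with += hits > 0
        rows[atlas.names[r]] = (n_anom, subj_with, len(retained))
    return rows


def toy_atlas_n(n):
    lobes = ["frontal", "parietal"]
    nets = ["DMN", "CEN", "DAN"]
    return make_atlas([
        (f"{'L' if i % 2 == 0 else 'R'}_t{i:02d}", "left" if i % 2 == 0 else "right",
         "cortical", "none", lobes[i % 2], nets[i % 3])
        for i in range(n)
    ])


class TestBurdenTable:
    def test_matches_bruteforce_on_random_instances(self, rng):
        for trial in range(40):
            n = int(rng.integers(3, 7))
            ns = int(rng.integers(1, 5))
            atlas = toy_atlas_n(n)
            ref, anomalies = random_instance(rng, n, ns)
            direction = Direction(rng.choice(["low", "high", "both"]))
            rows = burden_table(anomalies, atlas, ref, direction)
            expect = brute_force_burden(anomalies, atlas, ref, direction)
            assert len(rows) == n
            for row in rows:
                e_anom, e_subj, e_low = expect[row.region]
                assert (row.n_anomalies, row.n_subjects_with_anomaly,
                        row.n_low_variance) == (e_anom, e_subj, e_low)
                assert row.total_potential == e_low * ns
            pcts = [r.percentage_exact for r in rows]
            assert pcts == sorted(pcts, reverse=True)

    def test_double_counting_identities(self, rng):
        n, ns = 6, 4
        atlas = toy_atlas_n(n)
        ref, anomalies = random_instance(rng, n, ns)
        rows = burden_table(anomalies, atlas, ref, Direction.BOTH)
        total_flagged = sum(
            int((am.anomaly_mask(Direction.BOTH) & ref.retained_mask).sum())
            for am in anomalies)
        assert sum(r.n_anomalies for r in rows) == 2 * total_flagged
        assert sum(r.n_low_variance for r in rows) == 2 * int(ref.retained_mask.sum())

    def test_no_anomalies_gives_all_zero_percentages(self, rng):
        n = 5
        atlas = toy_atlas_n(n)
        ref, anomalies = random_instance(rng, n, 2)
        for am in anomalies:
            am.status[am.status == EdgeStatus.ANOMALY_LOW] = EdgeStatus.NORMAL
            am.status[am.status == EdgeStatus.ANOMALY_HIGH] = EdgeStatus.NORMAL
        rows = burden_table(anomalies, atlas, ref, Direction.BOTH)
        assert all(r.percentage == 0.00 for r in rows)

    def test_mixed_sizes_rejected(self, rng):
        ref, a1 = random_instance(rng, 4, 1)
        _, a2 = random_instance(rng, 5, 1)
        with pytest.raises(ValueError):
            burden_table(a1 + a2, toy_atlas_n(4), ref)


class TestEdgeFrequencyTable:
    def test_edge_in_all_subjects_ranks_first(self, rng):
        n, ns = 5, 4
        atlas = toy_atlas_n(n)
        ref, anomalies = random_instance(rng, n, ns)
        # force edge 0 low in every subject, on a retained edge
        ref.excluded_mask[0] = False
        ref.sigma[0] = 1.0
        for am in anomalies:
            am.status[0] = EdgeStatus.ANOMALY_LOW
        rows = edge_frequency_table(anomalies, atlas, Direction.BOTH)
        assert rows[0].n_patients == ns
        assert {rows[0].region_a, rows[0].region_b} == {atlas.names[0], atlas.names[1]}

    def test_sorted_by_frequency_then_names(self, rng):
        n = 4
        atlas = toy_atlas_n(n)
        ref, anomalies = random_instance(rng, n, 3)
        counts = {}
        for am in anomalies:
            for e in np.flatnonzero(am.anomaly_mask(Direction.BOTH)):
                counts[e] = counts.get(e, 0) + 1
        rows = edge_frequency_table(anomalies, atlas, Direction.BOTH)
        assert len(rows) == len(counts)
        freqs = [r.n_patients for r in rows]
        assert freqs == sorted(freqs, reverse=True)
        assert sorted(counts.values(), reverse=True) == freqs

    def test_annotation_on_default_atlas(self, atlas379):
        """A flagged caudate-OFC edge carries basal-ganglia/orbitofrontal
        affiliations and the right/corticobasal class."""
        n = 379
        m = n_edges(n)
        i_idx, j_idx = edge_index_pairs(n)
        ia, ib = sorted((atlas379.index["R_caudate"], atlas379.index["R_OFC"]))
        e = int(np.flatnonzero((i_idx == ia) & (j_idx == ib))[0])
        status = np.full(m, EdgeStatus.NORMAL, dtype=np.int8)
        status[e] = EdgeStatus.ANOMALY_LOW
        am = AnomalyMatrix("p1", Modality.STRUCTURAL, status,
                           np.zeros(m), 3.0, n)
        rows = edge_frequency_table([am], atlas379, Direction.LOW)
        assert len(rows) == 1
        row = rows[0]
        assert {row.region_a, row.region_b} == {"R_caudate", "R_OFC"}
        assert {row.affiliation_a, row.affiliation_b} == {"Basal ganglia",
                                                          "Orbitofrontal"}
        assert row.edge_class.hemisphere_relation.value == "right"
        assert row.edge_class.relationship.value == "corticobasal"


class TestNetworkSubmatrix:
    def _am(self, atlas, flagged_pairs=()):
        n = len(atlas)
        m = n_edges(n)
        i_idx, j_idx = edge_index_pairs(n)
        status = np.full(m, EdgeStatus.NORMAL, dtype=np.int8)
        for a, b in flagged_pairs:
            ia, ib = sorted((atlas.index[a], atlas.index[b]))
            e = int(np.flatnonzero((i_idx == ia) & (j_idx == ib))[0])
            status[e] = EdgeStatus.ANOMALY_LOW
        return AnomalyMatrix("p", Modality.STRUCTURAL, status, np.zeros(m), 3.0, n)

    def test_member_count_defines_shape(self):
        atlas = toy_atlas_n(9)
        am = self._am(atlas)
        dmn = [r.name for r in atlas if r.network == "DMN"]
        sub = network_submatrix(am, atlas, "DMN")
        assert sub.status.shape == (len(dmn), len(dmn))
        assert sub.members == dmn

    def test_planted_edge_only_in_its_network(self):
        atlas = toy_atlas_n(9)
        dmn = [r.name for r in atlas if r.network == "DMN"]
        am = self._am(atlas, flagged_pairs=[(dmn[0], dmn[1])])
        sub = network_submatrix(am, atlas, "DMN")
        assert (sub.status == EdgeStatus.ANOMALY_LOW).sum() == 2  # symmetric pair
        for other in ("CEN", "DAN"):
            sub_o = network_submatrix(am, atlas, other)
            assert (sub_o.status == EdgeStatus.ANOMALY_LOW).sum() == 0

    def test_all_excluded_renders_as_excluded(self):
        atlas = toy_atlas_n(6)
        am = self._am(atlas)
        am.status[:] = EdgeStatus.EXCLUDED
        sub = network_submatrix(am, atlas, "DMN")
        off_diag = ~np.eye(len(sub.members), dtype=bool)
        assert (sub.status[off_diag] == EdgeStatus.EXCLUDED).all()
        assert "v" not in sub.render() and "^" not in sub.render()

    def test_singleton_network_rejected(self):
        atlas = make_atlas([
            ("L_a", "left", "cortical", "none", "frontal", "DMN"),
            ("L_b", "left", "cortical", "none", "frontal", "Solo"),
            ("R_a", "right", "cortical", "none", "frontal", "DMN"),
        ])
        am = self._am(atlas)
        with pytest.raises(ValueError, match="fewer than 2"):
            network_submatrix(am, atlas, "Solo")


def test_burden_profile_renders_every_region(rng):
    atlas = toy_atlas_n(5)
    ref, anomalies = random_instance(rng, 5, 2)
    rows = burden_table(anomalies, atlas, ref, Direction.BOTH)
    text = burden_profile(rows)
    assert all(r.region in text for r in rows)
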