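"""Diversity, pairing, sharing, publicness and downsampling metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonolink import clonotype_calling as cc, repertoire_metrics as rm, synthetic_data as sd

from conftest import make_cell, make_chain, pipeline_cells


class TestShannonAndClonality:
    def test_single_clone_has_zero_diversity(self):
        assert rm.shannon_index([17]) == 0.0

    def test_two_equal_clones_give_ln2(self):
        assert rm.shannon_index([1, 1]) == pytest.approx(np.log(2), abs=1e-12)

    def test_direct_summation_oracle(self):
        sizes = [5, 3, 2]
        expected = -sum(n / 10 * np.log(n / 10) for n in sizes)
        assert rm.shannon_index(sizes) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=100), min_size=1, max_size=50))
    def test_maximum_at_uniform_and_relabeling_invariance(self, sizes):
        h = rm.shannon_index(sizes)
        assert h <= np.log(len(sizes)) + 1e-12
        assert rm.shannon_index(sizes[::-1]) == pytest.approx(h, abs=1e-12)

    def test_clonality_curve_examples(self):
        assert rm.clonality_curve([1, 1, 1, 1]) == [
            (1, 0.25), (2, 0.5), (3, 0.75), (4, 1.0)]
        curve = rm.clonality_curve([9, 1])
        assert curve[0] == (1, 0.9) and curve[1] == (2, 1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=100), min_size=1, max_size=50))
    def test_clonality_curve_properties(self, sizes):
        curve = rm.clonality_curve(sizes)
        fracs = [f for _, f in curve]
        assert fracs[-1] == pytest.approx(1.0, abs=1e-12)
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        increments = np.diff([0.0] + fracs)
        assert all(b <= a + 1e-12 for a, b in zip(increments, increments[1:]))


def _cell(bc, alphas, betas, donor="d1", tissue="blood"):
    return make_cell(
        bc,
        [make_chain("TRA", "TRAV1-2", j, f"NT{j}{i}", f"AA{j}{i}") for i, j in alphas],
        [make_chain("TRB", v, "TRBJ2-1", f"NT{v}{i}", f"AA{v}{i}") for i, v in betas],
        donor=donor, tissue=tissue,
    )


class TestPairing:
    def test_single_clone_promiscuity_is_one(self):
        cells = [_cell(f"c{i}", [(0, "TRAJ33")], [(0, "TRBV6-1")]) for i in range(5)]
        prom = rm.chain_pairing_promiscuity(cells, "a")
        assert list(prom[("d1", "blood")].values()) == [1]

    def test_planted_promiscuous_alpha_counts_three_betas(self):
        shared = make_chain("TRA", "TRAV1-2", "TRAJ33", "NTSHARED", "AASHARED")
        cells = [
            make_cell(f"c{i}", [shared],
                      [make_chain("TRB", f"TRBV{i}", "TRBJ2-1", f"NT{i}", f"AA{i}")])
            for i in range(3)
        ]
        prom = rm.chain_pairing_promiscuity(cells, "a")
        assert prom[("d1", "blood")][shared.nt_key()] == 3

    def test_multi_alpha_cell_pairs_each_alpha(self):
        cell = _cell("c0", [(0, "TRAJ33"), (1, "TRAJ12")], [(0, "TRBV20-1")])
        table, _ = rm.traj_trbv_pairing_table([cell])
        assert set(table["traj"]) == {"TRAJ33", "TRAJ12"}
        for _, row in table.iterrows():
            assert row["TRBV20-1"] == 100.0

    def test_promiscuous_fraction_increases_with_public_sharing(self):
        fractions = []
        for n_public in (0, 10):
            cfg = sd.RepertoireConfig(
                seed=23, donors=3, clones_per_donor=50, cells_per_sample=300,
                public_alpha_count=n_public, dropout=0.0, doublet_rate=0.0,
                capture_rate=1.0,
            )
            contigs, meta, _ = sd.generate_repertoire(cfg)
            cells, _ = pipeline_cells(contigs, meta)
            fractions.append(rm.promiscuous_fraction(cells, "a", scope="global"))
        assert fractions[1] > fractions[0]

    def test_all_traj12_paired_with_trbv64(self):
        cells = [_cell(f"c{i}", [(i, "TRAJ12")], [(i, "TRBV6-4")]) for i in range(4)]
        table, _ = rm.traj_trbv_pairing_table(cells)
        row = table[table["traj"] == "TRAJ12"].iloc[0]
        assert (row["TRBV6-1"], row["TRBV6-4"], row["TRBV20-1"], row["other"]) == (0, 100, 0, 0)


class TestSegmentUsage:
    def test_single_chain(self):
        cells = [_cell("c0", [(0, "TRAJ33")], [(0, "TRBV6-1")])]
        assert rm.segment_usage(cells, "TRAJ") == {"TRAJ33": 1.0}

    def test_invariant_to_cell_order(self, clean_cells):
        cells, _ = clean_cells
        assert rm.segment_usage(cells, "TRBV") == rm.segment_usage(cells[::-1], "TRBV")

    def test_proportions_sum_to_one(self, clean_cells):
        cells, _ = clean_cells
        for segment in ("TRAJ", "TRBV"):
            assert sum(rm.segment_usage(cells, segment).values()) == pytest.approx(1.0)


class TestSharing:
    def _tables(self, cells_a, cells_b):
        return (cc.call_nucleotide_clonotypes(cells_a, "ab"),
                cc.call_nucleotide_clonotypes(cells_b, "ab"))

    def test_identical_tables_share_everything(self):
        cells = [_cell(f"c{i}", [(i % 2, "TRAJ33")], [(i % 2, "TRBV6-1")]) for i in range(6)]
        ta, tb = self._tables(cells, cells)
        res = rm.cross_sample_sharing(ta, tb)
        assert res.pct_shared_a == res.pct_shared_b == 100.0

    def test_disjoint_tables_share_nothing(self):
        a = [_cell(f"a{i}", [(i, "TRAJ33")], [(i, "TRBV6-1")]) for i in range(3)]
        b = [_cell(f"b{i}", [(i + 10, "TRAJ33")], [(i + 10, "TRBV6-1")]) for i in range(3)]
        res = rm.cross_sample_sharing(*self._tables(a, b))
        assert res.pct_shared_a == res.pct_shared_b == 0.0

    def test_level_mismatch_raises(self):
        cells = [_cell("c0", [(0, "TRAJ33")], [(0, "TRBV6-1")])]
        ta = cc.call_nucleotide_clonotypes(cells, "ab")
        tb = cc.call_functional_clonotypes(cells, "ab")
        with pytest.raises(ValueError, match="level"):
            rm.cross_sample_sharing(ta, tb)

    def test_zero_overlap_config_gives_zero_sharing(self):
        cfg = sd.RepertoireConfig(seed=9, donors=1, clones_per_donor=60,
                                  cells_per_sample=300, tissue_overlap=0.0,
                                  public_alpha_count=0, dropout=0.0,
                                  doublet_rate=0.0, capture_rate=1.0)
        contigs, meta, _ = sd.generate_repertoire(cfg)
        cells, _ = pipeline_cells(contigs, meta)
        blood = [c for c in cells if c.tissue == "blood"]
        liver = [c for c in cells if c.tissue == "liver"]
        res = rm.cross_sample_sharing(*self._tables(blood, liver))
        assert res.pct_shared_a == res.pct_shared_b == 0.0

    def test_frequency_correlation_is_one_for_identical_tables(self):
        cids = [0, 0, 0, 0, 1, 1, 1, 2, 2]
        cells = [_cell(f"c{i}", [(cid, "TRAJ33")], [(cid, "TRBV6-1")])
                 for i, cid in enumerate(cids)]
        ta, _ = self._tables(cells, cells)
        r, _ = rm.shared_clonotype_frequency_correlation(ta, ta)
        assert r == pytest.approx(1.0)

    def test_frequency_correlation_hand_computation(self):
        # 4 shared clonotypes with sizes (A) 1,2,3,4 and (B) 4,3,2,1
        a = [_cell(f"a{i}", [(cid, "TRAJ33")], [(cid, "TRBV6-1")])
             for i, cid in enumerate([0, 1, 1, 2, 2, 2, 3, 3, 3, 3])]
        b = [_cell(f"b{i}", [(cid, "TRAJ33")], [(cid, "TRBV6-1")])
             for i, cid in enumerate([0, 0, 0, 0, 1, 1, 1, 2, 2, 3])]
        r, _ = rm.shared_clonotype_frequency_correlation(*self._tables(a, b))
        x = np.log10(np.array([1, 2, 3, 4]) / 10)
        y = np.log10(np.array([4, 3, 2, 1]) / 10)
        expected = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_shared_is_undefined(self):
        a = [_cell("a0", [(0, "TRAJ33")], [(0, "TRBV6-1")])]
        r, p = rm.shared_clonotype_frequency_correlation(*self._tables(a, a))
        assert np.isnan(r) and np.isnan(p)


class TestPublicness:
    def _fn_tables(self, cells_by_donor):
        return {d: cc.call_functional_clonotypes(cells, "ab")
                for d, cells in cells_by_donor.items()}

    def test_identical_single_clonotype_everywhere(self):
        cells_by_donor = {
            d: [_cell(f"{d}c{i}", [(0, "TRAJ33")], [(0, "TRBV6-1")], donor=d) for i in range(4)]
            for d in ("d1", "d2", "d3")
        }
        report = rm.publicness_spectrum(self._fn_tables(cells_by_donor))
        for bins in report.values():
            assert bins == {1: 0, 2: 0, 3: 4}

    def test_fully_private_repertoires(self):
        cells_by_donor = {
            d: [_cell(f"{d}c{i}", [(k + i, "TRAJ33")], [(k + i, "TRBV6-1")], donor=d)
                for i in range(3)]
            for k, d in ((0, "d1"), (100, "d2"))
        }
        report = rm.publicness_spectrum(self._fn_tables(cells_by_donor))
        for bins in report.values():
            assert bins == {1: 3, 2: 0}

    def test_bin_sums_equal_cell_totals(self, clean_cells):
        cells, _ = clean_cells
        by_donor = {}
        for c in cells:
            by_donor.setdefault(c.donor, []).append(c)
        report = rm.publicness_spectrum(self._fn_tables(by_donor))
        for donor, bins in report.items():
            assert sum(bins.values()) == len(by_donor[donor])

    def test_nucleotide_tables_rejected(self):
        cells = [_cell("c0", [(0, "TRAJ33")], [(0, "TRBV6-1")])]
        with pytest.raises(ValueError, match="functional"):
            rm.publicness_spectrum({"d1": cc.call_nucleotide_clonotypes(cells, "ab")})

    def test_planted_public_alphas_recovered_in_all_donors(self):
        cfg = sd.RepertoireConfig(seed=31, donors=4, clones_per_donor=60,
                                  cells_per_sample=400, public_alpha_count=6,
                                  dropout=0.0, doublet_rate=0.0, capture_rate=1.0)
        contigs, meta, truth = sd.generate_repertoire(cfg)
        cells, _ = pipeline_cells(contigs, meta)
        by_donor = {}
        for c in cells:
            by_donor.setdefault(c.donor, []).append(c)
        tables = {d: cc.call_functional_clonotypes(cs, "a") for d, cs in by_donor.items()}
        public = rm.public_signatures(tables, min_donors=len(by_donor))
        planted = {tuple(a) for a in truth.public_alpha_aa}
        observed = {key for sig in public for key in sig}
        assert planted <= observed
        assert len(public) >= cfg.public_alpha_count


class TestDownsampling:
    def test_equal_sizes_are_not_downsampled(self):
        labels = {"d1": ([0, 0, 1, 2], [3, 3, 3, 4])}
        reps, summary = rm.downsampled_comparison(labels, seed=0, n_reps=5)
        assert (reps["n_cells"] == 4).all()
        a = summary[summary["group"] == "A"].iloc[0]
        assert a["unique_clonotypes"] == 3
        assert a["shannon"] == pytest.approx(rm.shannon_index([2, 1, 1]))

    def test_subset_with_identical_structure_shows_no_difference(self):
        rng = np.random.default_rng(0)
        big = rng.integers(0, 30, size=400)
        small = big[:200]
        reps, summary = rm.downsampled_comparison({"d1": (big, small)}, seed=1, n_reps=100)
        m = summary.set_index("group")
        assert abs(m.loc["A", "unique_clonotypes"] - m.loc["B", "unique_clonotypes"]) < 1.5

    def test_planted_evenness_detected(self):
        # A: 40 clones evenly; B: skewed
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.integers(0, 40, size=300)
            b = rng.choice(40, size=600, p=np.arange(1, 41) / np.arange(1, 41).sum())
            _, summary = rm.downsampled_comparison({"d": (a, b)}, seed=seed, n_reps=20)
            m = summary.set_index("group")
            wins += m.loc["A", "shannon"] > m.loc["B", "shannon"]
        assert wins >= 19

    def test_empty_stratum_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            reps, _ = rm.downsampled_comparison({"d": ([], [1, 2])}, n_reps=2)
        assert reps.empty


class TestCaptureRate:
    @pytest.mark.parametrize("total,with_tcr,expected", [(10, 0, 0.0), (10, 10, 1.0), (20, 7, 0.35)])
    def test_simple_ratio(self, total, with_tcr, expected):
        assert rm.tcr_capture_rate(total, with_tcr) == expected

    def test_zero_total_flagged_undefined(self):
        assert np.isnan(rm.tcr_capture_rate(0, 0))

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            rm.tcr_capture_rate(5, 6)
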