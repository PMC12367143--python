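"""Cell-scale meta-analysis: consensus densities, turnover rates,
transcriptome construction and the demand-charging simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from aakin.cellmeta import (ProteomicsMeasurement, build_transcriptome,
                            codon_usage, conc_rate_to_per_cell,
                            demand_charging_sim, turnover_rate, violin_density)
from aakin.io import make_mm_oracle_fixture
from aakin.mm import invert_mm_for_substrate


class TestViolin:
    def test_single_measurement_is_a_gaussian(self):
        v = violin_density([(5.0, 1.0)])
        assert v.peak == pytest.approx(5.0, abs=0.01)
        assert np.allclose(v.density, norm.pdf(v.grid, 5.0, 1.0), atol=1e-9)

    def test_two_component_peak_matches_analytic_mixture(self):
        v = violin_density([(4.0, 0.5), (6.0, 0.5)])
        fine = np.linspace(2, 8, 200001)
        mix = norm.pdf(fine, 4.0, 0.5) + norm.pdf(fine, 6.0, 0.5)
        assert v.peak == pytest.approx(fine[np.argmax(mix)], abs=0.02)

    def test_default_sigma_is_20_percent(self):
        m = ProteomicsMeasurement(100.0)
        assert m.sigma == pytest.approx(20.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.1, 100.0), st.floats(0.05, 20.0)),
                    min_size=1, max_size=10))
    def test_density_integrates_to_one(self, measurements):
        v = violin_density(measurements, n_grid=4000)
        assert np.trapezoid(v.density, v.grid) == pytest.approx(1.0, abs=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            violin_density([])


class TestTurnoverAndUnits:
    def test_cysrs_turnover_this_work(self):
        assert turnover_rate(2714.8, 1610) == pytest.approx(1.68, rel=0.01)

    def test_cysrs_turnover_comparison_model(self):
        assert turnover_rate(2696.6, 606) == pytest.approx(4.44, rel=0.01)

    def test_zero_usage(self):
        assert turnover_rate(0.0, 100) == 0.0

    def test_zero_enzymes_rejected(self):
        with pytest.raises(ValueError):
            turnover_rate(1.0, 0)

    def test_um_per_s_to_molecules_per_cell(self):
        assert conc_rate_to_per_cell(4.478, 1.0) == pytest.approx(2696.6, rel=1e-4)
        assert conc_rate_to_per_cell(4.508, 1.0) == pytest.approx(2714.8, rel=1e-4)
        assert conc_rate_to_per_cell(0.0, 1.0) == 0.0


class TestTranscriptome:
    def test_hand_solvable_two_mrna_case(self):
        spec = build_transcriptome({"a": 100.0, "b": 300.0},
                                   {"a": 1000.0, "b": 1000.0}, 4.0e6)
        copies = dict(zip(spec.ids, spec.copies))
        assert copies == {"a": 1000, "b": 3000}

    def test_fractions_sum_to_one_and_scale_invariance(self):
        rpkm = {"a": 10.0, "b": 1.0, "c": 250.0}
        lengths = {"a": 900.0, "b": 1500.0, "c": 300.0}
        s1 = build_transcriptome(rpkm, lengths, 1.0e6)
        s2 = build_transcriptome({k: 2 * v for k, v in rpkm.items()},
                                 lengths, 1.0e6)
        assert s1.fractions.sum() == pytest.approx(1.0)
        assert np.array_equal(s1.copies, s2.copies)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.1, 1e4), st.integers(100, 5000)),
                    min_size=2, max_size=12))
    def test_nucleotide_total_within_one_mrna_length(self, rows):
        rpkm = [r for r, _ in rows]
        lengths = [float(l) for _, l in rows]
        spec = build_transcriptome(rpkm, lengths, 5.0e6)
        assert abs(spec.total_nt - 5.0e6) <= max(lengths)

    def test_all_zero_rpkm_rejected(self):
        with pytest.raises(ValueError):
            build_transcriptome([0.0, 0.0], [100.0, 100.0], 1e6)


class TestCodonUsage:
    def test_direct_count_with_copy_weight(self):
        spec = build_transcriptome({"m": 1.0}, {"m": 6.0}, 12.0)
        res = codon_usage(spec, {"m": "ATGAAA"})
        assert res["counts"] == {"ATG": 2, "AAA": 2}
        assert sum(res["fractions"].values()) == pytest.approx(1.0)

    def test_order_invariance(self):
        rpkm = {"a": 5.0, "b": 20.0}
        lengths = {"a": 6.0, "b": 9.0}
        cds = {"a": "ATGAAA", "b": "ATGCCCGGG"}
        s1 = build_transcriptome(rpkm, lengths, 3000.0)
        s2 = build_transcriptome(dict(reversed(list(rpkm.items()))),
                                 lengths, 3000.0)
        assert codon_usage(s1, cds)["counts"] == codon_usage(s2, cds)["counts"]

    def test_non_triplet_cds_flagged(self):
        spec = build_transcriptome({"m": 1.0}, {"m": 5.0}, 10.0)
        with pytest.raises(ValueError):
            codon_usage(spec, {"m": "ATGAA"})


class _OracleModel:
    def __init__(self, kcat=10.0, km=5.0):
        self.scheme, self.rates = make_mm_oracle_fixture(kcat, km)
        self.name = "oracle"
        self.sites = 1


class TestDemandSim:
    def test_zero_demand_charges_everything(self):
        rep = demand_charging_sim([_OracleModel()], [0.0], [2000], [100],
                                  duration=40.0, seed=1)
        r = rep["per_isoacceptor"][0]
        assert r["charged_fraction"] > 0.97
        assert not r["unsustainable"]

    def test_demand_above_capacity_collapses(self):
        # capacity = kcat * copies = 1000/s; demand 3000/s
        rep = demand_charging_sim([_OracleModel()], [3000.0], [3000], [100],
                                  duration=10.0, seed=2)
        r = rep["per_isoacceptor"][0]
        assert r["unsustainable"]
        assert r["free_charged"] < 0.1 * 3000

    def test_steady_free_pool_matches_mm_inversion(self):
        """The stationary uncharged pool balances supply and demand at the
        concentration the MM inversion predicts."""
        kcat, km, copies = 10.0, 5.0, 200
        demand = 800.0  # molecules/s; r per enzyme = 4 s^-1 < kcat
        rep = demand_charging_sim([_OracleModel(kcat, km)], [demand], [6000],
                                  [copies], duration=60.0, seed=3)
        r = rep["per_isoacceptor"][0]
        expected_conc = invert_mm_for_substrate(kcat, km, demand / copies)
        expected_copies = expected_conc * 602.214  # 1 um^3 volume
        assert r["free_uncharged"] == pytest.approx(expected_copies, rel=0.10)
        assert not r["unsustainable"]

    def test_total_trna_conserved_at_every_sample(self):
        rep = demand_charging_sim([_OracleModel()], [500.0], [2000], [100],
                                  duration=10.0, seed=4)
        r = rep["per_isoacceptor"][0]
        traj = r["trajectory"]
        scheme = _OracleModel().scheme
        bound = np.array([s.ligand_multiset()["R"] + s.ligand_multiset()["R*"]
                          for s in scheme.states])
        total = traj.pool_counts[:, 4] + traj.pool_counts[:, 5] + \
            traj.state_counts @ bound
        assert np.all(total == 2000)
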