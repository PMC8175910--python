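import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import socekit as sk
from socekit.errors import ValidationError

from conftest import make_trace


def exponential_trace(protocol, tau_readd=60.0, tau_removal=50.0, dt=0.5,
                      peak=600.0, plateau=260.0, c_inf=60.0):
    """Exponential relaxations in both decay phases, flat elsewhere."""
    readd = protocol.readdition_segment
    t_rem = protocol.removal_segment.start_s

    def ca(t):
        y = np.full_like(t, 80.0)
        in_readd = (t >= readd.start_s) & (t < readd.end_s)
        y[in_readd] = plateau + (peak - plateau) * np.exp(
            -(t[in_readd] - readd.start_s) / tau_readd
        )
        post = t >= t_rem
        y[post] = c_inf + (plateau - c_inf) * np.exp(-(t[post] - t_rem) / tau_removal)
        return y

    return make_trace(protocol, ca, dt=dt)


class TestRateWithCao:
    def test_exponential_initial_slope(self, protocol):
        """|dC/dt| max of P*exp(-t/tau) is P_amp/tau at the peak."""
        tr = exponential_trace(protocol, tau_readd=60.0, peak=600.0, plateau=0.0, dt=0.5)
        rate, flags = sk.estimate_rate_with_cao(tr, protocol.readdition_segment.start_s)
        assert not flags
        assert rate == pytest.approx(600.0 / 60.0, rel=0.03)

    def test_constant_trace_rate_zero(self, protocol, trace_factory):
        tr = trace_factory(protocol, lambda t: np.full_like(t, 300.0))
        rate, flags = sk.estimate_rate_with_cao(tr, protocol.readdition_segment.start_s)
        assert rate == 0.0 and not flags

    def test_short_window_flagged(self, protocol, trace_factory):
        tr = trace_factory(protocol, lambda t: np.full_like(t, 300.0))
        rate, flags = sk.estimate_rate_with_cao(tr, peak_time=595.0)
        assert np.isnan(rate) and "short_decay_window" in flags

    def test_matches_dense_grid_net_flux(self, protocol, noiseless_params):
        """Steepest slope on the 2-s trace agrees with the dense-grid ODE
        derivative (the model's net flux) within 5%."""
        coarse = sk.simulate_cell(noiseless_params, protocol, dt=2.0)
        dense = sk.simulate_cell(noiseless_params, protocol, dt=0.2)
        m = sk.SoceMetricsExtractor(noise_sd=0.0).extract(coarse)
        rate, _ = sk.estimate_rate_with_cao(coarse, m.peak_time)
        t_rem = protocol.removal_segment.start_s
        mask = (dense.t >= m.peak_time) & (dense.t < t_rem)
        oracle = -np.gradient(dense.ca_i[mask], dense.t[mask]).min()
        assert rate == pytest.approx(oracle, rel=0.05)


class TestPostRemovalDecay:
    def test_exact_exponential_recovery(self, protocol):
        tr = exponential_trace(protocol, tau_removal=50.0, plateau=260.0, c_inf=60.0, dt=2.0)
        est = sk.estimate_post_removal_decay(tr)
        assert est.method == "exponential"
        assert est.tau == pytest.approx(50.0, rel=0.01)
        assert est.rate_post_removal == pytest.approx((260.0 - 60.0) / 50.0, rel=0.01)
        assert est.fit_rsq > 0.999

    def test_constant_segment_flagged(self, protocol, trace_factory):
        tr = trace_factory(protocol, lambda t: np.full_like(t, 120.0))
        est = sk.estimate_post_removal_decay(tr)
        assert np.isnan(est.tau)
        assert "flat_segment" in est.qc_flags

    def test_noisy_flat_segment_flagged(self, protocol, trace_factory):
        rng = np.random.default_rng(0)

        def ca(t):
            return 120.0 + rng.normal(0, 2.0, size=len(t))

        tr = trace_factory(protocol, ca)
        est = sk.estimate_post_removal_decay(tr)
        assert np.isnan(est.tau) and ("flat_decay" in est.qc_flags or "flat_segment" in est.qc_flags)

    def test_short_segment_rejected(self):
        p = sk.build_standard_protocol(removal_s=30.0)
        t = np.arange(0, 631, 10.0)
        tr = sk.CalciumTrace("c", "p", t, np.linspace(300, 100, len(t)), p)
        with pytest.raises(ValidationError):
            sk.estimate_post_removal_decay(tr)

    def test_estimators_agree_on_exponential(self, protocol):
        """Steepest-slope and exponential-fit rates agree within
        discretisation error on a noiseless exponential."""
        tr = exponential_trace(protocol, tau_removal=50.0, plateau=260.0, c_inf=60.0, dt=0.5)
        est = sk.estimate_post_removal_decay(tr)
        seg = protocol.removal_segment
        mask = protocol.segment_mask(tr.t, seg)
        from socekit.efflux import _steepest_negative_slope

        slope = _steepest_negative_slope(tr.t[mask], tr.ca_i[mask], 3)
        assert slope == pytest.approx(est.rate_post_removal, rel=0.05)


class TestIsoBinning:
    @staticmethod
    def cell_table(values, rates, populations=None, key="peak"):
        n = len(values)
        rate_col = sk.efflux.RATE_FOR_KEY[key]
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "population": populations or ["a"] * n,
                key: values,
                rate_col: rates,
            }
        )

    def test_basic_counts(self):
        table = sk.bin_iso_cells(self.cell_table([150.0, 250.0], [1.0, 2.0]),
                                 "peak", [100, 200, 300])
        assert table.summary["n"].tolist() == [1, 1]

    def test_edge_value_goes_right_bin(self):
        table = sk.bin_iso_cells(self.cell_table([200.0], [1.0]), "peak", [100, 200, 300])
        assert str(table.summary["bin"].iloc[0]) == "[200.0, 300.0)"

    def test_out_of_range_counted_not_lost(self):
        table = sk.bin_iso_cells(
            self.cell_table([50.0, 150.0, 300.0, 400.0], [1, 1, 1, 1]),
            "peak", [100, 200, 300],
        )
        assert table.n_below == 1 and table.n_dropped == 2
        assert table.n_binnable == 4

    def test_empty_table_empty_result(self):
        table = sk.bin_iso_cells(self.cell_table([], []), "peak", [0, 100])
        assert table.summary.empty and table.n_binnable == 0

    @given(st.lists(st.floats(0.0, 999.0), min_size=0, max_size=60))
    def test_binning_conserves_cells(self, values):
        table = sk.bin_iso_cells(
            self.cell_table(values, [1.0] * len(values)), "peak", [100, 300, 600]
        )
        assert len(table.cells) + table.n_below + table.n_dropped == len(values)

    def test_untested_below_min_n(self):
        df = self.cell_table(
            [150.0] * 53,
            list(np.linspace(1, 2, 53)),
            populations=["a"] * 3 + ["b"] * 50,
        )
        result = sk.compare_iso_bins(sk.bin_iso_cells(df, "peak", [100, 200]), min_n=10)
        assert result["status"].tolist() == ["untested"]

    def test_three_populations_rejected(self):
        df = self.cell_table([150.0] * 30, [1.0] * 30,
                             populations=["a", "b", "c"] * 10)
        with pytest.raises(ValidationError, match="two populations"):
            sk.compare_iso_bins(sk.bin_iso_cells(df, "peak", [100, 200]))


class TestDiscrimination:
    def test_double_pump_capacity_orders_every_bin(self, protocol):
        """Populations differing only in v_max x2: the stronger-pump
        population clears faster in every well-populated iso-bin."""
        tr_a, _ = sk.simulate_population(
            sk.PopulationSpec("a", 150, base=sk.CellParams(v_max=40)), protocol, seed=21
        )
        tr_b, _ = sk.simulate_population(
            sk.PopulationSpec("b", 150, base=sk.CellParams(v_max=80)), protocol, seed=22
        )
        traces = tr_a + tr_b
        met = sk.SoceMetricsExtractor().fit(traces).transform(traces)
        eff = sk.EffluxEstimator().fit(traces).transform(traces)
        cells = met.merge(eff.drop(columns=["population"]), on="cell_id")
        for key in ("peak", "plateau"):
            table = sk.bin_iso_cells(cells, key)
            wide = table.summary.pivot(index="bin", columns="population",
                                       values=["n", "mean_rate"])
            both = wide.dropna()
            q = both[(both[("n", "a")] >= 10) & (both[("n", "b")] >= 10)]
            assert len(q) >= 1
            assert (q[("mean_rate", "b")] > q[("mean_rate", "a")]).all()

    def test_v_max_grid_orders_matched_plateau_bins(self, protocol):
        """Mean post-removal rate at matched plateau bins is strictly
        ordered across a 0.5x / 1x / 2x pump-capacity grid."""
        frames = []
        for label, v, seed in (("half", 20.0, 31), ("one", 40.0, 32), ("two", 80.0, 33)):
            traces, _ = sk.simulate_population(
                sk.PopulationSpec(label, 80, base=sk.CellParams(v_max=v, noise_sd=0)),
                protocol, seed=seed,
            )
            met = sk.SoceMetricsExtractor(noise_sd=0.0).fit(traces).transform(traces)
            eff = sk.EffluxEstimator().fit(traces).transform(traces)
            frames.append(met.merge(eff.drop(columns=["population"]), on="cell_id"))
        cells = pd.concat(frames, ignore_index=True)
        table = sk.bin_iso_cells(cells, "plateau", np.arange(0.0, 1000.1, 100.0))
        wide = table.summary.pivot(index="bin", columns="population", values=["n", "mean_rate"])
        both = wide.dropna()
        q = both[(both["n"] >= 5).all(axis=1)]
        assert len(q) >= 1
        assert (q[("mean_rate", "one")] > q[("mean_rate", "half")]).all()
        assert (q[("mean_rate", "two")] > q[("mean_rate", "one")]).all()

    def test_no_false_positives_on_identical_populations(self, protocol):
        """Identical populations (same seed and parameters) never differ:
        across 20 replicate runs at most one run shows any significant bin."""
        bad_runs = 0
        for seed in range(20):
            tr_a, _ = sk.simulate_population(
                sk.PopulationSpec("a", 60), protocol, seed=seed
            )
            tr_b, _ = sk.simulate_population(
                sk.PopulationSpec("b", 60), protocol, seed=seed
            )
            traces = tr_a + tr_b
            met = sk.SoceMetricsExtractor().fit(traces).transform(traces)
            rows = []
            for tr, (_, m) in zip(traces, met.iterrows()):
                rate, _ = sk.estimate_rate_with_cao(tr, m["peak_time"])
                rows.append({"cell_id": m["cell_id"], "population": m["population"],
                             "peak": m["peak"], "rate_with_cao": rate})
            table = sk.bin_iso_cells(pd.DataFrame(rows), "peak")
            result = sk.compare_iso_bins(table, min_n=10)
            tested = result[result["status"] == "tested"]
            if (tested["p_value"] < 0.05).any():
                bad_runs += 1
        assert bad_runs <= 1
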