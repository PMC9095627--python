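import numpy as np
import pandas as pd
import pytest
from scipy import stats

from persist.flowio import ParseError, read_events, write_events
from persist.model import CircuitSpec, Transcript
from persist.synthetic import (Complex, EventTable, SpectralModel,
                               TransfectionDesign, UptakeModel,
                               generate_controls, render_events, sample_copies)


@pytest.fixture
def design():
    return TransfectionDesign(
        (Complex((("reporter", 0.5), ("marker", 0.5)), "tagBFP"),),
        n_events=5000)


@pytest.fixture
def marker_circuit(registry):
    tr = [Transcript(name="reporter", payload="EYFP"),
          Transcript(name="marker", payload="tagBFP")]
    return CircuitSpec(tr, {"reporter": 0.0, "marker": 0.0}, registry)


class TestSampleCopies:
    def test_untransfectable_gives_all_zero(self, design):
        up = UptakeModel(p_transfected=0.0)
        copies = sample_copies(design, up, seed=1)
        assert (copies.to_numpy() == 0).all()

    def test_perfect_correlation_without_jitter(self, design):
        up = UptakeModel(rho_within=1.0)
        copies = sample_copies(design, up, seed=1)
        sel = copies["marker"] > 0
        ratio = copies.loc[sel, "reporter"] / copies.loc[sel, "marker"]
        assert np.allclose(ratio, 1.0)

    def test_marker_tracks_payload(self, design, uptake):
        copies = sample_copies(design, uptake, seed=2)
        sel = copies["marker"] > 0
        rho = stats.spearmanr(copies.loc[sel, "marker"],
                              copies.loc[sel, "reporter"]).statistic
        assert rho >= 0.9

    def test_transfected_marginal_matches_planted_lognormal(self, uptake):
        design = TransfectionDesign(
            (Complex((("p", 0.5), ("m", 0.5)), "tagBFP"),), n_events=100_000)
        copies = sample_copies(design, uptake, seed=3)
        x = np.log(copies.loc[copies["p"] > 0, "p"])
        sigma = np.sqrt(uptake.log_sigma ** 2 + uptake.jitter_sigma ** 2)
        d = stats.kstest(x, "norm",
                         args=(uptake.log_mu + np.log(0.5), sigma)).statistic
        assert d < 0.02

    def test_reproducible_given_seed(self, design, uptake):
        a = sample_copies(design, uptake, seed=9)
        b = sample_copies(design, uptake, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestRenderEvents:
    def test_zero_copies_yields_background_only(self, marker_circuit, spectral,
                                                params):
        copies = pd.DataFrame({"reporter": np.zeros(3000),
                               "marker": np.zeros(3000)})
        ev = render_events(copies, marker_circuit, params, spectral, seed=4)
        for i, ch in enumerate(spectral.channels):
            med = np.median(ev.data[ch])
            assert med == pytest.approx(np.exp(spectral.autofluor_mu[i]), rel=0.1)

    def test_planted_bleed_visible_in_raw_channels(self, registry, params):
        sp = SpectralModel(bleed=(("EYFP", "mKO2", 0.05),), cv_meas=0.0,
                           autofluor_mu=(0.0,) * 4, autofluor_sigma=1e-9)
        copies = pd.DataFrame({"reporter": np.full(500, 100.0)})
        circ = CircuitSpec([Transcript(name="reporter", payload="EYFP")],
                           {"reporter": 0.0}, registry)
        ev = render_events(copies, circ, params, sp, seed=5)
        slope = np.median(ev.data["mKO2"] / ev.data["EYFP"])
        assert slope == pytest.approx(0.05, rel=0.05)

    def test_determinism(self, marker_circuit, spectral, params, uptake, design):
        copies = sample_copies(design, uptake, seed=6)
        a = render_events(copies, marker_circuit, params, spectral, seed=7)
        b = render_events(copies, marker_circuit, params, spectral, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_unresolvable_copy_column_rejected(self, marker_circuit, spectral,
                                               params):
        copies = pd.DataFrame({"ghost": np.ones(10)})
        with pytest.raises(ValueError, match="ghost"):
            render_events(copies, marker_circuit, params, spectral, seed=1)


class TestControls:
    def test_untransfected_is_background(self, comp_ctx, spectral):
        untr = comp_ctx.controls["untransfected"]
        for i, ch in enumerate(spectral.channels):
            assert np.median(untr.data[ch]) < 3 * np.exp(spectral.autofluor_mu[i])

    def test_single_color_spans_three_decades(self, comp_ctx, spectral):
        for ch in spectral.channels:
            x = comp_ctx.controls[ch].data[ch]
            assert np.percentile(x, 99.5) / np.percentile(x, 2) > 1e3

    def test_minimum_event_count(self, comp_ctx):
        for table in comp_ctx.controls.values():
            assert len(table) >= 1000


class TestEventIO:
    def _table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.lognormal(3, 1, size=(n, 4)),
                          columns=["tagBFP", "EYFP", "mKO2", "iRFP720"])
        return EventTable(df, {"design": "unit-test", "seed": seed})

    def test_csv_roundtrip_bit_exact(self, tmp_path):
        t = self._table()
        path = tmp_path / "ev.csv"
        write_events(t, path, "csv")
        back = read_events(path)
        pd.testing.assert_frame_equal(back.data, t.data)
        assert back.metadata["design"] == "unit-test"

    def test_fcs_roundtrip_structure_and_values(self, tmp_path):
        t = self._table()
        path = tmp_path / "ev.fcs"
        write_events(t, path, "fcs")
        back = read_events(path)
        assert back.channels == t.channels
        assert len(back) == len(t)
        np.testing.assert_allclose(back.data.to_numpy(), t.data.to_numpy(),
                                   rtol=1e-6)

    def test_truncated_fcs_reports_byte_position(self, tmp_path):
        t = self._table()
        path = tmp_path / "ev.fcs"
        write_events(t, path, "fcs")
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 2])
        with pytest.raises(ParseError, match="byte"):
            read_events(path)

    def test_truncated_csv_reports_line(self, tmp_path):
        t = self._table()
        path = tmp_path / "ev.csv"
        write_events(t, path, "csv")
        lines = path.read_text().splitlines()
        lines[50] = "1.0,2.0"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="line"):
            read_events(path)

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_events(self._table(), tmp_path / "x", "xlsx")


class TestValidation:
    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Complex((("a", 0.5), ("b", 0.3)), "tagBFP")

    def test_duplicate_markers_rejected(self):
        c = Complex((("a", 1.0),), "tagBFP")
        with pytest.raises(ValueError):
            TransfectionDesign((c, c))

    def test_rho_within_range(self):
        with pytest.raises(ValueError):
            UptakeModel(rho_within=0.5)

    def test_non_finite_events_rejected(self):
        df = pd.DataFrame({"EYFP": [1.0, np.nan]})
        with pytest.raises(ValueError):
            EventTable(df)
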