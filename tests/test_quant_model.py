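import logging

import pandas as pd
import pytest

import phosstoich as ps
from phosstoich.quant_model import (
    NoSignalError,
    PeakReportError,
    aggregate_charge_areas,
    pair_cognates,
    read_peak_report,
    screen_phosphospecies,
    write_peak_report,
)


def _pair(site, dephos, phos, charges):
    return ps.CognatePair(
        site_label=site,
        dephos=ps.parse_peptide_string(dephos),
        phos=ps.parse_peptide_string(phos),
        charges_used=frozenset(charges),
    )


@pytest.fixture()
def shared_isomer_pairs():
    """S477 and T481: two phosphosites on one tryptic peptide."""
    return [
        _pair("α1-S477", "SGTATPQR", "S[+80]GTATPQR", {2}),
        _pair("α1-T481", "SGTATPQR", "SGTAT[+80]PQR", {2}),
    ]


def _report(rows):
    return pd.DataFrame(
        rows, columns=["species", "charge", "sample", "replicate", "area"]
    )


class TestReadWrite:
    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("species,charge,sample,replicate,area\n")
        assert read_peak_report(path).empty

    def test_single_row_passthrough(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "species,charge,sample,replicate,area\nSGTATPQR,2,basal,1,1e6\n"
        )
        df = read_peak_report(path)
        row = df.iloc[0]
        assert (row["species"], row["charge"], row["sample"], row["replicate"]) == (
            "SGTATPQR", 2, "basal", 1,
        )
        assert row["area"] == 1e6

    def test_roundtrip_byte_identical_on_synthetic_report(self, tmp_path):
        cfg = ps.table2_like_config(noise_cv=0.1, n_replicates=1, seed=5)
        report, _ = ps.simulate_peak_report(cfg)
        report = report.head(50)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_peak_report(report, p1)
        write_peak_report(read_peak_report(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_rejects_missing_column(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("species,charge,sample,area\nSGTATPQR,2,basal,1\n")
        with pytest.raises(PeakReportError, match="missing columns"):
            read_peak_report(path)

    def test_rejects_negative_area_and_duplicate_key(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "species,charge,sample,replicate,area\nSGTATPQR,2,basal,1,-5\n"
        )
        with pytest.raises(PeakReportError, match="negative area"):
            read_peak_report(path)
        path.write_text(
            "species,charge,sample,replicate,area\n"
            "SGTATPQR,2,basal,1,5\nSGTATPQR,2,basal,1,6\n"
        )
        with pytest.raises(PeakReportError, match="duplicate"):
            read_peak_report(path)


class TestChargeAggregation:
    def test_single_charge_unchanged(self):
        pair = _pair("s", "SGTATPQR", "S[+80]GTATPQR", {2})
        rep = _report(
            [
                ("SGTATPQR", 2, "basal", 1, 100.0),
                ("S[+80]GTATPQR", 2, "basal", 1, 40.0),
            ]
        )
        assert aggregate_charge_areas(rep, pair, "basal", 1) == (100.0, 40.0)

    def test_sum_over_charges(self):
        pair = _pair("s", "SGTATPQR", "S[+80]GTATPQR", {2, 3})
        rep = _report(
            [
                ("SGTATPQR", 2, "basal", 1, 100.0),
                ("SGTATPQR", 3, "basal", 1, 50.0),
                ("S[+80]GTATPQR", 2, "basal", 1, 10.0),
                ("S[+80]GTATPQR", 3, "basal", 1, 5.0),
            ]
        )
        assert aggregate_charge_areas(rep, pair, "basal", 1) == (150.0, 15.0)

    def test_missing_charge_contributes_zero_with_warning(self, caplog):
        pair = _pair("s", "SGTATPQR", "S[+80]GTATPQR", {2, 3})
        rep = _report(
            [
                ("SGTATPQR", 2, "basal", 1, 100.0),
                ("S[+80]GTATPQR", 2, "basal", 1, 10.0),
                ("S[+80]GTATPQR", 3, "basal", 1, 2.0),
            ]
        )
        with caplog.at_level(logging.WARNING, logger="phosstoich.quant_model"):
            i_p, i_pp = aggregate_charge_areas(rep, pair, "basal", 1)
        assert (i_p, i_pp) == (100.0, 12.0)
        assert any("charge 3+" in r.message for r in caplog.records)

    def test_no_signal_names_the_species(self):
        pair = _pair("s", "SGTATPQR", "S[+80]GTATPQR", {2})
        rep = _report([("SGTATPQR", 2, "basal", 1, 100.0)])
        with pytest.raises(NoSignalError, match=r"S\[\+80\]GTATPQR"):
            aggregate_charge_areas(rep, pair, "basal", 1)

    def test_permutation_invariant(self):
        pair = _pair("s", "SGTATPQR", "S[+80]GTATPQR", {1, 2, 3})
        rows = [
            ("SGTATPQR", z, "basal", 1, a)
            for z, a in [(1, 7.0), (2, 100.0), (3, 50.0)]
        ] + [("S[+80]GTATPQR", 2, "basal", 1, 1.0)]
        fwd = aggregate_charge_areas(_report(rows), pair, "basal", 1)
        rev = aggregate_charge_areas(_report(rows[::-1]), pair, "basal", 1)
        assert fwd == rev == (157.0, 1.0)


class TestScreening:
    def test_diphospho_below_threshold_excluded(self):
        report = screen_phosphospecies(
            {"S[+80]GTATPQR": 100.0, "S[+80]GTAT[+80]PQR": 8.0}
        )
        assert [s for s, *_ in report.excluded] == ["S[+80]GTAT[+80]PQR"]
        assert "<10%" in report.excluded[0][2]

    def test_mono_only_all_retained(self):
        report = screen_phosphospecies(
            {"S[+80]GTATPQR": 100.0, "SGTAT[+80]PQR": 30.0}
        )
        assert len(report.retained) == 2
        assert report.excluded == []

    def test_diphospho_at_threshold_boundary_needs_review(self):
        report = screen_phosphospecies(
            {"S[+80]GTATPQR": 100.0, "S[+80]GTAT[+80]PQR": 15.0}
        )
        assert [s for s, *_ in report.needs_review] == ["S[+80]GTAT[+80]PQR"]
        assert any(s == "S[+80]GTAT[+80]PQR" for s, _ in report.retained)

    def test_mono_species_never_removed_and_threshold_monotone(self):
        species = {"S[+80]GTATPQR": 100.0, "SGTAT[+80]PQR": 1.0,
                   "S[+80]GTAT[+80]PQR": 5.0}
        excluded_by_threshold = [
            len(screen_phosphospecies(species, threshold=t).excluded)
            for t in (0.01, 0.10, 0.50)
        ]
        assert excluded_by_threshold == sorted(excluded_by_threshold)
        for t in (0.01, 0.10, 0.50):
            retained = [s for s, _ in screen_phosphospecies(species, threshold=t).retained]
            assert "S[+80]GTATPQR" in retained and "SGTAT[+80]PQR" in retained

    def test_requires_mono_species(self):
        with pytest.raises(ValueError, match="mono-phospho"):
            screen_phosphospecies({"S[+80]GTAT[+80]PQR": 5.0})


class TestPairCognates:
    def test_positional_isomers_share_dephospho_denominator(self, shared_isomer_pairs):
        rep = _report(
            [
                ("SGTATPQR", 2, "basal", 1, 200.0),
                ("S[+80]GTATPQR", 2, "basal", 1, 30.0),
                ("SGTAT[+80]PQR", 2, "basal", 1, 10.0),
            ]
        )
        out = pair_cognates(rep, shared_isomer_pairs)
        assert len(out) == 2
        assert set(out["I_P"]) == {200.0}
        assert set(out["I_pP"]) == {30.0, 10.0}

    def test_one_row_per_replicate(self):
        pair = _pair("s", "SGTATPQR", "S[+80]GTATPQR", {2})
        rep = _report(
            [
                ("SGTATPQR", 2, "basal", r, 100.0 + r)
                for r in (1, 2, 3)
            ]
            + [("S[+80]GTATPQR", 2, "basal", r, 10.0) for r in (1, 2, 3)]
        )
        out = pair_cognates(rep, [pair])
        assert len(out) == 3
        assert sorted(out["replicate"]) == [1, 2, 3]

    def test_matches_generator_ledger(self, noiseless_config):
        report, ledger = ps.simulate_peak_report(noiseless_config)
        out = pair_cognates(report, noiseless_config.cognate_pairs())
        n_sites = len(noiseless_config.sites)
        assert len(out) == n_sites * len(noiseless_config.samples) * 3
        # spot-check one site against the ledger's construction
        site = noiseless_config.sites[-1]
        sample = noiseless_config.samples[0]
        row = out[(out["site_label"] == site.site_label) & (out["sample"] == sample)].iloc[0]
        theta = site.theta[sample]
        assert row["I_P"] == pytest.approx(site.total_amount * (1 - theta), rel=1e-12)
        assert row["I_pP"] == pytest.approx(
            site.total_amount * theta / site.flyability, rel=1e-12
        )

    def test_zero_total_signal_is_error(self):
        pair = _pair("s", "SGTATPQR", "S[+80]GTATPQR", {2})
        rep = _report(
            [
                ("SGTATPQR", 2, "basal", 1, 0.0),
                ("S[+80]GTATPQR", 2, "basal", 1, 0.0),
            ]
        )
        with pytest.raises(NoSignalError):
            pair_cognates(rep, [pair])

    def test_joint_mode_augments_denominator(self, shared_isomer_pairs):
        rep = _report(
            [
                ("SGTATPQR", 2, "basal", 1, 200.0),
                ("S[+80]GTATPQR", 2, "basal", 1, 30.0),
                ("SGTAT[+80]PQR", 2, "basal", 1, 10.0),
            ]
        )
        out = pair_cognates(rep, shared_isomer_pairs, joint_isomers=True)
        s477 = out[out["site_label"] == "α1-S477"].iloc[0]
        assert s477["I_P"] == 210.0  # 200 + sibling's 10
        assert s477["I_pP"] == 30.0


def test_cognate_pair_validation():
    with pytest.raises(ValueError, match="identical residue sequence"):
        _pair("s", "SGTATPQR", "S[+80]GSVSNYR", {2})
    with pytest.raises(ValueError, match="exactly one more phosphate"):
        _pair("s", "SGTATPQR", "S[+80]GTAT[+80]PQR", {2})
    with pytest.raises(ValueError, match="charges_used is empty"):
        _pair("s", "SGTATPQR", "S[+80]GTATPQR", set())


def test_builtin_targets_table(builtin_pairs):
    pairs, flyability = builtin_pairs
    assert len(pairs) == 19
    assert len(flyability) == 19
    assert min(flyability.values()) == pytest.approx(0.58)
    assert max(flyability.values()) == pytest.approx(12.22)
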