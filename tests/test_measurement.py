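import math

import pytest
from hypothesis import given, settings, strategies as st

from rdcfit import (
    Condition,
    ExclusionReason,
    Method,
    Peak,
    RdcDataset,
    RdcRecord,
    filter_rdcs,
    peak_position_uncertainty,
    rdc_from_splittings,
    read_pales_table,
    read_rdc_table,
    splitting_from_hsqc_trosy,
    splitting_from_ipap,
    write_rdc_table,
)
from rdcfit.measurement import MeasurementError


def peak(residue=1, nu=0.0, sn=10.0, lw=10.0, overlapped=False):
    return Peak(residue=residue, nu15N=nu, SN=sn, LW=lw, overlapped=overlapped)


class TestPositionUncertainty:
    @pytest.mark.parametrize(
        "lw, sn, expected", [(10, 10, 0.5), (11, 55, 0.1), (11, 1, 5.5)]
    )
    def test_formula(self, lw, sn, expected):
        assert peak_position_uncertainty(lw, sn) == pytest.approx(expected)

    @pytest.mark.parametrize("lw, sn", [(10, 0), (0, 10), (-1, 5), (5, -1)])
    def test_nonpositive_inputs_error(self, lw, sn):
        with pytest.raises(MeasurementError):
            peak_position_uncertainty(lw, sn)


class TestHsqcTrosySplitting:
    def test_factor_of_two(self):
        m = splitting_from_hsqc_trosy(
            peak(nu=0.0), peak(nu=-46.5), Condition.ISOTROPIC
        )
        assert m.splitting == pytest.approx(-93.0)

    def test_identical_positions_give_zero(self):
        m = splitting_from_hsqc_trosy(peak(nu=5.0), peak(nu=5.0), "anisotropic")
        assert m.splitting == 0.0

    def test_uncertainty_propagation(self):
        m = splitting_from_hsqc_trosy(peak(), peak(), Condition.ISOTROPIC)
        # sigma_v = 0.5 each, doubled and combined in quadrature
        assert m.sigma == pytest.approx(2 * 0.5 * math.sqrt(2))

    def test_residue_mismatch_errors(self):
        with pytest.raises(MeasurementError, match="mismatch"):
            splitting_from_hsqc_trosy(
                peak(residue=1), peak(residue=2), Condition.ISOTROPIC
            )


class TestIpapSplitting:
    def test_component_difference(self):
        m = splitting_from_ipap(peak(nu=-46.5), peak(nu=46.5), Condition.ISOTROPIC)
        assert m.splitting == pytest.approx(93.0)

    def test_coincident_components_zero(self):
        m = splitting_from_ipap(peak(nu=1.0), peak(nu=1.0), Condition.ISOTROPIC)
        assert m.splitting == 0.0

    def test_uncertainty_propagation(self):
        m = splitting_from_ipap(peak(), peak(), Condition.ANISOTROPIC)
        assert m.sigma == pytest.approx(0.5 * math.sqrt(2))


class TestRdcFromSplittings:
    def split(self, value, condition, sigma_sn=10.0):
        return splitting_from_hsqc_trosy(
            peak(nu=0.0, sn=sigma_sn), peak(nu=value / 2.0, sn=sigma_sn), condition
        )

    def test_difference_of_splittings(self):
        rec = rdc_from_splittings(
            self.split(-93.0, Condition.ISOTROPIC),
            self.split(-85.0, Condition.ANISOTROPIC),
        )
        assert rec.D == pytest.approx(8.0)

    def test_equal_splittings_give_zero(self):
        rec = rdc_from_splittings(
            self.split(-93.0, Condition.ISOTROPIC),
            self.split(-93.0, Condition.ANISOTROPIC),
        )
        assert rec.D == pytest.approx(0.0)

    def test_sigma_quadrature(self):
        iso = self.split(-93.0, Condition.ISOTROPIC)
        aniso = self.split(-85.0, Condition.ANISOTROPIC)
        rec = rdc_from_splittings(iso, aniso)
        assert rec.sigma_D == pytest.approx(math.hypot(iso.sigma, aniso.sigma))

    def test_method_mismatch_errors(self):
        iso = splitting_from_ipap(peak(nu=-46.5), peak(nu=46.5), Condition.ISOTROPIC)
        aniso = self.split(-85.0, Condition.ANISOTROPIC)
        with pytest.raises(MeasurementError, match="method"):
            rdc_from_splittings(iso, aniso)


class TestFilters:
    def dataset(self):
        return RdcDataset(
            records=[
                RdcRecord(residue=1, D=5.0, sigma_D=6.0),  # sigma too large
                RdcRecord(residue=2, D=5.0, sigma_D=1.0),  # flexible (S2=0.80)
                RdcRecord(residue=3, D=5.0, sigma_D=1.0),  # exchange
                RdcRecord(residue=4, D=5.0, sigma_D=1.0, overlapped=True),
                RdcRecord(residue=5, D=5.0, sigma_D=5.0),  # boundary: retained
                RdcRecord(residue=6, D=5.0, sigma_D=1.0),  # clean
            ]
        )

    def test_exclusion_reasons(self):
        out = filter_rdcs(
            self.dataset(),
            s2_by_residue={2: 0.80, 5: 0.9, 6: 0.95},
            exchange_residues={3},
        )
        by = out.by_residue(include_excluded=True)
        assert by[1].reason is ExclusionReason.SIGMA_TOO_LARGE
        assert by[2].reason is ExclusionReason.FLEXIBLE
        assert by[3].reason is ExclusionReason.EXCHANGE
        assert by[4].reason is ExclusionReason.OVERLAP
        assert not by[5].excluded  # sigma_D = 5.0 exactly: strict inequality
        assert not by[6].excluded

    def test_boundary_s2_retained(self):
        out = filter_rdcs(self.dataset(), s2_by_residue={6: 0.85})
        assert not out.by_residue(include_excluded=True)[6].excluded

    def test_priority_flexible_beats_sigma(self):
        ds = RdcDataset(records=[RdcRecord(residue=1, D=1.0, sigma_D=9.0)])
        out = filter_rdcs(ds, s2_by_residue={1: 0.5})
        assert out.records[0].reason is ExclusionReason.FLEXIBLE

    def test_idempotent(self):
        kwargs = dict(s2_by_residue={2: 0.80}, exchange_residues={3})
        once = filter_rdcs(self.dataset(), **kwargs)
        twice = filter_rdcs(once, **kwargs)
        assert once.records == twice.records

    def test_rms_sigma_over_survivors(self):
        out = filter_rdcs(self.dataset())
        included = [r.sigma_D for r in out.included]
        expected = math.sqrt(sum(s**2 for s in included) / len(included))
        assert out.rms_sigma == pytest.approx(expected)
        assert 1 not in {r.residue for r in out.included}

    @settings(max_examples=30, deadline=None)
    @given(
        s2_min=st.floats(min_value=0.5, max_value=1.0),
        s2_min_higher=st.floats(min_value=0.0, max_value=0.4),
        sigma_max=st.floats(min_value=0.5, max_value=8.0),
        sigma_extra=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_survivors_monotone_in_thresholds(
        self, s2_min, s2_min_higher, sigma_max, sigma_extra
    ):
        ds = self.dataset()
        s2 = {2: 0.80, 3: 0.99, 6: 0.92}
        n = len(filter_rdcs(ds, s2, s2_min=s2_min, sigma_max=sigma_max).included)
        n_stricter_s2 = len(
            filter_rdcs(ds, s2, s2_min=s2_min + s2_min_higher, sigma_max=sigma_max).included
        )
        n_looser_sigma = len(
            filter_rdcs(ds, s2, s2_min=s2_min, sigma_max=sigma_max + sigma_extra).included
        )
        assert n_stricter_s2 <= n
        assert n_looser_sigma >= n


class TestTables:
    def test_rdc_table_round_trip(self, tmp_path):
        ds = filter_rdcs(
            RdcDataset(
                records=[
                    RdcRecord(residue=1, D=8.25, sigma_D=1.5),
                    RdcRecord(residue=2, D=-3.5, sigma_D=7.0),
                ]
            )
        )
        p = tmp_path / "rdc.tsv"
        write_rdc_table(ds, p, comment="test")
        back = read_rdc_table(p)
        assert [r.residue for r in back.records] == [1, 2]
        assert back.records[0].D == pytest.approx(8.25)
        assert back.records[1].excluded
        assert back.records[1].reason is ExclusionReason.SIGMA_TOO_LARGE

    def test_pales_dialect_reader(self, tmp_path):
        p = tmp_path / "dc.tab"
        p.write_text(
            "DATA SEQUENCE MAKE\n"
            "VARS RESID_I RESNAME_I ATOMNAME_I RESID_J RESNAME_J ATOMNAME_J D DD W\n"
            "FORMAT %5d %6s %6s %5d %6s %6s %9.3f %9.3f %.2f\n"
            "    2    ALA      H     2    ALA      N    8.120     1.100 1.00\n"
            "    3    LYS      H     3    LYS      N   -4.250     0.900 0.00\n"
        )
        ds = read_pales_table(p)
        assert len(ds.records) == 2
        assert ds.records[0].D == pytest.approx(8.12)
        assert ds.records[0].sigma_D == pytest.approx(1.1)
        assert not ds.records[0].excluded
        assert ds.records[1].excluded
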