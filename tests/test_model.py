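import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmacomp import (
    ModelParameters,
    conservation_residuals,
    ode_oracle,
    solve_full_model,
    solve_holoenzyme_model,
    transcription_rates,
)


def binding_quadratic(a_total, b_total, K):
    """Closed-form complex concentration for a single 1:1 binding reaction.

    Independent oracle: AB solves AB^2 - (At + Bt + K) AB + At Bt = 0,
    taking the root that keeps both free concentrations nonnegative.
    """
    s = a_total + b_total + K
    return (s - math.sqrt(s * s - 4 * a_total * b_total)) / 2


def species_rel_dev(a, b, floor_frac=1e-9):
    sa, sb = a.species(), b.species()
    scale = max(sa.values()) or 1.0
    return max(abs(sa[k] - sb[k]) / max(sa[k], floor_frac * scale) for k in sa)


class TestHoloenzymeModel:
    def test_reduces_to_single_binding_quadratic(self):
        # only E and sigma70 present: the network is one binding reaction
        p = ModelParameters(
            Rsd_total=0.0, RNA6S_total=0.0, sigma38_total=0.0,
            E_total=4.3, sigma70_total=12.0,
        )
        st_ = solve_holoenzyme_model(p)
        expected = binding_quadratic(4.3e-6, 12.0e-6, 3.3e-9)
        assert st_.E_sigma70 == pytest.approx(expected, rel=1e-10)
        assert st_.Rsd_sigma70 == 0.0 and st_.c6S_E_sigma70 == 0.0

    def test_empty_system_is_all_zero(self):
        p = ModelParameters(
            E_total=0, sigma70_total=0, sigma38_total=0, Rsd_total=0, RNA6S_total=0
        )
        st_ = solve_holoenzyme_model(p)
        assert all(v == 0.0 for v in st_.species().values())
        assert st_.residual_norm == 0.0

    def test_root_matches_ode_oracle_at_defaults(self, params):
        root = solve_holoenzyme_model(params)
        ode = ode_oracle(params, "holoenzyme")
        assert root.method == "root"
        assert species_rel_dev(root, ode) <= 1e-6

    def test_conservation_residuals_tiny(self, params):
        st_ = solve_holoenzyme_model(params)
        assert max(conservation_residuals(st_, params).values()) <= 1e-8

    def test_all_species_nonnegative(self, params):
        assert all(v >= 0 for v in solve_holoenzyme_model(params).species().values())

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        e=st.floats(0.0, 50.0),
        s70=st.floats(0.0, 50.0),
        s38=st.floats(0.0, 50.0),
        rsd=st.floats(0.0, 50.0),
        x6=st.floats(0.0, 50.0),
    )
    def test_conservation_holds_for_arbitrary_totals(self, e, s70, s38, rsd, x6):
        p = ModelParameters(
            E_total=e, sigma70_total=s70, sigma38_total=s38, Rsd_total=rsd, RNA6S_total=x6
        )
        st_ = solve_holoenzyme_model(p)
        assert max(conservation_residuals(st_, p).values()) <= 1e-8
        assert all(v >= 0 for v in st_.species().values())

    def test_zero_dissociation_constant_rejected(self, params):
        with pytest.raises(ValueError, match="K_Rsd"):
            solve_holoenzyme_model(params.replace(K_Rsd=0.0))


class TestOdeOracle:
    def test_on_rate_does_not_change_equilibrium(self, params):
        a = ode_oracle(params, "holoenzyme", kon=1e6)
        b = ode_oracle(params, "holoenzyme", kon=2e6)
        assert species_rel_dev(a, b) <= 1e-6

    def test_zero_totals_give_zero_state(self):
        p = ModelParameters(
            E_total=0, sigma70_total=0, sigma38_total=0, Rsd_total=0, RNA6S_total=0
        )
        st_ = ode_oracle(p, "holoenzyme")
        assert all(v == 0.0 for v in st_.species().values())

    def test_unknown_variant_rejected(self, params):
        with pytest.raises(ValueError):
            ode_oracle(params, "with_dna")


class TestFullModel:
    def test_no_promoters_means_no_transcription(self, params):
        st_ = solve_full_model(params.replace(P70_count=0.0, P38_count=0.0))
        assert st_.rate70 == 0.0 and st_.rate38 == 0.0
        assert st_.E_sigma70_P70 == 0.0 and st_.Ee38 == 0.0

    def test_conservation_residuals_tiny(self, params):
        st_ = solve_full_model(params)
        assert max(conservation_residuals(st_, params).values()) <= 1e-8

    def test_flux_balance_clearance_equals_completion(self, params):
        st_ = solve_full_model(params)
        c, e = params.clearance_rate_c, params.elongation_escape_rate_e
        assert abs(c * st_.E_sigma70_P70 - e * st_.Ee70) <= 1e-8 * st_.rate70
        assert abs(c * st_.E_sigma38_P38 - e * st_.Ee38) <= 1e-8 * st_.rate38

    def test_halving_clearance_lowers_both_rates(self, params):
        base = solve_full_model(params)
        slow = solve_full_model(params.replace(clearance_rate_c=params.clearance_rate_c / 2))
        assert slow.rate70 < base.rate70
        assert slow.rate38 < base.rate38

    def test_root_matches_ode_route(self, params):
        # the kinetic route carries a small O(c/(kon*K)) perturbation of the
        # promoter equilibria, so agreement is looser than for the pure
        # binding network
        root = solve_full_model(params)
        ode = ode_oracle(params, "full")
        assert species_rel_dev(root, ode) <= 5e-3
        assert ode.rate38 == pytest.approx(root.rate38, rel=1e-2)

    def test_transcription_rates_accessor(self, params):
        st_ = solve_full_model(params)
        r70, r38 = transcription_rates(st_)
        assert r70 == st_.rate70 and r38 == st_.rate38
        with pytest.raises(ValueError):
            transcription_rates(solve_holoenzyme_model(params))

    def test_unbounded_elongation_pool_rejected(self, params):
        with pytest.raises(ValueError):
            solve_full_model(params.replace(elongation_escape_rate_e=0.0))


class TestCompetitionProperties:
    """Qualitative behavior of holoenzyme partitioning."""

    def test_rsd_shifts_partition_toward_sigma38(self, params):
        # without 6S RNA, Rsd sequesters sigma70: E.sigma70 falls and
        # E.sigma38 rises as total Rsd increases
        grid = np.linspace(0.0, 20.0, 21)
        states = [
            solve_holoenzyme_model(params.replace(RNA6S_total=0.0, Rsd_total=r))
            for r in grid
        ]
        e70 = np.array([s.E_sigma70 for s in states])
        e38 = np.array([s.E_sigma38 for s in states])
        assert np.all(np.diff(e70) <= 0)
        assert np.all(np.diff(e38) >= 0)

    def test_6s_rna_buffers_the_holoenzyme_against_rsd(self, params):
        # with 6S RNA present, the 6S-bound holoenzyme pool releases
        # E.sigma70 as Rsd rises, damping the change in free holoenzyme
        grid = np.linspace(0.0, 20.0, 21)
        without = [
            solve_holoenzyme_model(params.replace(RNA6S_total=0.0, Rsd_total=r))
            for r in grid
        ]
        with6s = [solve_holoenzyme_model(params.replace(Rsd_total=r)) for r in grid]
        span = lambda sts: abs(sts[0].E_sigma70 - sts[-1].E_sigma70)
        assert span(with6s) < span(without)
        complex6s = np.array([s.c6S_E_sigma70 for s in with6s])
        assert np.all(np.diff(complex6s) <= 0)

    def test_6s_rna_lowers_both_transcription_rates(self, params):
        grid = np.linspace(0.0, 26.0, 14)
        states = [solve_full_model(params.replace(RNA6S_total=x)) for x in grid]
        r70 = np.array([s.rate70 for s in states])
        r38 = np.array([s.rate38 for s in states])
        assert np.all(np.diff(r70) <= 0)
        assert np.all(np.diff(r38) <= 0)
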