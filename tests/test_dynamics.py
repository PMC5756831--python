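import numpy as np
import pytest

from channelweb import (
    NumericalError,
    calibrate_parameters,
    derivatives,
    functional_response,
    removal_experiment,
    simulate,
)
from channelweb.dynamics import DynamicsParams, baseline_run

from conftest import make_net, planted


def single_consumer_params(y=1.0, omega=1.0, H=1.0, q=0.0, h=1.0):
    """Minimal 2-node system (resource 0, consumer 1) built by hand."""
    S = 2
    om = np.zeros((S, S))
    om[0, 1] = omega
    return DynamicsParams(
        node_ids=("res", "con"),
        is_producer=np.array([True, False]),
        is_consumer=np.array([False, True]),
        is_detritus=np.array([False, False]),
        r=np.zeros(S),
        K=1.0,
        d=np.zeros(S),
        x=np.zeros(S),
        ex=np.zeros(S),
        a=np.ones(S),
        y=np.array([0.0, y]),
        H=np.array([0.0, H]),
        q=np.array([0.0, q]),
        h=h,
        omega=om,
        p_route=np.zeros((S, S)),
        c_conv=np.zeros((S, S)),
        forcing=np.zeros(S),
        b_star=np.ones(S),
    )


class TestFunctionalResponse:
    def test_reduces_to_holling_type_ii(self):
        # h=1, q=0, single prey: Phi = y w B / (H + w B)
        for b in (0.1, 0.5, 1.0, 4.0):
            p = single_consumer_params(y=2.0, omega=1.0, H=1.5, q=0.0, h=1.0)
            phi = functional_response(p, np.array([b, 1.0]), 0, 1)
            assert phi == pytest.approx(2.0 * b / (1.5 + b), rel=1e-12)

    def test_zero_prey_biomass_gives_zero(self):
        p = single_consumer_params()
        assert functional_response(p, np.array([0.0, 1.0]), 0, 1) == 0.0

    def test_hand_value_h2(self):
        # y=1, w=1, H=1, q=0, h=2, B_i=1 -> 1/(1+1) = 0.5
        p = single_consumer_params(h=2.0)
        assert functional_response(p, np.array([1.0, 1.0]), 0, 1) == pytest.approx(0.5)

    def test_type_iii_low_density_is_sigmoid(self):
        # Phi ~ B^2 as B -> 0 when h=2: halving B quarters Phi
        p = single_consumer_params(h=2.0)
        phi1 = functional_response(p, np.array([1e-4, 1.0]), 0, 1)
        phi2 = functional_response(p, np.array([5e-5, 1.0]), 0, 1)
        assert phi1 / phi2 == pytest.approx(4.0, rel=1e-3)

    def test_interference_lowers_feeding(self):
        lo = single_consumer_params(q=0.0)
        hi = single_consumer_params(q=2.0)
        B = np.array([1.0, 3.0])
        assert functional_response(hi, B, 0, 1) < functional_response(lo, B, 0, 1)


class TestCalibration:
    def test_logistic_equilibrium_of_a_lone_producer(self):
        p = single_consumer_params()
        # producer at B = K with d = 0 and no consumers: dB/dt = 0
        params = DynamicsParams(
            **{
                **p.__dict__,
                "r": np.array([0.5, 0.0]),
                "y": np.zeros(2),
                "omega": np.zeros((2, 2)),
                "K": 2.0,
            }
        )
        dB = derivatives(params, np.array([2.0, 0.0]))
        assert dB[0] == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("seed", range(20))
    def test_empirical_state_is_an_equilibrium(self, seed):
        net, _ = planted(k=2 + seed % 3, m=7, L=3, eps=0.07, seed=seed)
        params = calibrate_parameters(net)
        dB = derivatives(params, net.biomass)
        rel = np.abs(dB) / np.maximum(net.biomass, 1e-12)
        assert rel.max() <= 1e-6

    def test_realized_fluxes_match_data(self):
        net, _ = planted(k=2, m=6, L=3, eps=0.1, seed=5)
        params = calibrate_parameters(net)
        from channelweb.dynamics import functional_response_matrix

        phi = functional_response_matrix(params, net.biomass)
        realized = phi * net.biomass[None, :]
        assert np.allclose(realized, net.F, atol=1e-9 * max(1.0, net.F.max()))
        # respiration rates reproduce the respiration flows
        assert np.allclose(params.x * net.biomass, net.respiration)

    def test_assimilation_from_egestion_fraction(self):
        # respiration = 0.2 x intake, egestion = 0.3 x intake  =>  a = 0.7
        F = np.zeros((3, 3))
        F[0, 1] = 1.0  # detritus -> consumer intake
        F[1, 2] = 0.3  # egestion back to a second detritus pool
        net = make_net(
            "dcs",
            ["detritus", "consumer", "detritus"],
            F,
            biomass=[5.0, 1.0, 2.0],
            imports=[1.0, 0, 0],
            exports=[0, 0.5, 0.3],
            respiration=[0, 0.2, 0],
        )
        params = calibrate_parameters(net)
        assert params.a[1] == pytest.approx(0.7)
        assert params.x[1] == pytest.approx(0.2)

    def test_infeasible_assimilation_names_the_node(self):
        F = np.zeros((3, 3))
        F[0, 1] = 1.0
        F[1, 2] = 1.5  # egestion above intake
        net = make_net(
            "dcs", ["detritus", "consumer", "detritus"], F, imports=[1, 0.5, 0]
        )
        with pytest.raises(NumericalError, match="c"):
            calibrate_parameters(net)

    def test_zero_biomass_flowing_node_errors(self):
        F = np.zeros((2, 2))
        F[0, 1] = 1.0
        net = make_net(
            "bc", ["producer", "consumer"], F, biomass=[1.0, 0.0], imports=[1, 0],
            respiration=[0, 1.0],
        )
        with pytest.raises(NumericalError):
            calibrate_parameters(net)


class TestSimulation:
    def test_equilibrium_persists_for_2000_days(self):
        for seed in range(5):
            net, _ = planted(k=2, m=8, L=3, eps=0.05, seed=seed)
            params = calibrate_parameters(net)
            traj = simulate(params, net.biomass, 2000.0)
            rel = np.abs(traj.B / net.biomass[None, :] - 1.0)
            assert rel.max() <= 1e-3

    def test_biomass_never_below_floor(self):
        net, _ = planted(k=2, m=8, L=3, eps=0.05, seed=7)
        params = calibrate_parameters(net)
        state = net.biomass.copy()
        state[1] = 0.0  # knock a consumer out and integrate
        frozen = np.zeros(net.S, dtype=bool)
        frozen[1] = True
        traj = simulate(params, state, 300.0, frozen=frozen)
        assert traj.B.min() >= 0.0

    def test_removing_isolated_node_leaves_others_untouched(self):
        net, _ = planted(k=2, m=6, L=3, eps=0.0, seed=4)
        S = net.S
        grown = np.zeros((S + 1, S + 1))
        grown[:S, :S] = net.F
        net2 = make_net(
            list(net.node_ids) + ["iso"],
            list(net.category) + ["consumer"],
            grown,
            biomass=np.append(net.biomass, 2.0),
            imports=np.append(net.imports, 1.0),
            exports=np.append(net.exports, 1.0),
            respiration=np.append(net.respiration, 0.0),
        )
        params = calibrate_parameters(net2)
        run = removal_experiment(net2, params, "iso", burn_in=200.0, window=200.0)
        others = np.arange(S)
        assert np.allclose(run.b_minus[others], run.b_plus[others], rtol=1e-4)

    def test_control_averages_match_empirical_biomass(self):
        net, _ = planted(k=2, m=8, L=3, eps=0.05, seed=9)
        params = calibrate_parameters(net)
        b_plus, _ = baseline_run(net, params)
        assert np.allclose(b_plus, net.biomass, rtol=1e-4)

    def test_within_channel_impact_exceeds_cross_channel(self):
        """Removing a mid-channel consumer perturbs its own channel more."""
        net, truth = planted(k=2, m=8, L=3, eps=0.05, seed=0)
        params = calibrate_parameters(net)
        # node 3: a consumer of channel 0
        run = removal_experiment(net, params, net.node_ids[3])
        re = np.abs(
            np.log((run.b_plus + 1) / (run.b_minus + 1)) / (run.b_k + 1)
        )
        re[3] = np.nan
        own = truth.labels == truth.labels[3]
        own[3] = False
        assert np.nanmean(re[own]) > np.nanmean(re[~own & ~np.isnan(re)])
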