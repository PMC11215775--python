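import numpy as np
import pytest

import girsanov as g
from girsanov.errors import (ConfigError, ReweightingUndefinedError,
                             SchemeParseError)
from girsanov.integrators import (apply_operator, invert_step_noise,
                                  operator_params, parse_scheme, step)

from conftest import DATA_DIR


# ---------------------------------------------------------------------------
# scheme parsing
# ---------------------------------------------------------------------------

def test_parse_aboba_sequence_and_half_steps():
    s = parse_scheme("ABOBA")
    assert s.letters == ("A", "B", "O", "B", "A")
    assert s.halves == (True, True, False, True, True)
    assert s.n_noise == 1
    assert s.u_eval_point == "intermediate"


def test_rvo_alias_maps_to_same_operator_sequence():
    rvo, abo = parse_scheme("RVOVR"), parse_scheme("ABOBA")
    assert rvo.letters == abo.letters
    assert rvo.halves == abo.halves
    assert rvo.name == "ABOBA"
    assert rvo.from_rvo and not abo.from_rvo
    assert parse_scheme("r v o").letters == parse_scheme("ABO").letters


@pytest.mark.parametrize("text,n_noise", [
    ("ABO", 1), ("ABOBA", 1), ("AOBOA", 2), ("BOAOB", 2), ("OBABO", 2),
])
def test_noise_count_per_scheme(text, n_noise):
    assert parse_scheme(text).n_noise == n_noise


def test_parse_errors():
    with pytest.raises(SchemeParseError):
        parse_scheme("ABX")
    with pytest.raises(SchemeParseError):
        parse_scheme("")
    with pytest.raises(SchemeParseError, match="undefined"):
        parse_scheme("OABAO")  # not a supported splitting
    with pytest.raises(SchemeParseError):
        parse_scheme("AVO")  # mixed notations


# ---------------------------------------------------------------------------
# operator parameters
# ---------------------------------------------------------------------------

def test_operator_params_limits_and_value(params_2d):
    frictionless = g.LangevinParams(dt=0.0005, xi=0.0, T=300.0, masses=np.ones(2))
    ops = operator_params(frictionless)
    assert ops.d == 1.0
    np.testing.assert_array_equal(ops.f, 0.0)

    cold = g.LangevinParams(dt=0.0005, xi=5.0, T=0.0, masses=np.ones(2))
    np.testing.assert_array_equal(operator_params(cold).f, 0.0)

    ops = operator_params(params_2d)
    assert ops.d == pytest.approx(np.exp(-0.0025), rel=1e-15)
    assert ops.d_half**2 == pytest.approx(ops.d, rel=1e-14)
    # fluctuation-dissipation: d^2 RT M + f^2 = RT M per dof
    varp = params_2d.RT * params_2d.masses
    np.testing.assert_allclose(ops.d**2 * varp + ops.f**2, varp, rtol=1e-12)
    np.testing.assert_allclose(ops.d_half**2 * varp + ops.f_half**2, varp,
                               rtol=1e-12)


def test_invalid_langevin_params():
    for kwargs in ({"dt": 0.0}, {"xi": -1.0}, {"T": -5.0}):
        with pytest.raises(ConfigError):
            g.LangevinParams(**{"dt": 0.0005, "xi": 5.0, "T": 300.0,
                                "masses": np.ones(1), **kwargs})
    with pytest.raises(ConfigError):
        g.LangevinParams(dt=0.0005, xi=5.0, T=300.0, masses=np.zeros(1))


# ---------------------------------------------------------------------------
# single operators
# ---------------------------------------------------------------------------

def test_operator_support(params_1d):
    ops = operator_params(params_1d)
    pot = g.Harmonic(k=1.0)
    s = g.PhaseState(np.array([1.0]), np.array([0.5]))
    sa = apply_operator("A", s, pot, ops)
    assert sa.p[0] == s.p[0] and sa.q[0] != s.q[0]
    sb = apply_operator("B", s, pot, ops)
    assert sb.q[0] == s.q[0] and sb.p[0] != s.p[0]
    so = apply_operator("O", s, pot, ops, noise=np.array([0.3]))
    assert so.q[0] == s.q[0]
    with pytest.raises(ConfigError):
        apply_operator("O", s, pot, ops)  # missing noise


def test_b_step_closed_form():
    par = g.LangevinParams(dt=0.1, xi=5.0, T=300.0, masses=np.ones(1))
    ops = operator_params(par)
    s = g.PhaseState(np.array([1.0]), np.array([0.0]))
    out = apply_operator("B", s, g.Harmonic(k=1.0), ops)
    assert out.p[0] == pytest.approx(-0.1, rel=1e-14)


def test_o_step_preserves_stationary_momentum_variance(params_1d):
    """Ornstein-Uhlenbeck update: p ~ N(0, RT M) must be invariant."""
    ops = operator_params(params_1d)
    rng = np.random.default_rng(10)
    n = 100_000
    varp = params_1d.RT * params_1d.masses[0]
    p = rng.normal(0.0, np.sqrt(varp), n)
    p_out = ops.d * p + ops.f[0] * rng.standard_normal(n)
    se = varp * np.sqrt(2.0 / n)
    assert abs(p_out.var() - varp) < 3 * se


# ---------------------------------------------------------------------------
# full steps
# ---------------------------------------------------------------------------

def test_step_matches_hand_unrolled_abo(params_1d):
    pot = g.Harmonic(k=4.0)
    pair = g.make_pair(pot)
    ops = operator_params(params_1d)
    rng = np.random.default_rng(5)
    s0 = g.PhaseState(np.array([0.7]), np.array([-0.2]))
    s1, noise = step(s0, parse_scheme("ABO"), pair, params_1d, rng, ops=ops)
    # manual composition A then B then O
    q = s0.q + ops.a * s0.p
    p = s0.p - params_1d.dt * pot.gradient(q)
    p = ops.d * p + ops.f * noise.eta1
    np.testing.assert_allclose(s1.q, q, rtol=0, atol=0)
    np.testing.assert_allclose(s1.p, p, rtol=0, atol=0)


def test_step_determinism_and_zero_perturbation_hook(mb_biased_pair, params_2d):
    s0 = g.PhaseState(np.array([-0.5, 1.5]), np.array([0.4, 0.1]))
    a, _ = step(s0, parse_scheme("ABOBA"), mb_biased_pair, params_2d,
                np.random.default_rng(7))
    b, _ = step(s0, parse_scheme("ABOBA"), mb_biased_pair, params_2d,
                np.random.default_rng(7))
    np.testing.assert_array_equal(a.q, b.q)
    np.testing.assert_array_equal(a.p, b.p)

    seen = {}
    unb = g.make_pair(g.MuellerBrown())
    step(s0, parse_scheme("ABOBA"), unb, params_2d, np.random.default_rng(7),
         hook=lambda noise, delta: seen.update(d=delta.delta1))
    np.testing.assert_array_equal(seen["d"], 0.0)


def test_two_noise_scheme_simulates_but_refuses_reweighting(mb_biased_pair,
                                                            params_2d):
    s0 = g.PhaseState(np.array([-0.5, 1.5]), np.array([0.0, 0.0]))
    res = g.simulate(s0, "OBABO", mb_biased_pair, params_2d, 50, 10, seed=1,
                     reweight=False)
    assert res.n_frames == 6
    with pytest.raises(ReweightingUndefinedError):
        g.simulate(s0, "OBABO", mb_biased_pair, params_2d, 50, 10, seed=1,
                   reweight=True)


def test_simulate_frame_bookkeeping(mb_biased_pair, params_2d):
    s0 = g.PhaseState(np.array([-0.5, 1.5]), np.array([0.0, 0.0]))
    res = g.simulate(s0, "ABOBA", mb_biased_pair, params_2d, 100, 10, seed=2)
    assert res.n_frames == 11
    assert len(res.reweighting) == 11
    assert res.reweighting.dS[0] == 0.0
    np.testing.assert_allclose(res.times, np.arange(11) * 0.005)
    with pytest.raises(ConfigError):
        g.simulate(s0, "ABOBA", mb_biased_pair, params_2d, 101, 10, seed=2)


def test_fast_and_generic_engines_agree(mb_biased_pair, params_2d):
    s0 = g.PhaseState(np.array([-0.5, 1.5]), np.array([0.8, -0.3]))
    for scheme in ("ABO", "ABOBA"):
        a = g.simulate(s0, scheme, mb_biased_pair, params_2d, 500, 10, seed=4,
                       engine="generic")
        b = g.simulate(s0, scheme, mb_biased_pair, params_2d, 500, 10, seed=4,
                       engine="fast")
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-12, rtol=0)
        np.testing.assert_allclose(a.momenta, b.momenta, atol=1e-12, rtol=0)
        np.testing.assert_allclose(a.reweighting.dS, b.reweighting.dS,
                                   atol=1e-12, rtol=0)
        np.testing.assert_allclose(a.reweighting.U_q, b.reweighting.U_q,
                                   atol=1e-12, rtol=0)


def test_harmonic_equilibrium_variance_and_equipartition(params_1d):
    """Long ABOBA run must sample the Boltzmann density: var(q) = RT/k and
    <p^2/M> = RT within 3 standard errors (block averaging)."""
    k = 100.0
    pair = g.make_pair(g.Harmonic(k=k))
    s0 = g.PhaseState(np.zeros(1), np.zeros(1))
    res = g.simulate(s0, "ABOBA", pair, params_1d, 600_000, 10, seed=8)
    q = res.positions[200:, 0]
    p = res.momenta[200:, 0]
    RT = params_1d.RT

    def block_se(x, nblocks=30):
        blocks = np.array_split(x, nblocks)
        vals = np.array([np.mean(b) for b in blocks])
        return vals.mean(), vals.std(ddof=1) / np.sqrt(nblocks)

    mean_q2, se_q2 = block_se(q**2)
    assert abs(mean_q2 - RT / k) < 3 * se_q2
    mean_p2, se_p2 = block_se(p**2 / params_1d.masses[0])
    assert abs(mean_p2 - RT) < 3 * se_p2


def test_frictionless_limit_energy_drift_bounded():
    """With ξ = 0 the integrator degenerates to a deterministic
    velocity-Verlet-like scheme: harmonic energy drift stays O(Δt²)."""
    par = g.LangevinParams(dt=0.0005, xi=0.0, T=300.0, masses=np.ones(1))
    pot = g.Harmonic(k=100.0)
    pair = g.make_pair(pot)
    s0 = g.PhaseState(np.array([0.2]), np.array([0.0]))
    res = g.simulate(s0, "ABOBA", pair, par, 1000, 1, seed=0, reweight=False,
                     engine="generic")
    e = np.array([pot.energy(q) + 0.5 * p[0]**2 for q, p in
                  zip(res.positions, res.momenta)])
    assert np.max(np.abs(e - e[0])) / e[0] < 1e-4


def test_blowup_reports_step_index(params_1d):
    pair = g.make_pair(g.Harmonic(k=100.0))
    s0 = g.PhaseState(np.array([0.0]), np.array([1e9]))
    with pytest.raises(g.SimulationBlowupError) as exc:
        g.simulate(s0, "ABOBA", pair, params_1d, 100, 10, seed=0,
                   blowup_bound=100.0)
    assert exc.value.step >= 1


# ---------------------------------------------------------------------------
# noise inversion oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scheme", ["ABO", "ABOBA"])
def test_inversion_recovers_recorded_noise(scheme, mb_biased_pair, params_2d):
    rng = np.random.default_rng(12)
    s0 = g.PhaseState(rng.uniform(-1, 1, 2), rng.normal(0, 1.5, 2))
    s1, noise = step(s0, parse_scheme(scheme), mb_biased_pair, params_2d, rng)
    eta = invert_step_noise(s0, s1, scheme, mb_biased_pair.V, params_2d)
    np.testing.assert_allclose(eta, noise.eta1, atol=1e-12, rtol=0)


def test_inversion_linear_perturbation_closed_form(params_1d):
    """For ABO with linear U the noise shift is exactly (d Δt / f) dU/dx."""
    pot = g.Harmonic(k=3.0)
    U = g.LinearBias(2.0)
    pair = g.pair_from_simulation(pot, U)
    ops = operator_params(params_1d)
    rng = np.random.default_rng(13)
    s0 = g.PhaseState(np.array([0.4]), np.array([-0.6]))
    s1, noise = step(s0, parse_scheme("ABO"), pair, params_1d, rng)
    eta_t = invert_step_noise(s0, s1, "ABO", pair.V_target, params_1d)
    expected = ops.d * params_1d.dt / ops.f[0] * 2.0
    assert eta_t[0] - noise.eta1[0] == pytest.approx(expected, rel=1e-10)


def test_inversion_continuity_and_f_zero_error(params_1d):
    pair = g.make_pair(g.Harmonic(k=3.0))
    rng = np.random.default_rng(14)
    s0 = g.PhaseState(np.array([0.4]), np.array([-0.6]))
    s1, _ = step(s0, parse_scheme("ABO"), pair, params_1d, rng)
    eta = invert_step_noise(s0, s1, "ABO", pair.V, params_1d)
    s1b = g.PhaseState(s1.q, s1.p + 1e-12)
    eta_b = invert_step_noise(s0, s1b, "ABO", pair.V, params_1d)
    ops = operator_params(params_1d)
    assert abs(eta_b[0] - eta[0]) == pytest.approx(1e-12 / ops.f[0], rel=1e-3)

    frozen = g.LangevinParams(dt=0.0005, xi=0.0, T=300.0, masses=np.ones(1))
    with pytest.raises(ReweightingUndefinedError):
        invert_step_noise(s0, s1, "ABO", pair.V, frozen)


@pytest.mark.parametrize("scheme", ["AOBOA", "BOAOB", "OBABO"])
def test_two_noise_inversion_recovers_endpoint_combination(scheme, params_2d,
                                                           mb_biased_pair):
    rng = np.random.default_rng(15)
    ops = operator_params(params_2d)
    s0 = g.PhaseState(rng.uniform(-1, 1, 2), rng.normal(0, 1.5, 2))
    s1, noise = step(s0, parse_scheme(scheme), mb_biased_pair, params_2d, rng)
    comb = invert_step_noise(s0, s1, scheme, mb_biased_pair.V, params_2d)
    np.testing.assert_allclose(comb, ops.d_half * noise.eta1 + noise.eta2,
                               atol=1e-10, rtol=0)


# ---------------------------------------------------------------------------
# twin implementation + golden fixture
# ---------------------------------------------------------------------------

def test_abo_form_and_rvo_form_trajectories_coincide(mb_biased_pair):
    """The momentum and the velocity formulations of ABOBA, driven by the
    same noise stream, agree to floating-point precision over 100 steps."""
    par = g.LangevinParams(dt=0.0005, xi=5.0, T=300.0,
                           masses=np.array([1.3, 2.1]))
    s0 = g.PhaseState(np.array([-0.5, 1.5]), np.array([0.9, -0.2]))
    res = g.simulate(s0, "ABOBA", mb_biased_pair, par, 100, 1, seed=21,
                     engine="generic", reweight=False)
    q2, p2 = g.simulate_velocity_form(s0, "RVOVR", mb_biased_pair, par, 100,
                                      np.random.default_rng(21))
    assert np.max(np.abs(res.positions - q2)) <= 1e-13
    assert np.max(np.abs(res.momenta - p2)) <= 1e-13


def test_golden_20_step_fixture_is_stable(tmp_path):
    """Noise-draw order is part of the file contract: regenerating the
    deterministic fixture must reproduce the committed files byte-for-byte."""
    g.generate_fixtures(42, tmp_path)
    for name in ("abo_traj.tsv", "abo_rw.tsv", "aboba_traj.tsv", "aboba_rw.tsv"):
        fresh = (tmp_path / name).read_text()
        committed = open(f"{DATA_DIR}/{name}").read()
        assert fresh == committed, f"fixture drift in {name}"
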