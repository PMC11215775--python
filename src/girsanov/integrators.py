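"""Langevin splitting integrators with deterministic noise bookkeeping.

Underdamped Langevin dynamics

    M q̈ = -∇V(q) - ξ M q̇ + sqrt(2 RT ξ M) η(t)

is integrated by composing three per-degree-of-freedom update operators:

    A (drift):    q <- q + a p          a = Δt / M_ll
    B (kick):     p <- p - Δt ∇V(q)
    O (thermal):  p <- d p + f η        d = exp(-ξ Δt),
                                        f = sqrt(RT M_ll (1 - d^2))

A scheme string such as ``"ABOBA"`` states the order of application; a
letter that occurs twice is applied with half a time step (Δt -> Δt/2 in
the formulas above).  The equivalent RVO notation (R = drift on positions,
V = velocity kick) is accepted as an alias: ``"RVOVR"`` parses to the same
operator sequence as ``"ABOBA"``.

Each O application consumes one standard-normal vector per degree of
freedom; the draw order is fixed as (step, O-occurrence, dof), which makes
both trajectories and path-reweighting factors reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .constants import GAS_CONSTANT
from .errors import (ConfigError, ReweightingUndefinedError, SchemeParseError,
                     SimulationBlowupError)
from .potentials import Potential, PotentialPair, make_pair

__all__ = [
    "LangevinParams",
    "OperatorParams",
    "SplittingScheme",
    "PhaseState",
    "NoiseDraw",
    "SimulationResult",
    "parse_scheme",
    "operator_params",
    "apply_operator",
    "step",
    "simulate",
    "simulate_velocity_form",
    "invert_step_noise",
    "maxwell_boltzmann_momenta",
    "SUPPORTED_SCHEMES",
    "REWEIGHTABLE_SCHEMES",
]

#: Splitting schemes with a defined path-probability ratio, keyed by their
#: canonical ABO-notation name, with the RVO alias alongside.
SUPPORTED_SCHEMES = {
    "ABO": "RVO",
    "ABOBA": "RVOVR",
    "AOBOA": "ROVOR",
    "BOAOB": "VOROV",
    "OBABO": "OVRVO",
}

#: Schemes whose per-channel random-number-difference formulas are
#: implemented and certified against the step-inversion oracle.  The
#: two-noise schemes (AOBOA, BOAOB, OBABO) can be simulated, and their
#: endpoint fixes the noise combination d' η(1) + η(2), but the per-channel
#: split of Δη is not implemented, so reweighting is refused for them.
REWEIGHTABLE_SCHEMES = ("ABO", "ABOBA")

_RVO_TO_ABO = {"R": "A", "V": "B", "O": "O"}


@dataclass(frozen=True)
class LangevinParams:
    """Integrator parameters: Δt in ps, collision rate ξ in 1/ps,
    temperature T in K, per-dof masses in amu."""

    dt: float
    xi: float
    T: float
    masses: np.ndarray
    R: float = GAS_CONSTANT

    def __post_init__(self):
        object.__setattr__(self, "masses",
                           np.atleast_1d(np.asarray(self.masses, dtype=float)))
        if self.dt <= 0:
            raise ConfigError("time step must be positive")
        if self.xi < 0:
            raise ConfigError("collision rate must be nonnegative")
        if self.T < 0:
            raise ConfigError("temperature must be nonnegative")
        if np.any(self.masses <= 0):
            raise ConfigError("masses must be positive")

    @property
    def ndof(self) -> int:
        return self.masses.size

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass(frozen=True)
class OperatorParams:
    """Derived per-step update coefficients (full- and half-step).

    ``d`` is the dimensionless dissipation factor, ``f`` the per-dof
    fluctuation amplitude in momentum units (amu nm/ps), ``a`` the per-dof
    position-update factor Δt/M.  Primed (half-step) analogues are obtained
    by substituting Δt -> Δt/2.
    """

    dt: float
    d: float
    f: np.ndarray
    a: np.ndarray
    d_half: float
    f_half: np.ndarray
    a_half: np.ndarray


def operator_params(params: LangevinParams) -> OperatorParams:
    """Dissipation/fluctuation/drift coefficients for full and half steps.

    d = exp(-ξΔt); f_l = sqrt(RT M_ll (1 - d^2)); a_l = Δt/M_ll.  The
    fluctuation-dissipation identity d^2 RT M + f^2 = RT M holds per dof.
    """
    varp = params.RT * params.masses  # stationary momentum variance per dof
    d = float(np.exp(-params.xi * params.dt))
    d_half = float(np.exp(-params.xi * params.dt / 2.0))
    f = np.sqrt(varp * (1.0 - d * d))
    f_half = np.sqrt(varp * (1.0 - d_half * d_half))
    a = params.dt / params.masses
    return OperatorParams(dt=params.dt, d=d, f=f, a=a,
                          d_half=d_half, f_half=f_half, a_half=a / 2.0)


@dataclass(frozen=True)
class SplittingScheme:
    """Parsed operator sequence.

    ``letters``/``halves`` give the ABO-notation sequence and which
    applications use half-step coefficients.  ``n_noise`` is the number of
    standard-normal vectors consumed per full integrator step (the number
    of O applications).  ``u_eval_point`` tags where the perturbation force
    is evaluated when assembling the random-number difference:
    ``"after_update"`` (at the drifted position, ABO) or ``"intermediate"``
    (at the mid-step position, ABOBA); ``None`` for schemes whose Δη is not
    implemented.
    """

    name: str
    letters: tuple[str, ...]
    halves: tuple[bool, ...]
    n_noise: int
    u_eval_point: Optional[str]
    from_rvo: bool = False

    @property
    def reweightable(self) -> bool:
        return self.name in REWEIGHTABLE_SCHEMES


_U_EVAL = {"ABO": "after_update", "ABOBA": "intermediate"}


def parse_scheme(text: str) -> SplittingScheme:
    """Parse a splitting-scheme string (ABO or RVO notation, spaces and
    case ignored) into a :class:`SplittingScheme`.

    Only schemes with a defined path-probability ratio are accepted:
    ABO/ABOBA/AOBOA/BOAOB/OBABO and their RVO aliases.
    """
    if not isinstance(text, str) or not text.strip():
        raise SchemeParseError("empty splitting-scheme string")
    cleaned = text.replace(" ", "").upper()
    bad = set(cleaned) - set("ABORV")
    if bad:
        raise SchemeParseError(
            f"unknown update operator(s) {sorted(bad)} in scheme {text!r}")
    from_rvo = bool(set(cleaned) & set("RV"))
    if from_rvo and set(cleaned) & set("AB"):
        raise SchemeParseError(f"mixed ABO/RVO notation in scheme {text!r}")
    letters = tuple(_RVO_TO_ABO.get(ch, ch) for ch in cleaned)
    name = "".join(letters)
    if name not in SUPPORTED_SCHEMES:
        known = ", ".join(f"{k} (alias {v})" for k, v in SUPPORTED_SCHEMES.items())
        raise SchemeParseError(
            f"path reweighting is undefined for splitting {text!r}; "
            f"supported schemes: {known}")
    counts = {ch: letters.count(ch) for ch in set(letters)}
    halves = tuple(counts[ch] == 2 for ch in letters)
    return SplittingScheme(name=name, letters=letters, halves=halves,
                           n_noise=counts.get("O", 0),
                           u_eval_point=_U_EVAL.get(name), from_rvo=from_rvo)


@dataclass
class PhaseState:
    """Positions, momenta, and integer step index."""

    q: np.ndarray
    p: np.ndarray
    k: int = 0

    def __post_init__(self):
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if self.q.shape != self.p.shape:
            raise ConfigError("q and p must have the same length")
        if self.k < 0:
            raise ConfigError("step index must be nonnegative")

    def copy(self) -> "PhaseState":
        return PhaseState(self.q.copy(), self.p.copy(), self.k)


@dataclass
class NoiseDraw:
    """Standard-normal vectors consumed by one integrator step."""

    eta1: np.ndarray
    eta2: Optional[np.ndarray] = None


def maxwell_boltzmann_momenta(params: LangevinParams, rng: np.random.Generator) -> np.ndarray:
    """Draw momenta from the stationary Maxwell-Boltzmann density N(0, RT M)."""
    return rng.standard_normal(params.ndof) * np.sqrt(params.RT * params.masses)


def apply_operator(letter: str, state: PhaseState, potential_V: Potential,
                   ops: OperatorParams, half: bool = False,
                   noise: Optional[np.ndarray] = None) -> PhaseState:
    """Apply a single A/B/O update operator and return the new state.

    ``noise`` must be supplied exactly when ``letter == "O"``.
    """
    q, p = state.q.copy(), state.p.copy()
    if letter == "A":
        q = q + (ops.a_half if half else ops.a) * p
    elif letter == "B":
        dt_eff = ops.dt / 2.0 if half else ops.dt
        p = p - dt_eff * potential_V.gradient(q)
    elif letter == "O":
        if noise is None:
            raise ConfigError("O-step requires a noise vector")
        d = ops.d_half if half else ops.d
        f = ops.f_half if half else ops.f
        p = d * p + f * noise
    else:
        raise ConfigError(f"unknown update operator {letter!r}")
    return PhaseState(q, p, state.k)


def _delta_eta_coef(scheme: SplittingScheme, ops: OperatorParams) -> np.ndarray:
    """Per-dof prefactor c with Δη = c * ∇U(q_eval).  See reweighting module."""
    if np.any(ops.f == 0.0):
        raise ReweightingUndefinedError(
            "fluctuation amplitude f = 0 (ξ = 0 or T = 0): random-number "
            "differences are undefined")
    if scheme.name == "ABO":
        return ops.d * ops.dt / ops.f
    if scheme.name == "ABOBA":
        return (1.0 + ops.d) * ops.dt / (2.0 * ops.f)
    raise ReweightingUndefinedError(
        f"random-number difference not implemented for scheme {scheme.name}; "
        f"certified schemes: {', '.join(REWEIGHTABLE_SCHEMES)}")


def step(state: PhaseState, scheme: SplittingScheme, pair: PotentialPair,
         params: LangevinParams, rng: np.random.Generator,
         ops: Optional[OperatorParams] = None,
         hook: Optional[Callable] = None) -> tuple[PhaseState, NoiseDraw]:
    """Advance one full integrator step.

    Draws exactly ``scheme.n_noise`` standard-normal vectors in the fixed
    order (O-occurrence, dof).  If ``hook`` is given it is invoked once,
    before returning, with ``(noise, delta_eta)`` where ``delta_eta`` is the
    per-channel random-number difference for reweighting to the pair's
    target potential (requires a certified scheme unless U == 0).
    """
    if ops is None:
        ops = operator_params(params)
    want_rw = hook is not None
    if want_rw and not pair.unperturbed and not scheme.reweightable:
        raise ReweightingUndefinedError(
            f"reweighting not available for scheme {scheme.name}")
    q = state.q.copy()
    p = state.p.copy()
    etas: list[np.ndarray] = []
    grad_u = None
    seen_b = False
    for letter, half in zip(scheme.letters, scheme.halves):
        if letter == "A":
            q = q + (ops.a_half if half else ops.a) * p
        elif letter == "B":
            if not seen_b:
                # the first kick position is where the perturbation force
                # enters the random-number difference for ABO and ABOBA
                if want_rw and not pair.unperturbed:
                    grad_u = pair.U.gradient(q)
                seen_b = True
            g = pair.V.gradient(q)
            p = p - (ops.dt / 2.0 if half else ops.dt) * g
        else:  # O
            eta = rng.standard_normal(params.ndof)
            etas.append(eta)
            d = ops.d_half if half else ops.d
            f = ops.f_half if half else ops.f
            p = d * p + f * eta
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(p))):
        raise SimulationBlowupError(state.k + 1)
    noise = NoiseDraw(eta1=etas[0], eta2=etas[1] if len(etas) > 1 else None)
    if want_rw:
        from .reweighting import DeltaEta  # local import to avoid a cycle
        if pair.unperturbed or grad_u is None:
            delta = DeltaEta(delta1=np.zeros(params.ndof))
        else:
            delta = DeltaEta(delta1=_delta_eta_coef(scheme, ops) * grad_u)
        hook(noise, delta)
    return PhaseState(q, p, state.k + 1), noise


@dataclass
class SimulationResult:
    """Recorded trajectory frames plus the aligned reweighting records."""

    scheme: str
    dt: float
    n_out: int
    times: np.ndarray            # ps, length n_frames
    positions: np.ndarray        # (n_frames, ndof) nm
    momenta: np.ndarray          # (n_frames, ndof) amu nm/ps
    reweighting: Optional["ReweightingTrajectory"]
    final_state: PhaseState

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def simulate(initial: PhaseState, scheme: SplittingScheme | str,
             pair: PotentialPair | Potential, params: LangevinParams,
             n_steps: int, n_out: int, seed: int | None = None,
             rng: np.random.Generator | None = None,
             reweight: bool = True, engine: str = "auto",
             blowup_bound: float = 1e3) -> SimulationResult:
    """Run ``n_steps`` integrator steps, recording every ``n_out`` steps.

    Frames are recorded at steps 0, n_out, 2 n_out, ..., n_steps, so the
    trajectory holds ``n_steps / n_out + 1`` frames.  The reweighting record
    at frame k' carries the log-weight increment accumulated over the n_out
    steps ending at k' (the record at frame 0 is zero) together with the
    perturbation energy U(q_k').

    ``engine`` selects the implementation: ``"generic"`` is the pure-Python
    operator composition above; ``"fast"`` is a numba kernel specialized to
    ABO/ABOBA on the built-in potentials; ``"auto"`` uses the fast kernel
    when applicable.  Both engines consume the identical noise stream and
    produce matching trajectories.
    """
    from .reweighting import ReweightingTrajectory

    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    if isinstance(pair, Potential):
        pair = make_pair(pair)
    if n_out < 1:
        raise ConfigError("n_out must be >= 1")
    if n_steps % n_out != 0:
        raise ConfigError(f"n_out = {n_out} does not divide n_steps = {n_steps}")
    if params.ndof != pair.ndim:
        raise ConfigError("params.masses length must match potential dimension")
    if reweight and not pair.unperturbed and not scheme.reweightable:
        raise ReweightingUndefinedError(
            f"reweighting not available for scheme {scheme.name}; "
            "run with reweight=False or use ABO/ABOBA")
    if rng is None:
        rng = np.random.default_rng(seed)
    ops = operator_params(params)

    n_frames = n_steps // n_out + 1
    ndof = params.ndof
    out_q = np.empty((n_frames, ndof))
    out_p = np.empty((n_frames, ndof))
    out_dS = np.zeros(n_frames)
    out_U = np.zeros(n_frames)

    if engine not in ("auto", "generic", "fast"):
        raise ConfigError(f"unknown engine {engine!r}")
    use_fast = False
    if engine in ("auto", "fast"):
        from . import _kernels
        use_fast = _kernels.can_run(scheme, pair)
        if engine == "fast" and not use_fast:
            raise ConfigError("fast engine cannot handle this scheme/potential")

    out_q[0] = initial.q
    out_p[0] = initial.p
    if reweight:
        out_U[0] = pair.U.energy(initial.q)

    if use_fast:
        from . import _kernels
        final = _kernels.run(scheme, pair, params, ops, initial, n_steps, n_out,
                             rng, reweight, out_q, out_p, out_dS, out_U,
                             blowup_bound)
    else:
        state = initial.copy()
        buf = 0.0

        def hook(noise: NoiseDraw, delta) -> None:
            nonlocal buf
            d1 = delta.delta1
            buf += float(noise.eta1 @ d1 + 0.5 * d1 @ d1)
            if noise.eta2 is not None and delta.delta2 is not None:
                d2 = delta.delta2
                buf += float(noise.eta2 @ d2 + 0.5 * d2 @ d2)

        use_hook = hook if reweight else None
        for s in range(1, n_steps + 1):
            state, _ = step(state, scheme, pair, params, rng, ops=ops,
                            hook=use_hook)
            if np.any(np.abs(state.q) > blowup_bound):
                raise SimulationBlowupError(s)
            if s % n_out == 0:
                fi = s // n_out
                out_q[fi] = state.q
                out_p[fi] = state.p
                if reweight:
                    out_dS[fi] = buf
                    out_U[fi] = pair.U.energy(state.q)
                buf = 0.0
        final = state

    times = np.arange(n_frames) * (n_out * params.dt)
    rw = None
    if reweight:
        rw = ReweightingTrajectory(frame_index=np.arange(n_frames),
                                   time_ps=times.copy(), dS=out_dS, U_q=out_U)
    return SimulationResult(scheme=scheme.name, dt=params.dt, n_out=n_out,
                            times=times, positions=out_q, momenta=out_p,
                            reweighting=rw, final_state=final)


def simulate_velocity_form(initial: PhaseState, scheme: SplittingScheme | str,
                           pair: PotentialPair | Potential, params: LangevinParams,
                           n_steps: int, rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Twin implementation in RVO (position/velocity) form, recording every step.

    The R step drifts positions with the velocity (q <- q + Δt v), the V step
    kicks velocities (v <- v - Δt ∇V(q)/M), and the O step mixes
    v <- d v + (f/M) η.  Algebraically identical to the ABO-form
    (momentum) update; the two implementations differ only in the order of
    floating-point operations, so trajectories driven by the same noise
    stream agree to machine precision.  Returns (positions, momenta) arrays
    of shape (n_steps + 1, ndof).
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    if isinstance(pair, Potential):
        pair = make_pair(pair)
    ops = operator_params(params)
    m = params.masses
    q = initial.q.astype(float).copy()
    v = initial.p / m
    fbar, fbar_half = ops.f / m, ops.f_half / m
    out_q = np.empty((n_steps + 1, params.ndof))
    out_p = np.empty((n_steps + 1, params.ndof))
    out_q[0], out_p[0] = q, v * m
    for s in range(1, n_steps + 1):
        for letter, half in zip(scheme.letters, scheme.halves):
            dt_eff = params.dt / 2.0 if half else params.dt
            if letter == "A":      # R step
                q = q + dt_eff * v
            elif letter == "B":    # V step
                v = v - dt_eff * (pair.V.gradient(q) / m)
            else:                  # O step
                eta = rng.standard_normal(params.ndof)
                v = (ops.d_half if half else ops.d) * v \
                    + (fbar_half if half else fbar) * eta
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(v))):
            raise SimulationBlowupError(s)
        out_q[s], out_p[s] = q, v * m
    return out_q, out_p


def _replay(state: PhaseState, scheme: SplittingScheme, potential: Potential,
            ops: OperatorParams, noise_value: np.ndarray) -> PhaseState:
    """Replay one step with every O application fed the same noise vector."""
    s = state.copy()
    for letter, half in zip(scheme.letters, scheme.halves):
        s = apply_operator(letter, s, potential, ops, half=half,
                           noise=noise_value if letter == "O" else None)
    return s


def invert_step_noise(state_k: PhaseState, state_k1: PhaseState,
                      scheme: SplittingScheme | str, potential: Potential,
                      params: LangevinParams) -> np.ndarray:
    """Solve for the noise that produces the transition state_k -> state_k1
    under ``potential``.

    For one-noise schemes (ABO, ABOBA) the endpoint momentum is affine in
    the noise, so two replays of the operator sequence -- one with η = 0 and
    one with η = 1 per dof -- determine the unique η exactly.  For two-noise
    schemes the endpoint fixes only the combination η_comb = d' η(1) + η(2),
    which is returned, computed from a per-scheme closed-form inversion that
    uses the recorded endpoint positions.

    This is the independent oracle used to certify the closed-form
    random-number differences; reweighting code never calls it.
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    ops = operator_params(params)
    ndof = params.ndof
    if np.any((ops.f_half if scheme.n_noise == 2 else ops.f) == 0.0):
        raise ReweightingUndefinedError(
            "noise inversion undefined for f = 0 (ξ = 0 or T = 0)")
    if scheme.n_noise == 1:
        zero = _replay(state_k, scheme, potential, ops, np.zeros(ndof))
        ones = _replay(state_k, scheme, potential, ops, np.ones(ndof))
        coef = ones.p - zero.p
        if np.any(coef == 0.0):
            raise ReweightingUndefinedError("transition does not determine the noise")
        return (state_k1.p - zero.p) / coef
    return _invert_two_noise_combination(state_k, state_k1, scheme,
                                         potential, params, ops)


def _invert_two_noise_combination(state_k, state_k1, scheme, potential,
                                  params, ops) -> np.ndarray:
    """Endpoint-determined combination d' η(1) + η(2) for AOBOA/BOAOB/OBABO.

    All kick positions are known from the endpoints (the initial position,
    the half-drifted midpoint, or the final position), so the combination
    follows in closed form from the operator definitions.
    """
    q0, p0 = state_k.q, state_k.p
    q1, p1 = state_k1.q, state_k1.p
    dt, dp, fp = ops.dt, ops.d_half, ops.f_half
    if scheme.name == "AOBOA":
        qm = q0 + ops.a_half * p0
        return (p1 - dp * dp * p0 + dp * dt * potential.gradient(qm)) / fp
    if scheme.name == "BOAOB":
        pb = p0 - 0.5 * dt * potential.gradient(q0)
        return (p1 + 0.5 * dt * potential.gradient(q1) - dp * dp * pb) / fp
    if scheme.name == "OBABO":
        g = potential.gradient(q0) + potential.gradient(q1)
        return (p1 - dp * dp * p0 + 0.5 * dp * dt * g) / fp
    raise ReweightingUndefinedError(
        f"noise inversion not implemented for scheme {scheme.name}")
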