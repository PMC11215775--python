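"""Potential energy surfaces, bias potentials, and simulation/target pairs.

Every potential exposes a single ``evaluate(q) -> (energy, gradient)``
contract (plus ``energy`` and ``gradient`` shortcuts) so that integrators
and reweighting code share one interface.  Positions are 1-D numpy arrays
of length ``ndim`` in nm; energies are kJ/mol and gradients kJ/mol/nm.

The central composite object is :class:`PotentialPair`, which ties together
the simulation potential V (the one the integrator propagates on), the
target potential Ṽ (the one expectations should be reweighted to) and the
perturbation U connecting them,

    Ṽ(q) = V(q) + U(q).

An enhanced-sampling bias U_bias, added on top of the target to drive the
simulation (V = Ṽ + U_bias), corresponds to U = -U_bias.  The sign
convention is resolved once, at pair construction; all downstream
reweighting code only ever sees U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = [
    "Potential",
    "ZeroPotential",
    "Harmonic",
    "DoubleWell",
    "MuellerBrownParams",
    "MuellerBrown",
    "BiasSpec",
    "LinearBias",
    "PolynomialBias",
    "AxisPotential",
    "ScaledPotential",
    "SumPotential",
    "PotentialPair",
    "make_pair",
    "pair_from_simulation",
    "make_bias",
    "bias_energy",
    "bias_gradient",
    "mueller_brown_energy",
    "mueller_brown_gradient",
    "finite_difference_gradient",
]


def _as_position(q, ndim: int) -> np.ndarray:
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if q.shape != (ndim,):
        raise ConfigError(f"expected position of dimension {ndim}, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ConfigError(f"non-finite position {q!r}")
    return q


class Potential:
    """Base class: an energy/gradient map on R^ndim."""

    ndim: int = 1

    def energy(self, q) -> float:
        raise NotImplementedError

    def gradient(self, q) -> np.ndarray:
        raise NotImplementedError

    def evaluate(self, q) -> tuple[float, np.ndarray]:
        return self.energy(q), self.gradient(q)

    # conveniences -------------------------------------------------------
    def __add__(self, other: "Potential") -> "SumPotential":
        return SumPotential([self, other])

    def __neg__(self) -> "ScaledPotential":
        return ScaledPotential(self, -1.0)

    @property
    def is_zero(self) -> bool:
        return False


class ZeroPotential(Potential):
    """Identically-zero potential (the unperturbed case U == 0)."""

    def __init__(self, ndim: int = 1):
        self.ndim = ndim

    def energy(self, q) -> float:
        _as_position(q, self.ndim)
        return 0.0

    def gradient(self, q) -> np.ndarray:
        _as_position(q, self.ndim)
        return np.zeros(self.ndim)

    @property
    def is_zero(self) -> bool:
        return True


class Harmonic(Potential):
    """Isotropic harmonic well  V(q) = 1/2 k |q - q0|^2."""

    def __init__(self, k: float, center=0.0, ndim: int = 1):
        if k <= 0:
            raise ConfigError("harmonic stiffness must be positive")
        self.k = float(k)
        self.ndim = ndim
        self.center = np.broadcast_to(np.asarray(center, dtype=float), (ndim,)).copy()

    def energy(self, q) -> float:
        q = _as_position(q, self.ndim)
        d = q - self.center
        return 0.5 * self.k * float(d @ d)

    def gradient(self, q) -> np.ndarray:
        q = _as_position(q, self.ndim)
        return self.k * (q - self.center)


class DoubleWell(Potential):
    """1-D quartic double well  V(q) = h ((q-q0)^2/w^2 - 1)^2.

    Minima at q0 ± w, barrier of height ``h`` (kJ/mol) at q0.  Used as a
    low-dimensional surrogate for bistable dissociation dynamics along a
    single reaction coordinate.
    """

    ndim = 1

    def __init__(self, height: float, center: float = 0.0, half_width: float = 1.0):
        if height <= 0:
            raise ConfigError("double-well barrier height must be positive")
        if half_width <= 0:
            raise ConfigError("double-well half width must be positive")
        self.height = float(height)
        self.center = float(center)
        self.half_width = float(half_width)

    def energy(self, q) -> float:
        q = _as_position(q, 1)
        u = (q[0] - self.center) ** 2 / self.half_width**2 - 1.0
        return self.height * u * u

    def gradient(self, q) -> np.ndarray:
        q = _as_position(q, 1)
        d = q[0] - self.center
        u = d * d / self.half_width**2 - 1.0
        return np.array([4.0 * self.height * u * d / self.half_width**2])

    @property
    def minima(self) -> tuple[float, float]:
        return (self.center - self.half_width, self.center + self.half_width)


# ---------------------------------------------------------------------------
# Mueller-Brown surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuellerBrownParams:
    """Parameters of the four-term Mueller-Brown surface.

    Amplitudes ``A`` are kJ/mol, exponent coefficients ``a``, ``b``, ``c``
    are nm^-2 and the term centers ``x0``, ``y0`` are nm.
    """

    A: tuple[float, ...] = (-20.0, -10.0, -17.0, 1.5)
    a: tuple[float, ...] = (-1.0, -1.0, -6.5, 0.7)
    b: tuple[float, ...] = (0.0, 0.0, 11.0, 0.6)
    c: tuple[float, ...] = (-10.0, -10.0, -6.5, 0.7)
    x0: tuple[float, ...] = (1.0, 0.0, -0.5, -1.0)
    y0: tuple[float, ...] = (0.0, 0.5, 1.5, 1.0)

    def __post_init__(self):
        for name in ("A", "a", "b", "c", "x0", "y0"):
            if len(getattr(self, name)) != 4:
                raise ConfigError("Mueller-Brown parameters require exactly 4 terms")


class MuellerBrown(Potential):
    """Two-dimensional Mueller-Brown potential.

    V(x, y) = sum_n A_n exp[a_n (x-x_n)^2 + b_n (x-x_n)(y-y_n) + c_n (y-y_n)^2]

    With the default parameters the surface has its global minimum near
    (-0.56, 1.44) nm and two shallower minima near (0.0, 0.5) and
    (0.6, 0.0) nm, separated by barriers of a few RT at 300 K.
    """

    ndim = 2

    def __init__(self, params: MuellerBrownParams | None = None):
        self.params = params if params is not None else MuellerBrownParams()
        p = self.params
        self._A = np.asarray(p.A, dtype=float)
        self._a = np.asarray(p.a, dtype=float)
        self._b = np.asarray(p.b, dtype=float)
        self._c = np.asarray(p.c, dtype=float)
        self._x0 = np.asarray(p.x0, dtype=float)
        self._y0 = np.asarray(p.y0, dtype=float)

    def _terms(self, q):
        dx = q[0] - self._x0
        dy = q[1] - self._y0
        expo = self._a * dx * dx + self._b * dx * dy + self._c * dy * dy
        return dx, dy, self._A * np.exp(expo)

    def energy(self, q) -> float:
        q = _as_position(q, 2)
        return float(self._terms(q)[2].sum())

    def gradient(self, q) -> np.ndarray:
        q = _as_position(q, 2)
        dx, dy, t = self._terms(q)
        gx = float((t * (2.0 * self._a * dx + self._b * dy)).sum())
        gy = float((t * (self._b * dx + 2.0 * self._c * dy)).sum())
        return np.array([gx, gy])


def mueller_brown_energy(q, params: MuellerBrownParams | None = None) -> float:
    return MuellerBrown(params).energy(q)


def mueller_brown_gradient(q, params: MuellerBrownParams | None = None) -> np.ndarray:
    return MuellerBrown(params).gradient(q)


# ---------------------------------------------------------------------------
# Bias potentials along one coordinate
# ---------------------------------------------------------------------------

#: Polynomial bias coefficients a_1..a_13 (built-in, used with prefactor
#: k = 50 kJ/mol/nm); the linear bias uses k = 1 kJ/mol/nm.
POLYNOMIAL_BIAS_COEFFS: tuple[float, ...] = (
    2.06e-02, -2.32e-02, 3.83e-03, 3.92e-02, -1.39e-02, -3.39e-02, 3.82e-04,
    1.24e-02, 3.37e-03, -1.18e-03, -7.50e-04, -1.38e-04, -8.81e-06,
)


@dataclass(frozen=True)
class BiasSpec:
    """Declarative description of a 1-D bias potential.

    ``linear``:      U_bias(x) = k x
    ``polynomial``:  U_bias(x) = k * sum_{i=1..m} a_i x^i
    """

    kind: str = "linear"
    k: float = 1.0
    coefficients: tuple[float, ...] = ()

    def __post_init__(self):
        if self.kind not in ("linear", "polynomial"):
            raise ConfigError(f"unknown bias kind {self.kind!r}")
        if self.kind == "polynomial" and len(self.coefficients) == 0:
            object.__setattr__(self, "coefficients", POLYNOMIAL_BIAS_COEFFS)

    @property
    def m(self) -> int:
        return len(self.coefficients)


class LinearBias(Potential):
    """U(x) = k x along a single coordinate."""

    ndim = 1

    def __init__(self, k: float):
        self.k = float(k)

    def energy(self, q) -> float:
        q = _as_position(q, 1)
        return self.k * q[0]

    def gradient(self, q) -> np.ndarray:
        _as_position(q, 1)
        return np.array([self.k])


class PolynomialBias(Potential):
    """U(x) = k * sum_{i=1..m} a_i x^i, evaluated by Horner's scheme."""

    ndim = 1

    def __init__(self, k: float, coefficients=POLYNOMIAL_BIAS_COEFFS):
        self.k = float(k)
        self.coefficients = tuple(float(c) for c in coefficients)
        if not self.coefficients:
            raise ConfigError("polynomial bias requires at least one coefficient")

    def energy(self, q) -> float:
        q = _as_position(q, 1)
        x = q[0]
        acc = 0.0
        for c in reversed(self.coefficients):
            acc = acc * x + c
        return self.k * acc * x

    def gradient(self, q) -> np.ndarray:
        q = _as_position(q, 1)
        x = q[0]
        acc = 0.0
        for i, c in zip(range(len(self.coefficients), 0, -1), reversed(self.coefficients)):
            acc = acc * x + i * c
        return np.array([self.k * acc])


def bias_from_spec(spec: BiasSpec) -> Potential:
    if spec.kind == "linear":
        return LinearBias(spec.k)
    if spec.kind == "polynomial":
        return PolynomialBias(spec.k, spec.coefficients)
    raise ConfigError(f"unknown bias kind {spec.kind!r}")


def bias_energy(x: float, spec: BiasSpec) -> float:
    """Energy of the 1-D bias at scalar position ``x`` (nm)."""
    return bias_from_spec(spec).energy([x])


def bias_gradient(x: float, spec: BiasSpec) -> float:
    """dU_bias/dx at scalar position ``x``."""
    return float(bias_from_spec(spec).gradient([x])[0])


def make_bias(spec: BiasSpec, ndim: int, axis: int = 0) -> Potential:
    """Lift a 1-D bias spec to an ``ndim``-dimensional potential along ``axis``."""
    base = bias_from_spec(spec)
    if ndim == 1 and axis == 0:
        return base
    return AxisPotential(base, axis=axis, ndim=ndim)


# ---------------------------------------------------------------------------
# Composition helpers
# ---------------------------------------------------------------------------

class AxisPotential(Potential):
    """Apply a 1-D potential along one coordinate of an n-D system."""

    def __init__(self, base: Potential, axis: int, ndim: int):
        if base.ndim != 1:
            raise ConfigError("AxisPotential wraps 1-D potentials only")
        if not (0 <= axis < ndim):
            raise ConfigError("axis out of range")
        self.base = base
        self.axis = axis
        self.ndim = ndim

    def energy(self, q) -> float:
        q = _as_position(q, self.ndim)
        return self.base.energy(q[self.axis : self.axis + 1])

    def gradient(self, q) -> np.ndarray:
        q = _as_position(q, self.ndim)
        g = np.zeros(self.ndim)
        g[self.axis] = self.base.gradient(q[self.axis : self.axis + 1])[0]
        return g

    @property
    def is_zero(self) -> bool:
        return self.base.is_zero


class ScaledPotential(Potential):
    def __init__(self, base: Potential, scale: float):
        self.base = base
        self.scale = float(scale)
        self.ndim = base.ndim

    def energy(self, q) -> float:
        return self.scale * self.base.energy(q)

    def gradient(self, q) -> np.ndarray:
        return self.scale * self.base.gradient(q)

    @property
    def is_zero(self) -> bool:
        return self.base.is_zero or self.scale == 0.0


class SumPotential(Potential):
    def __init__(self, terms):
        terms = list(terms)
        if not terms:
            raise ConfigError("SumPotential needs at least one term")
        ndims = {t.ndim for t in terms}
        if len(ndims) != 1:
            raise ConfigError(f"dimensionality mismatch among summed potentials: {ndims}")
        self.terms = terms
        self.ndim = terms[0].ndim

    def energy(self, q) -> float:
        return sum(t.energy(q) for t in self.terms)

    def gradient(self, q) -> np.ndarray:
        g = np.zeros(self.ndim)
        for t in self.terms:
            g = g + t.gradient(q)
        return g

    @property
    def is_zero(self) -> bool:
        return all(t.is_zero for t in self.terms)


@dataclass
class PotentialPair:
    """Simulation potential V, target potential Ṽ and perturbation U.

    The stored triple always satisfies the perturbation identity
    Ṽ(q) = V(q) + U(q).  ``convention`` records whether the pair was built
    from a perturbation U directly or from an enhanced-sampling bias
    (U = -U_bias, so that V = Ṽ + U_bias).
    """

    V: Potential
    V_target: Potential
    U: Potential
    convention: str = "perturbation"  # or "bias"

    def __post_init__(self):
        ndims = {self.V.ndim, self.V_target.ndim, self.U.ndim}
        if len(ndims) != 1:
            raise ConfigError(f"dimensionality mismatch in PotentialPair: {ndims}")

    @property
    def ndim(self) -> int:
        return self.V.ndim

    @property
    def unperturbed(self) -> bool:
        return self.U.is_zero

    def identity_residual(self, q) -> float:
        """Ṽ(q) - V(q) - U(q); zero by construction."""
        return self.V_target.energy(q) - self.V.energy(q) - self.U.energy(q)


def make_pair(target: Potential, U_or_bias: Potential | None = None,
              as_bias: bool = False) -> PotentialPair:
    """Build a :class:`PotentialPair` from a target potential and a
    perturbation (``as_bias=False``) or an enhanced-sampling bias
    (``as_bias=True``).

    Perturbation viewpoint: Ṽ = V + U, so the simulation potential is
    V = Ṽ - U.  Bias viewpoint: the simulation runs on the biased surface
    V = Ṽ + U_bias, equivalent to U = -U_bias.
    """
    if U_or_bias is None:
        U_or_bias = ZeroPotential(target.ndim)
    if U_or_bias.ndim != target.ndim:
        raise ConfigError(
            f"dimensionality mismatch: target ndim {target.ndim}, "
            f"perturbation ndim {U_or_bias.ndim}")
    if as_bias:
        U = ScaledPotential(U_or_bias, -1.0)
        V = SumPotential([target, U_or_bias])
        return PotentialPair(V=V, V_target=target, U=U, convention="bias")
    U = U_or_bias
    V = SumPotential([target, ScaledPotential(U, -1.0)])
    return PotentialPair(V=V, V_target=target, U=U, convention="perturbation")


def pair_from_simulation(V: Potential, U: Potential) -> PotentialPair:
    """Pair for prospective reweighting: given the simulation potential V and
    a perturbation U, the target is Ṽ = V + U."""
    if U.ndim != V.ndim:
        raise ConfigError("dimensionality mismatch between V and U")
    return PotentialPair(V=V, V_target=SumPotential([V, U]), U=U,
                         convention="perturbation")


def finite_difference_gradient(potential: Potential, q, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient; the standing oracle for analytic gradients."""
    if h <= 0:
        raise ConfigError("finite-difference step must be positive")
    q = _as_position(q, potential.ndim)
    g = np.zeros(potential.ndim)
    for i in range(potential.ndim):
        qp = q.copy()
        qm = q.copy()
        qp[i] += h
        qm[i] -= h
        g[i] = (potential.energy(qp) - potential.energy(qm)) / (2.0 * h)
    return g
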