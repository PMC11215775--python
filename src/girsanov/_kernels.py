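"""Numba-accelerated production kernels for ABO/ABOBA on built-in potentials.

The generic operator composition in :mod:`girsanov.integrators` is the
reference implementation; these kernels reproduce it step-for-step (same
noise-stream order, same arithmetic sequence) for the potential families
that production runs actually use -- harmonic wells, quartic double wells,
the Mueller-Brown surface, and linear/polynomial biases along one axis.
Equality of the two engines is asserted in the test suite.

Potentials are encoded as flat term lists: per term an integer code, a
padded parameter row, and an axis index (for 1-D terms lifted into n-D).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import SimulationBlowupError
from . import potentials as P

TERM_ZERO = 0
TERM_HARMONIC = 1      # params: k, c_0..c_{ndof-1}
TERM_DOUBLEWELL = 2    # params: h, z0, w           (axis)
TERM_LINEAR = 3        # params: k                  (axis)
TERM_POLY = 4          # params: k, m, a_1..a_m     (axis)
TERM_MB = 5            # params: A[4], a[4], b[4], c[4], x0[4], y0[4]

_PARAM_WIDTH = 32


def _encode_terms(pot, ndof: int, scale: float = 1.0, axis: int = 0):
    """Flatten a potential expression tree into term rows; None if unsupported."""
    if isinstance(pot, P.ZeroPotential):
        return []
    if isinstance(pot, P.ScaledPotential):
        return _encode_terms(pot.base, ndof, scale * pot.scale, axis)
    if isinstance(pot, P.SumPotential):
        out = []
        for t in pot.terms:
            enc = _encode_terms(t, ndof, scale, axis)
            if enc is None:
                return None
            out.extend(enc)
        return out
    if isinstance(pot, P.AxisPotential):
        return _encode_terms(pot.base, ndof, scale, pot.axis)
    row = np.zeros(_PARAM_WIDTH)
    if isinstance(pot, P.Harmonic):
        if 1 + pot.ndim > _PARAM_WIDTH:
            return None
        row[0] = scale * pot.k
        row[1:1 + pot.ndim] = pot.center
        return [(TERM_HARMONIC, row, axis)]
    if isinstance(pot, P.DoubleWell):
        row[:3] = scale * pot.height, pot.center, pot.half_width
        # note: scaling a double well scales the energy, handled via row[0]
        return [(TERM_DOUBLEWELL, row, axis)]
    if isinstance(pot, P.LinearBias):
        row[0] = scale * pot.k
        return [(TERM_LINEAR, row, axis)]
    if isinstance(pot, P.PolynomialBias):
        m = len(pot.coefficients)
        if 2 + m > _PARAM_WIDTH:
            return None
        row[0] = scale * pot.k
        row[1] = m
        row[2:2 + m] = pot.coefficients
        return [(TERM_POLY, row, axis)]
    if isinstance(pot, P.MuellerBrown):
        if ndof != 2:
            return None
        row[0:4] = np.asarray(pot.params.A) * scale
        row[4:8] = pot.params.a
        row[8:12] = pot.params.b
        row[12:16] = pot.params.c
        row[16:20] = pot.params.x0
        row[20:24] = pot.params.y0
        return [(TERM_MB, row, axis)]
    return None


def _pack(terms):
    n = len(terms)
    codes = np.zeros(n, dtype=np.int64)
    prm = np.zeros((n, _PARAM_WIDTH))
    axes = np.zeros(n, dtype=np.int64)
    for i, (c, row, ax) in enumerate(terms):
        codes[i], prm[i], axes[i] = c, row, ax
    return codes, prm, axes


def can_run(scheme, pair) -> bool:
    if scheme.name not in ("ABO", "ABOBA"):
        return False
    ndof = pair.ndim
    return (_encode_terms(pair.V, ndof) is not None
            and _encode_terms(pair.U, ndof) is not None)


@njit(cache=False)
def _term_gradient(code, prm, axis, q, grad):
    """Add the term's gradient into ``grad``; returns nothing."""
    if code == TERM_HARMONIC:
        k = prm[0]
        for l in range(q.size):
            grad[l] += k * (q[l] - prm[1 + l])
    elif code == TERM_DOUBLEWELL:
        h, z0, w = prm[0], prm[1], prm[2]
        d = q[axis] - z0
        u = d * d / (w * w) - 1.0
        grad[axis] += 4.0 * h * u * d / (w * w)
    elif code == TERM_LINEAR:
        grad[axis] += prm[0]
    elif code == TERM_POLY:
        k = prm[0]
        m = int(prm[1])
        x = q[axis]
        acc = 0.0
        for i in range(m, 0, -1):
            acc = acc * x + i * prm[1 + i]
        grad[axis] += k * acc
    elif code == TERM_MB:
        x, y = q[0], q[1]
        for n in range(4):
            A = prm[n]
            a = prm[4 + n]
            b = prm[8 + n]
            c = prm[12 + n]
            dx = x - prm[16 + n]
            dy = y - prm[20 + n]
            t = A * np.exp(a * dx * dx + b * dx * dy + c * dy * dy)
            grad[0] += t * (2.0 * a * dx + b * dy)
            grad[1] += t * (b * dx + 2.0 * c * dy)


@njit(cache=False)
def _term_energy(code, prm, axis, q):
    if code == TERM_HARMONIC:
        k = prm[0]
        e = 0.0
        for l in range(q.size):
            d = q[l] - prm[1 + l]
            e += 0.5 * k * d * d
        return e
    elif code == TERM_DOUBLEWELL:
        h, z0, w = prm[0], prm[1], prm[2]
        u = (q[axis] - z0) ** 2 / (w * w) - 1.0
        return h * u * u
    elif code == TERM_LINEAR:
        return prm[0] * q[axis]
    elif code == TERM_POLY:
        k = prm[0]
        m = int(prm[1])
        x = q[axis]
        acc = 0.0
        for i in range(m, 0, -1):
            acc = acc * x + prm[1 + i]
        return k * acc * x
    elif code == TERM_MB:
        x, y = q[0], q[1]
        e = 0.0
        for n in range(4):
            dx = x - prm[16 + n]
            dy = y - prm[20 + n]
            e += prm[n] * np.exp(prm[4 + n] * dx * dx + prm[8 + n] * dx * dy
                                 + prm[12 + n] * dy * dy)
        return e
    return 0.0


@njit(cache=False)
def _gradient(codes, prm, axes, q, grad):
    for l in range(grad.size):
        grad[l] = 0.0
    for t in range(codes.size):
        _term_gradient(codes[t], prm[t], axes[t], q, grad)


@njit(cache=False)
def _energy(codes, prm, axes, q):
    e = 0.0
    for t in range(codes.size):
        e += _term_energy(codes[t], prm[t], axes[t], q)
    return e


@njit(cache=False)
def _run_chunk(is_aboba, q, p, n_local, k0, n_out, dt, d, f, a, a_half,
               vcodes, vprm, vaxes, ucodes, uprm, uaxes, has_u,
               noise, coef, out_q, out_p, out_dS, out_U, dS_buf,
               blowup_bound):
    """Advance n_local steps; returns (status_step, dS_buffer).

    status_step < 0 on success, otherwise the 1-based global step index at
    which the simulation blew up.  Frames are written whenever the global
    step index is a multiple of n_out.
    """
    ndof = q.size
    gradv = np.empty(ndof)
    gradu = np.empty(ndof)
    half_dt = 0.5 * dt
    for s in range(n_local):
        if is_aboba:
            for l in range(ndof):
                q[l] += a_half[l] * p[l]
            _gradient(vcodes, vprm, vaxes, q, gradv)
            if has_u:
                _gradient(ucodes, uprm, uaxes, q, gradu)
            for l in range(ndof):
                p[l] -= half_dt * gradv[l]
            for l in range(ndof):
                eta = noise[s, l]
                if has_u:
                    de = coef[l] * gradu[l]
                    dS_buf += eta * de + 0.5 * de * de
                p[l] = d * p[l] + f[l] * eta
            for l in range(ndof):
                p[l] -= half_dt * gradv[l]
            for l in range(ndof):
                q[l] += a_half[l] * p[l]
        else:  # ABO
            for l in range(ndof):
                q[l] += a[l] * p[l]
            _gradient(vcodes, vprm, vaxes, q, gradv)
            if has_u:
                _gradient(ucodes, uprm, uaxes, q, gradu)
            for l in range(ndof):
                p[l] -= dt * gradv[l]
            for l in range(ndof):
                eta = noise[s, l]
                if has_u:
                    de = coef[l] * gradu[l]
                    dS_buf += eta * de + 0.5 * de * de
                p[l] = d * p[l] + f[l] * eta
        k = k0 + s + 1
        ok = True
        for l in range(ndof):
            if not np.isfinite(q[l]) or not np.isfinite(p[l]) \
                    or np.abs(q[l]) > blowup_bound:
                ok = False
        if not ok:
            return k, dS_buf
        if k % n_out == 0:
            fi = k // n_out
            for l in range(ndof):
                out_q[fi, l] = q[l]
                out_p[fi, l] = p[l]
            out_dS[fi] = dS_buf
            if has_u:
                out_U[fi] = _energy(ucodes, uprm, uaxes, q)
            dS_buf = 0.0
    return -1, dS_buf


#: steps per kernel invocation; bounds the pre-drawn noise block
CHUNK_STEPS = 500_000


def run(scheme, pair, params, ops, initial, n_steps, n_out, rng, reweight,
        out_q, out_p, out_dS, out_U, blowup_bound):
    """Driver: chunked noise generation + kernel calls.  Mirrors the generic
    engine's noise-stream order exactly (one standard_normal(ndof) per step)."""
    from .integrators import PhaseState

    ndof = params.ndof
    vcodes, vprm, vaxes = _pack(_encode_terms(pair.V, ndof))
    uterms = _encode_terms(pair.U, ndof) if reweight else []
    has_u = reweight and not pair.unperturbed and len(uterms) > 0
    ucodes, uprm, uaxes = _pack(uterms if has_u else [])
    if not has_u:
        ucodes = np.zeros(0, dtype=np.int64)
        uprm = np.zeros((0, _PARAM_WIDTH))
        uaxes = np.zeros(0, dtype=np.int64)

    is_aboba = scheme.name == "ABOBA"
    if has_u:
        from .integrators import _delta_eta_coef
        coef = _delta_eta_coef(scheme, ops)
    else:
        coef = np.zeros(ndof)

    q = initial.q.astype(float).copy()
    p = initial.p.astype(float).copy()
    if has_u:
        out_U[0] = _energy(ucodes, uprm, uaxes, q)

    chunk = max(n_out, (CHUNK_STEPS // n_out) * n_out)
    dS_buf = 0.0
    k0 = 0
    while k0 < n_steps:
        n_local = min(chunk, n_steps - k0)
        noise = rng.standard_normal((n_local, ndof))
        status, dS_buf = _run_chunk(
            is_aboba, q, p, n_local, k0, n_out, params.dt, ops.d, ops.f,
            ops.a, ops.a_half, vcodes, vprm, vaxes, ucodes, uprm, uaxes,
            has_u, noise, coef, out_q, out_p, out_dS, out_U, dS_buf,
            blowup_bound)
        if status >= 0:
            raise SimulationBlowupError(int(status))
        k0 += n_local
    return PhaseState(q, p, n_steps)
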