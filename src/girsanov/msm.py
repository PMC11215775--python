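"""Markov state models with Girsanov-reweighted count estimation.

Position space is discretized on a regular grid; sliding-window transition
pairs (s_m, s_{m+lag}) are counted with per-window path weights

    C̃_ij(τ) ∝ sum over windows m of W_m 1[s_m = i] 1[s_{m+lag} = j],

row-normalized into a (generally nonreversible) transition matrix, whose
left eigenvectors and implied timescales t_i(τ) = -τ/ln|λ_i(τ)| summarize
stationary density and slow kinetics.  With all weights equal the estimator
reduces bit-for-bit to the plain maximum-likelihood count matrix, and any
global rescaling of the weights cancels in the row normalization (which is
why the partition-function ratio in the initial-state factor can be
dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .errors import ConfigError, NumericalError

__all__ = [
    "GridDiscretization",
    "ReweightedCountMatrix",
    "TransitionMatrix",
    "SpectralResult",
    "discretize",
    "reweighted_count_matrix",
    "transition_matrix",
    "spectral_analysis",
    "implied_timescales",
    "stationary_distribution",
    "total_variation",
]


@dataclass(frozen=True)
class GridDiscretization:
    """Regular grid over a rectangular box.

    ``mins``/``maxs`` are per-dimension ranges in nm, ``nbins`` per-dimension
    bin counts.  States are numbered row-major (first dimension slowest).
    Bins are half-open [lo, hi) except the last bin of each dimension, which
    is closed so the upper corner belongs to the final state.
    """

    mins: tuple[float, ...]
    maxs: tuple[float, ...]
    nbins: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "mins", tuple(float(v) for v in self.mins))
        object.__setattr__(self, "maxs", tuple(float(v) for v in self.maxs))
        object.__setattr__(self, "nbins", tuple(int(v) for v in self.nbins))
        if not (len(self.mins) == len(self.maxs) == len(self.nbins)):
            raise ConfigError("grid dimensions inconsistent")
        if any(hi <= lo for lo, hi in zip(self.mins, self.maxs)):
            raise ConfigError("grid ranges must be nondegenerate")
        if any(n < 1 for n in self.nbins):
            raise ConfigError("bin counts must be >= 1")

    @property
    def ndim(self) -> int:
        return len(self.nbins)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.nbins))

    def bin_centers(self, dim: int) -> np.ndarray:
        edges = np.linspace(self.mins[dim], self.maxs[dim], self.nbins[dim] + 1)
        return 0.5 * (edges[:-1] + edges[1:])


def discretize(positions: np.ndarray, grid: GridDiscretization,
               out_of_range: str = "clip") -> np.ndarray:
    """Map a position trajectory to a row-major state-index sequence.

    Frames outside the box are clipped to the nearest edge bin (a warning
    summarizes the count) or, with ``out_of_range="drop"``, marked -1 for
    the caller to remove.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        raise ConfigError("empty trajectory")
    if positions.shape[1] != grid.ndim:
        raise ConfigError(
            f"positions have dimension {positions.shape[1]}, grid {grid.ndim}")
    if out_of_range not in ("clip", "drop"):
        raise ConfigError(f"unknown out_of_range mode {out_of_range!r}")
    dtraj = np.zeros(positions.shape[0], dtype=np.int64)
    oob = np.zeros(positions.shape[0], dtype=bool)
    for dim in range(grid.ndim):
        lo, hi, n = grid.mins[dim], grid.maxs[dim], grid.nbins[dim]
        x = positions[:, dim]
        idx = np.floor((x - lo) / (hi - lo) * n).astype(np.int64)
        oob |= (idx < 0) | (idx > n) | ((idx == n) & (x > hi))
        np.clip(idx, 0, n - 1, out=idx)  # also closes the last bin at x == hi
        dtraj = dtraj * n + idx
    n_oob = int(oob.sum())
    if n_oob:
        warnings.warn(f"{n_oob} of {positions.shape[0]} frames outside the "
                      f"grid box were {'clipped' if out_of_range == 'clip' else 'dropped'}",
                      stacklevel=2)
        if out_of_range == "drop":
            dtraj[oob] = -1
    return dtraj


@dataclass
class ReweightedCountMatrix:
    """Real-valued transition counts at one lag.

    Entries are sums of rescaled window weights exp(log W - log_rescale);
    ``log_rescale`` (the max log weight) is recorded but cancels in the row
    normalization.  With unit weights the entries are the integer
    sliding-window counts.
    """

    C: np.ndarray
    lag_frames: int
    lag_ps: float
    log_rescale: float = 0.0

    @property
    def n_states(self) -> int:
        return self.C.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.C.sum())


def _as_list(x):
    # a bare sequence of scalars is one trajectory, not a list of them
    if isinstance(x, (list, tuple)) and (len(x) == 0 or np.ndim(x[0]) > 0):
        return list(x)
    return [x]


def reweighted_count_matrix(dtrajs, lag: int, n_states: int,
                            log_weights=None, frame_interval_ps: float = 1.0,
                            ) -> ReweightedCountMatrix:
    """Sliding-window (stride 1) transition counts with optional path weights.

    ``dtrajs`` is one state-index sequence or a list of them (replicas);
    ``log_weights``, if given, must align: one array per trajectory with
    entry m holding log W of the window starting at frame m (length
    ``len(dtraj) - lag``).  Weights are exponentiated after a single global
    max-log shift shared by all trajectories, so replicas are combined on a
    common scale.
    """
    if lag < 1:
        raise ConfigError("lag must be >= 1")
    dtrajs = _as_list(dtrajs)
    if log_weights is None:
        lws = None
    else:
        lws = _as_list(log_weights)
        if len(lws) != len(dtrajs):
            raise ConfigError("one log-weight array per trajectory required")
    C = np.zeros((n_states, n_states))
    log_rescale = 0.0
    if lws is not None:
        all_max = [np.max(lw) for lw, d in zip(lws, dtrajs)
                   if len(d) > lag and len(lw)]
        log_rescale = float(max(all_max)) if all_max else 0.0
    for i, dtraj in enumerate(dtrajs):
        dtraj = np.asarray(dtraj, dtype=np.int64)
        n_win = len(dtraj) - lag
        if n_win <= 0:
            continue
        if dtraj.max() >= n_states:
            raise ConfigError("state index out of range")
        s0 = dtraj[:n_win]
        s1 = dtraj[lag:]
        keep = (s0 >= 0) & (s1 >= 0)
        if lws is None:
            w = np.ones(n_win)
        else:
            lw = np.asarray(lws[i], dtype=float)
            if len(lw) != n_win:
                raise ConfigError(
                    f"trajectory {i}: expected {n_win} window weights, "
                    f"got {len(lw)}")
            w = np.exp(lw - log_rescale)
        np.add.at(C, (s0[keep], s1[keep]), w[keep])
    return ReweightedCountMatrix(C=C, lag_frames=lag,
                                 lag_ps=lag * frame_interval_ps,
                                 log_rescale=log_rescale)


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix over the active state set.

    ``active_set`` maps the rows/columns of P back to the original state
    indices; states with zero outgoing weight are dropped (no self-loop
    padding, no reversibility constraint).
    """

    P: np.ndarray
    active_set: np.ndarray
    n_states_full: int

    @property
    def n_active(self) -> int:
        return self.P.shape[0]

    def embed(self, vec: np.ndarray) -> np.ndarray:
        """Embed a vector over the active set into the full state space."""
        full = np.zeros(self.n_states_full, dtype=vec.dtype)
        full[self.active_set] = vec
        return full


def transition_matrix(counts: ReweightedCountMatrix | np.ndarray) -> TransitionMatrix:
    """Row-normalize a count matrix, restricted to states with outgoing weight."""
    C = counts.C if isinstance(counts, ReweightedCountMatrix) else np.asarray(counts, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ConfigError("count matrix must be square")
    if np.any(C < 0):
        raise ConfigError("count matrix entries must be nonnegative")
    rowsum = C.sum(axis=1)
    active = np.flatnonzero(rowsum > 0)
    if active.size == 0:
        raise ConfigError("all-zero count matrix")
    sub = C[np.ix_(active, active)]
    subsum = sub.sum(axis=1)
    if np.any(subsum == 0):
        # outgoing weight went exclusively to dropped states; prune iteratively
        keep = active.copy()
        while True:
            sub = C[np.ix_(keep, keep)]
            subsum = sub.sum(axis=1)
            alive = subsum > 0
            if alive.all():
                break
            keep = keep[alive]
            if keep.size == 0:
                raise ConfigError("no states with outgoing weight remain")
        active = keep
    P = sub / subsum[:, None]
    return TransitionMatrix(P=P, active_set=active, n_states_full=C.shape[0])


@dataclass
class SpectralResult:
    """Eigenvalues (descending |λ|), left eigenvectors, and the active set.

    ``left_eigenvectors[i]`` is l_i over the active states: l_0 is
    entrywise nonnegative and sums to one (the stationary density); the
    others are sign-fixed (largest-|entry| positive) with unit 2-norm.
    """

    eigenvalues: np.ndarray
    left_eigenvectors: np.ndarray
    active_set: np.ndarray
    n_states_full: int
    is_complex: bool = False

    def stationary(self, full: bool = True) -> np.ndarray:
        l0 = np.real(self.left_eigenvectors[0])
        if not full:
            return l0
        out = np.zeros(self.n_states_full)
        out[self.active_set] = l0
        return out

    def eigenvector(self, i: int, full: bool = True) -> np.ndarray:
        v = self.left_eigenvectors[i]
        if not full:
            return v
        out = np.zeros(self.n_states_full, dtype=v.dtype)
        out[self.active_set] = v
        return out


def spectral_analysis(tm: TransitionMatrix | np.ndarray,
                      tol_stochastic: float = 1e-8) -> SpectralResult:
    """Left eigen-decomposition of a row-stochastic matrix.

    Eigenpairs are sorted by descending modulus (ties broken by descending
    real part).  Nonnegligible imaginary parts are surfaced (with a warning)
    rather than truncated.
    """
    if isinstance(tm, np.ndarray):
        P = np.asarray(tm, dtype=float)
        active = np.arange(P.shape[0])
        n_full = P.shape[0]
    else:
        P, active, n_full = tm.P, tm.active_set, tm.n_states_full
    rowsum = P.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > tol_stochastic) or np.any(P < -tol_stochastic):
        raise ConfigError("input matrix is not row-stochastic")
    vals, vecs = scipy.linalg.eig(P, left=True, right=False)
    order = np.lexsort((-vals.real, -np.abs(vals)))
    vals = vals[order]
    vecs = vecs[:, order].T  # row i is left eigenvector l_i
    imag_scale = float(np.max(np.abs(vals.imag))) if vals.size else 0.0
    is_complex = imag_scale > 1e-10
    if is_complex:
        warnings.warn(f"complex eigenvalues (max |Im| = {imag_scale:.3g}); "
                      "returning complex spectral data", stacklevel=2)
    else:
        vals = vals.real
        vecs = vecs.real
    if abs(vals[0] - 1.0) > 1e-6:
        warnings.warn(f"leading eigenvalue {vals[0]!r} deviates from 1",
                      stacklevel=2)
    out = vecs.astype(complex) if is_complex else vecs.copy()
    # stationary vector: nonnegative, sums to 1
    l0 = np.real(out[0])
    total = l0.sum()
    if total == 0:
        raise NumericalError("degenerate stationary eigenvector")
    l0 = l0 / total
    out[0] = np.clip(l0, 0.0, None) / np.clip(l0, 0.0, None).sum() \
        if np.any(l0 < -1e-12) else l0
    # remaining vectors: unit norm, largest-|entry| positive
    for i in range(1, out.shape[0]):
        v = out[i]
        nrm = np.linalg.norm(v)
        if nrm > 0:
            v = v / nrm
        pivot = int(np.argmax(np.abs(v)))
        if np.real(v[pivot]) < 0:
            v = -v
        out[i] = v
    return SpectralResult(eigenvalues=vals, left_eigenvectors=out,
                          active_set=active, n_states_full=n_full,
                          is_complex=is_complex)


def stationary_distribution(tm: TransitionMatrix, full: bool = True) -> np.ndarray:
    return spectral_analysis(tm).stationary(full=full)


def implied_timescales(spectra: dict[float, SpectralResult] | Sequence[tuple[float, SpectralResult]],
                       n_timescales: int = 1) -> "pd.DataFrame":
    """Implied timescales t_i(τ) = -τ / ln |λ_i(τ)| for a series of lags.

    ``spectra`` maps lag time (ps) to a spectral result.  A real eigenvalue
    λ_i <= 0 or any |λ_i| >= 1 yields NaN (undefined marker), never an
    exception; complex eigenvalues inside the unit disk use their modulus.
    Returns a tidy table with columns lag_ps, t_1 .. t_n (ps).
    """
    import pandas as pd

    items = sorted(spectra.items()) if isinstance(spectra, dict) else sorted(spectra)
    lags = [lag for lag, _ in items]
    if any(b <= a for a, b in zip(lags, lags[1:])):
        raise ConfigError("lag times must be strictly increasing")
    rows = []
    for lag, spec in items:
        row = {"lag_ps": lag}
        for i in range(1, n_timescales + 1):
            t = np.nan
            if i < len(spec.eigenvalues):
                lam = complex(spec.eigenvalues[i])
                mod = abs(lam)
                real_nonpositive = abs(lam.imag) < 1e-12 and lam.real <= 0.0
                if 0.0 < mod < 1.0 and not real_nonpositive:
                    t = -lag / np.log(mod)
            row[f"t_{i}"] = t
        rows.append(row)
    return pd.DataFrame(rows)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance between two distributions on the same grid."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ConfigError("distributions must share a state space")
    return 0.5 * float(np.abs(p - q).sum())
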