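"""Path-weight assembly: random-number differences, interval accumulation,
initial-state ratios, sliding windows, and the reweighting-factor file.

For a path x = (x_k', ..., x_k'+n) started at a recorded frame k', the
relative path probability at the target potential Ṽ versus the simulation
potential V factorizes as  W = g(x_k') * M[x | x_k'] with

    log g = -U(q_k') / RT            (initial-state Boltzmann ratio,
                                      partition-function constant omitted)
    log M = -sum over steps of s_k,  s_k = sum_l (η_l Δη_l + 1/2 Δη_l^2)

where Δη is the integrator-specific random-number difference: the shift of
the Gaussian noise that would make the step taken at V coincide with the
same step at Ṽ.  During a simulation the per-step s_k are accumulated in a
buffer over each recording interval of n_out steps and flushed to a record
ΔS^(k') aligned with the trajectory frames; any window of whole recording
intervals can then be reweighted after the fact.

Everything is carried in log space; exponentiation happens only inside the
count-matrix estimator, after a max-log shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, FileFormatError, ReweightingUndefinedError
from .integrators import (NoiseDraw, OperatorParams, SplittingScheme,
                          _delta_eta_coef, parse_scheme)

__all__ = [
    "DeltaEta",
    "ReweightingRecord",
    "ReweightingTrajectory",
    "PathWeight",
    "delta_eta",
    "log_m_increment",
    "IntervalAccumulator",
    "accumulate_interval",
    "initial_state_log_ratio",
    "window_weight",
    "window_log_weights",
    "write_reweighting_file",
    "read_reweighting_file",
    "write_trajectory_file",
    "read_trajectory_file",
    "write_trajectory_h5",
    "read_trajectory_h5",
]


@dataclass
class DeltaEta:
    """Per-dof random-number difference; ``delta2`` only for two-noise schemes."""

    delta1: np.ndarray
    delta2: Optional[np.ndarray] = None


@dataclass
class ReweightingRecord:
    """One row of the reweighting-factor trajectory."""

    frame_index: int
    time_ps: float
    dS: float     # log-weight increment accumulated over the preceding interval
    U_q: float    # perturbation energy U(q_k') in kJ/mol


@dataclass
class ReweightingTrajectory:
    """Columnar reweighting records aligned one-to-one with trajectory frames."""

    frame_index: np.ndarray
    time_ps: np.ndarray
    dS: np.ndarray
    U_q: np.ndarray

    def __post_init__(self):
        n = len(self.frame_index)
        for name in ("time_ps", "dS", "U_q"):
            if len(getattr(self, name)) != n:
                raise ConfigError("reweighting columns must have equal length")
        if n and self.dS[0] != 0.0:
            raise ConfigError("the record at the first frame must have dS = 0")

    def __len__(self) -> int:
        return len(self.frame_index)

    def __getitem__(self, i: int) -> ReweightingRecord:
        return ReweightingRecord(int(self.frame_index[i]), float(self.time_ps[i]),
                                 float(self.dS[i]), float(self.U_q[i]))


@dataclass
class PathWeight:
    """Log-decomposed path weight  log W = log g + log M."""

    log_g: float
    log_M: float

    @property
    def log_W(self) -> float:
        return self.log_g + self.log_M

    @property
    def W(self) -> float:
        return float(np.exp(self.log_W))


def delta_eta(scheme: SplittingScheme | str, grad_u: np.ndarray,
              ops: OperatorParams, as_bias: bool = False) -> DeltaEta:
    """Random-number difference for one integrator step.

    ``grad_u`` is the perturbation gradient ∇U evaluated at the scheme's
    tagged position (after the drift for ABO, at the mid-step position for
    ABOBA).  With ``as_bias=True`` the input is interpreted as the bias
    gradient ∇U_bias and the sign is flipped (U = -U_bias).

    Closed forms (per dof, certified against the step-inversion oracle):

        ABO:    Δη = (d Δt / f) ∂U
        ABOBA:  Δη = ((1 + d) Δt / (2 f)) ∂U
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    grad_u = np.atleast_1d(np.asarray(grad_u, dtype=float))
    if as_bias:
        grad_u = -grad_u
    coef = _delta_eta_coef(scheme, ops)  # raises for f = 0 / uncertified scheme
    return DeltaEta(delta1=coef * grad_u)


def log_m_increment(noise: NoiseDraw, delta: DeltaEta) -> float:
    """One-step contribution s_k = sum_l (η Δη + 1/2 Δη^2), both channels.

    The conditional path-probability ratio over a window is
    M = exp(-sum_k s_k); per step and dof, exp(-s_k) equals the
    standard-normal density ratio φ(η + Δη)/φ(η).
    """
    d1 = np.atleast_1d(delta.delta1)
    e1 = np.atleast_1d(noise.eta1)
    if e1.shape != d1.shape:
        raise ConfigError("noise/delta shape mismatch")
    s = float(e1 @ d1 + 0.5 * d1 @ d1)
    if (noise.eta2 is None) != (delta.delta2 is None):
        raise ConfigError("noise and delta disagree on the number of channels")
    if noise.eta2 is not None:
        d2 = np.atleast_1d(delta.delta2)
        e2 = np.atleast_1d(noise.eta2)
        if e2.shape != d2.shape:
            raise ConfigError("noise/delta shape mismatch")
        s += float(e2 @ d2 + 0.5 * d2 @ d2)
    return s


class IntervalAccumulator:
    """Streaming buffer for ΔS over one recording interval of n_out steps."""

    def __init__(self, n_out: int):
        if n_out < 1:
            raise ConfigError("n_out must be >= 1")
        self.n_out = n_out
        self._buf = 0.0
        self._count = 0

    def add(self, increment: float) -> None:
        self._buf += increment
        self._count += 1

    def flush(self) -> float:
        """Return ΔS for the elapsed interval and reset the buffer."""
        if self._count != self.n_out:
            raise ConfigError(
                f"interval holds {self._count} increments, expected {self.n_out}")
        out = self._buf
        self._buf = 0.0
        self._count = 0
        return out


def accumulate_interval(increments) -> float:
    """ΔS for one recording interval: the plain sum of its step increments."""
    increments = list(increments)
    acc = IntervalAccumulator(len(increments))
    for inc in increments:
        acc.add(inc)
    return acc.flush()


def initial_state_log_ratio(U_q0: float, RT: float) -> float:
    """log g = -U(q_0)/RT, the Boltzmann ratio of the window's first frame
    between the target and simulation ensembles (Z/Z̃ omitted; the
    Maxwell-Boltzmann momentum factors cancel identically)."""
    if RT <= 0:
        raise ConfigError("RT must be positive")
    return -float(U_q0) / RT


def window_weight(records: ReweightingTrajectory, start: int, n_interval: int,
                  RT: float) -> PathWeight:
    """Path weight of the sliding window covering recorded frames
    [start, start + n_interval]."""
    if n_interval < 1:
        raise ConfigError("n_interval must be >= 1")
    if start < 0 or start + n_interval > len(records) - 1:
        raise ConfigError(
            f"window [{start}, {start + n_interval}] exceeds trajectory "
            f"of {len(records)} frames")
    log_g = initial_state_log_ratio(records.U_q[start], RT)
    log_M = -float(np.sum(records.dS[start + 1: start + n_interval + 1]))
    return PathWeight(log_g=log_g, log_M=log_M)


def window_log_weights(records: ReweightingTrajectory, n_interval: int,
                       RT: float) -> np.ndarray:
    """log W for every window start frame, vectorized via a cumulative sum.

    Returns an array of length ``len(records) - n_interval``; entry m is the
    log weight of the window starting at recorded frame m.
    """
    if n_interval < 1:
        raise ConfigError("n_interval must be >= 1")
    n = len(records)
    if n_interval >= n:
        raise ConfigError("window length exceeds trajectory")
    cum = np.cumsum(records.dS)  # cum[i] = sum of dS[0..i]
    log_M = -(cum[n_interval:] - cum[:-n_interval])
    log_g = -records.U_q[: n - n_interval] / RT
    return log_g + log_M


# ---------------------------------------------------------------------------
# File formats (TSV, lockstep with the position trajectory)
# ---------------------------------------------------------------------------

_RW_COLUMNS = ["frame_index", "time_ps", "dS", "U_kJ_per_mol"]


def write_reweighting_file(records: ReweightingTrajectory, path) -> None:
    df = pd.DataFrame({
        "frame_index": records.frame_index.astype(int),
        "time_ps": records.time_ps,
        "dS": records.dS,
        "U_kJ_per_mol": records.U_q,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_reweighting_file(path) -> ReweightingTrajectory:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FileFormatError(f"cannot parse reweighting file {path}: {exc}")
    missing = [c for c in _RW_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(
            f"reweighting file {path} lacks column(s) {missing}")
    frames = df["frame_index"].to_numpy()
    expected = np.arange(len(frames))
    if len(frames) and not np.array_equal(frames, expected):
        bad = int(np.argmax(frames != expected))
        raise FileFormatError(
            f"reweighting file {path}: row {bad} has frame_index "
            f"{frames[bad]}, expected {bad}")
    for col in ("dS", "U_kJ_per_mol"):
        vals = df[col].to_numpy(dtype=float)
        if len(vals) and not np.all(np.isfinite(vals)):
            bad = int(np.argmax(~np.isfinite(vals)))
            raise FileFormatError(
                f"reweighting file {path}: row {bad} has non-finite {col}")
    return ReweightingTrajectory(
        frame_index=frames.astype(int),
        time_ps=df["time_ps"].to_numpy(dtype=float),
        dS=df["dS"].to_numpy(dtype=float),
        U_q=df["U_kJ_per_mol"].to_numpy(dtype=float),
    )


def write_trajectory_file(times: np.ndarray, positions: np.ndarray, path) -> None:
    """Columnar position trajectory: frame_index, time_ps, one column per dof."""
    positions = np.atleast_2d(positions)
    data = {"frame_index": np.arange(positions.shape[0]),
            "time_ps": times}
    for l in range(positions.shape[1]):
        data[f"q{l}"] = positions[:, l]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_trajectory_h5(times: np.ndarray, positions: np.ndarray, path,
                        records: ReweightingTrajectory | None = None) -> None:
    """Binary array-container alternative to the TSV files (same schema),
    for large runs: datasets time_ps, positions, and optionally dS and
    U_kJ_per_mol."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_ps", data=np.asarray(times, dtype=float))
        fh.create_dataset("positions", data=np.atleast_2d(positions))
        if records is not None:
            fh.create_dataset("dS", data=records.dS)
            fh.create_dataset("U_kJ_per_mol", data=records.U_q)


def read_trajectory_h5(path) -> tuple[np.ndarray, np.ndarray,
                                      ReweightingTrajectory | None]:
    import h5py

    with h5py.File(path, "r") as fh:
        if "time_ps" not in fh or "positions" not in fh:
            raise FileFormatError(f"{path}: missing time_ps/positions datasets")
        times = fh["time_ps"][:]
        positions = fh["positions"][:]
        records = None
        if "dS" in fh:
            if "U_kJ_per_mol" not in fh or len(fh["dS"]) != len(times):
                raise FileFormatError(f"{path}: misaligned reweighting datasets")
            records = ReweightingTrajectory(
                frame_index=np.arange(len(times)), time_ps=times.copy(),
                dS=fh["dS"][:], U_q=fh["U_kJ_per_mol"][:])
    return times, positions, records


def read_trajectory_file(path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover
        raise FileFormatError(f"cannot parse trajectory file {path}: {exc}")
    if "frame_index" not in df.columns or "time_ps" not in df.columns:
        raise FileFormatError(f"trajectory file {path} lacks header columns")
    qcols = [c for c in df.columns if c.startswith("q")]
    if not qcols:
        raise FileFormatError(f"trajectory file {path} has no position columns")
    frames = df["frame_index"].to_numpy()
    expected = np.arange(len(frames))
    if len(frames) and not np.array_equal(frames, expected):
        bad = int(np.argmax(frames != expected))
        raise FileFormatError(
            f"trajectory file {path}: row {bad} has frame_index "
            f"{frames[bad]}, expected {bad}")
    return (df["time_ps"].to_numpy(dtype=float),
            df[qcols].to_numpy(dtype=float))
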