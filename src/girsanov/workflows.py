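"""Config-driven experiments: biased/unbiased paired runs with a three-way
MSM comparison (direct unbiased, biased unreweighted, biased reweighted).

Two built-in studies:

* ``mueller_brown`` -- 2-D Mueller-Brown surface, linear bias of
  1 kJ/mol/nm along x, ABOBA at Δt = 0.5 fs, ξ = 5/ps, T = 300 K,
  6 x 6 MSM grid over [-3.5, 1.5] x [-1.5, 3.5] nm.
* ``double_well`` -- 1-D quartic double well (barrier 8 kJ/mol, minima at
  0.35 and 0.55 nm, particle mass 40.08 amu, ξ = 2/ps, Δt = 1 fs) standing
  in for a bistable ion-dissociation coordinate, linear bias of 5 kJ/mol/nm,
  50-state MSM grid over [0.3, 0.6] nm.

Desk-scale defaults run in minutes on one core; sampling sizes can be
scaled with a single multiplier.  Every experiment is reproducible from
(config, seed).
"""

from __future__ import annotations

import json
import tomllib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .constants import FS_TO_PS, GAS_CONSTANT
from .errors import ConfigError
from .integrators import (LangevinParams, PhaseState, maxwell_boltzmann_momenta,
                          parse_scheme, simulate)
from .msm import (GridDiscretization, discretize, implied_timescales,
                  reweighted_count_matrix, spectral_analysis,
                  total_variation, transition_matrix)
from .potentials import (BiasSpec, DoubleWell, MuellerBrown, Potential,
                         make_bias, make_pair)
from .reweighting import (window_log_weights, write_reweighting_file,
                          write_trajectory_file)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "mueller_brown_config",
    "double_well_config",
    "run_experiment",
    "run_mb_experiment",
    "run_doublewell_surrogate",
    "generate_fixtures",
    "boltzmann_reference",
]


@dataclass(frozen=True)
class ExperimentConfig:
    system: str = "mueller_brown"
    bias: BiasSpec = field(default_factory=lambda: BiasSpec("linear", 1.0))
    bias_axis: int = 0
    scheme: str = "ABOBA"
    dt_fs: float = 0.5
    xi: float = 5.0          # 1/ps
    T: float = 300.0         # K
    mass: float = 1.0        # amu per dof
    n_steps: int = 5_000_000
    n_out: int = 10
    n_replicas: int = 5
    seed: int = 2024
    burn_in_frames: int = 20_000
    grid_mins: tuple[float, ...] = (-3.5, -1.5)
    grid_maxs: tuple[float, ...] = (1.5, 3.5)
    grid_bins: tuple[int, ...] = (6, 6)
    lags_ps: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5, 4.5)
    comparison_lag_ps: float = 2.5
    out_prefix: Optional[str] = None

    @property
    def params(self) -> LangevinParams:
        ndof = len(self.grid_bins)
        return LangevinParams(dt=self.dt_fs * FS_TO_PS, xi=self.xi, T=self.T,
                              masses=np.full(ndof, self.mass))

    @property
    def grid(self) -> GridDiscretization:
        return GridDiscretization(self.grid_mins, self.grid_maxs, self.grid_bins)

    @property
    def frame_interval_ps(self) -> float:
        return self.n_out * self.dt_fs * FS_TO_PS

    def lag_frames(self, lag_ps: float) -> int:
        ratio = lag_ps / self.frame_interval_ps
        lag = int(round(ratio))
        if lag < 1 or abs(ratio - lag) > 1e-9:
            raise ConfigError(
                f"lag {lag_ps} ps is not a positive multiple of the "
                f"recording interval {self.frame_interval_ps} ps")
        return lag

    def scaled(self, scale: float) -> "ExperimentConfig":
        """Shrink (or grow) the sampling effort by a multiplier."""
        if scale <= 0:
            raise ConfigError("scale must be positive")
        n = max(self.n_out, int(self.n_steps * scale))
        n -= n % self.n_out
        burn = int(self.burn_in_frames * scale)
        max_lag = max(self.lag_frames(l) for l in self.lags_ps)
        n = max(n, self.n_out * (burn + 4 * max_lag + 10))
        return replace(self, n_steps=n, burn_in_frames=burn)

    @staticmethod
    def from_toml(path) -> "ExperimentConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return ExperimentConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "ExperimentConfig":
        system = raw.get("system", {}).get("kind", "mueller_brown")
        base = {"mueller_brown": mueller_brown_config,
                "double_well": double_well_config}.get(system)
        if base is None:
            raise ConfigError(f"unknown system {system!r}")
        cfg = base()
        b = raw.get("bias", {})
        if b:
            cfg = replace(cfg, bias=BiasSpec(kind=b.get("kind", cfg.bias.kind),
                                             k=b.get("k", cfg.bias.k)))
        integ = raw.get("integrator", {})
        cfg = replace(cfg,
                      scheme=integ.get("scheme", cfg.scheme),
                      dt_fs=integ.get("dt_fs", cfg.dt_fs),
                      xi=integ.get("xi", cfg.xi),
                      T=integ.get("T", cfg.T),
                      mass=integ.get("mass", cfg.mass))
        samp = raw.get("sampling", {})
        cfg = replace(cfg,
                      n_steps=samp.get("n_steps", cfg.n_steps),
                      n_out=samp.get("n_out", cfg.n_out),
                      n_replicas=samp.get("n_replicas", cfg.n_replicas),
                      seed=samp.get("seed", cfg.seed),
                      burn_in_frames=samp.get("burn_in_frames", cfg.burn_in_frames))
        msm = raw.get("msm", {})
        cfg = replace(cfg,
                      lags_ps=tuple(msm.get("lags_ps", cfg.lags_ps)),
                      comparison_lag_ps=msm.get("comparison_lag_ps",
                                                cfg.comparison_lag_ps))
        return cfg


def mueller_brown_config(**overrides) -> ExperimentConfig:
    return replace(ExperimentConfig(), **overrides)


def double_well_config(**overrides) -> ExperimentConfig:
    cfg = ExperimentConfig(
        system="double_well",
        bias=BiasSpec("linear", 5.0),
        dt_fs=1.0, xi=2.0, mass=40.08,
        n_steps=2_000_000, n_out=10, n_replicas=3,
        burn_in_frames=5_000,
        grid_mins=(0.3,), grid_maxs=(0.6,), grid_bins=(50,),
        lags_ps=(1.0, 2.0, 3.0, 4.0, 5.0),
        comparison_lag_ps=2.0,
    )
    return replace(cfg, **overrides)


#: Double-well surrogate geometry (nm, kJ/mol): barrier at 0.45 nm,
#: minima at 0.35 / 0.55 nm.
_DW_BARRIER = 8.0
_DW_CENTER = 0.45
_DW_HALF_WIDTH = 0.1


def target_potential(config: ExperimentConfig) -> Potential:
    if config.system == "mueller_brown":
        return MuellerBrown()
    if config.system == "double_well":
        return DoubleWell(height=_DW_BARRIER, center=_DW_CENTER,
                          half_width=_DW_HALF_WIDTH)
    raise ConfigError(f"unknown system {config.system!r}")


def boltzmann_reference(config: ExperimentConfig, potential: Potential,
                        n_sub: int = 40) -> np.ndarray:
    """Discretized Boltzmann density of ``potential`` on the config's grid
    (midpoint quadrature with ``n_sub`` points per bin per dimension)."""
    grid = config.grid
    RT = GAS_CONSTANT * config.T
    axes = []
    for dim in range(grid.ndim):
        edges = np.linspace(grid.mins[dim], grid.maxs[dim],
                            grid.nbins[dim] * n_sub + 1)
        axes.append(0.5 * (edges[:-1] + edges[1:]))
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    energies = np.array([potential.energy(p) for p in pts])
    w = np.exp(-(energies - energies.min()) / RT)
    dens = np.zeros(grid.n_states)
    dtraj = discretize(pts, grid)
    np.add.at(dens, dtraj, w)
    return dens / dens.sum()


@dataclass
class ReplicaData:
    dtraj: np.ndarray
    dS: np.ndarray
    U_q: np.ndarray
    positions: np.ndarray


@dataclass
class ExperimentResult:
    """Three-way MSM comparison bundle."""

    config: ExperimentConfig
    stationary: dict            # variant -> full-grid stationary vector
    eigenvector2: dict          # variant -> full-grid l_1
    timescales: pd.DataFrame    # lag_ps x variant t_1 columns
    replica_t1: dict            # variant -> per-replica t_1 at comparison lag
    lambda0: dict               # variant -> {lag_ps: leading eigenvalue}
    tv_reweighted_vs_direct: float
    tv_unreweighted_vs_direct: float
    tv_reweighted_vs_boltzmann: float
    tv_unreweighted_vs_boltzmann: float
    weight_stats: dict          # log-weight distribution + effective sample size
    n_frames_per_replica: int

    def summary(self) -> dict:
        return {
            "system": self.config.system,
            "n_replicas": self.config.n_replicas,
            "n_steps": self.config.n_steps,
            "n_frames_per_replica": self.n_frames_per_replica,
            "comparison_lag_ps": self.config.comparison_lag_ps,
            "tv_reweighted_vs_direct": self.tv_reweighted_vs_direct,
            "tv_unreweighted_vs_direct": self.tv_unreweighted_vs_direct,
            "tv_reweighted_vs_boltzmann": self.tv_reweighted_vs_boltzmann,
            "tv_unreweighted_vs_boltzmann": self.tv_unreweighted_vs_boltzmann,
            "weight_stats": self.weight_stats,
            "lambda0": {k: v for k, v in self.lambda0.items()},
        }

    def write(self, out_prefix) -> None:
        out = Path(out_prefix)
        out.mkdir(parents=True, exist_ok=True)
        grid = self.config.grid
        ev = pd.DataFrame({"state": np.arange(grid.n_states)})
        for variant, vec in self.stationary.items():
            ev[f"l0_{variant}"] = vec
        for variant, vec in self.eigenvector2.items():
            ev[f"l1_{variant}"] = np.real(vec)
        ev.to_csv(out / "eigenvectors.csv", index=False)
        self.timescales.to_csv(out / "implied_timescales.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=float)


def _simulate_replica(config: ExperimentConfig, pair, replica: int,
                      biased: bool) -> ReplicaData:
    params = config.params
    grid = config.grid
    rng = np.random.default_rng([config.seed, replica, int(biased)])
    q0 = np.array([rng.uniform(grid.mins[d], grid.maxs[d])
                   for d in range(grid.ndim)])
    p0 = maxwell_boltzmann_momenta(params, rng)
    res = simulate(PhaseState(q0, p0), config.scheme, pair, params,
                   n_steps=config.n_steps, n_out=config.n_out, rng=rng,
                   reweight=biased)
    burn = config.burn_in_frames
    if burn >= res.n_frames - 1:
        raise ConfigError("burn-in longer than trajectory")
    positions = res.positions[burn:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dtraj = discretize(positions, grid)
    if biased:
        dS = res.reweighting.dS[burn:].copy()
        dS[0] = 0.0  # the interval ending at the first kept frame is discarded
        U_q = res.reweighting.U_q[burn:]
    else:
        dS = np.zeros(len(dtraj))
        U_q = np.zeros(len(dtraj))
    return ReplicaData(dtraj=dtraj, dS=dS, U_q=U_q, positions=positions)


def _msm_variant(config, replicas, lag_frames, reweighted: bool):
    """Pooled-count transition matrix + spectral result for one variant."""
    from .reweighting import ReweightingTrajectory

    dtrajs = [r.dtraj for r in replicas]
    lws = None
    if reweighted:
        RT = GAS_CONSTANT * config.T
        lws = []
        for r in replicas:
            rec = ReweightingTrajectory(frame_index=np.arange(len(r.dtraj)),
                                        time_ps=np.arange(len(r.dtraj), dtype=float),
                                        dS=r.dS, U_q=r.U_q)
            lws.append(window_log_weights(rec, lag_frames, RT))
    counts = reweighted_count_matrix(dtrajs, lag_frames, config.grid.n_states,
                                     log_weights=lws,
                                     frame_interval_ps=config.frame_interval_ps)
    tm = transition_matrix(counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = spectral_analysis(tm)
    return counts, tm, spec, lws


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate unbiased and biased replicas and build the three-way MSM
    comparison across the configured lag list."""
    target = target_potential(config)
    ndof = config.grid.ndim
    pair_direct = make_pair(target)
    pair_biased = make_pair(target, make_bias(config.bias, ndof, config.bias_axis),
                            as_bias=True)

    direct = [_simulate_replica(config, pair_direct, r, biased=False)
              for r in range(config.n_replicas)]
    biased = [_simulate_replica(config, pair_biased, r, biased=True)
              for r in range(config.n_replicas)]

    variants = {"direct": (direct, False),
                "biased": (biased, False),
                "reweighted": (biased, True)}

    lambda0 = {v: {} for v in variants}
    spectra = {v: {} for v in variants}
    for lag_ps in config.lags_ps:
        lf = config.lag_frames(lag_ps)
        for v, (reps, rw) in variants.items():
            _, _, spec, _ = _msm_variant(config, reps, lf, rw)
            spectra[v][lag_ps] = spec
            lambda0[v][lag_ps] = float(np.real(spec.eigenvalues[0]))

    its = None
    for v in variants:
        tab = implied_timescales(spectra[v], n_timescales=1)
        tab = tab.rename(columns={"t_1": f"t1_{v}"})
        its = tab if its is None else its.merge(tab, on="lag_ps")

    clag = config.comparison_lag_ps
    clf = config.lag_frames(clag)
    stationary = {}
    eigenvector2 = {}
    for v in variants:
        spec = spectra[v][clag]
        stationary[v] = spec.stationary(full=True)
        eigenvector2[v] = (spec.eigenvector(1, full=True)
                           if len(spec.eigenvalues) > 1
                           else np.zeros(config.grid.n_states))

    # per-replica slowest timescale at the comparison lag (bootstrap basis)
    replica_t1 = {v: [] for v in variants}
    for v, (reps, rw) in variants.items():
        for r in reps:
            try:
                _, _, spec, _ = _msm_variant(config, [r], clf, rw)
                lam = complex(spec.eigenvalues[1])
                mod = abs(lam)
                t1 = -clag / np.log(mod) if 0 < mod < 1 else np.nan
            except Exception:
                t1 = np.nan
            replica_t1[v].append(float(t1))

    # weight diagnostics at the comparison lag
    _, _, _, lws = _msm_variant(config, biased, clf, True)
    allw = np.concatenate(lws)
    shifted = np.exp(allw - allw.max())
    ess = float(shifted.sum() ** 2 / (shifted ** 2).sum())
    weight_stats = {
        "log_w_min": float(allw.min()),
        "log_w_median": float(np.median(allw)),
        "log_w_max": float(allw.max()),
        "n_windows": int(allw.size),
        "effective_sample_size": ess,
    }

    boltz = boltzmann_reference(config, target)
    result = ExperimentResult(
        config=config,
        stationary=stationary,
        eigenvector2=eigenvector2,
        timescales=its,
        replica_t1=replica_t1,
        lambda0=lambda0,
        tv_reweighted_vs_direct=total_variation(stationary["reweighted"],
                                                stationary["direct"]),
        tv_unreweighted_vs_direct=total_variation(stationary["biased"],
                                                  stationary["direct"]),
        tv_reweighted_vs_boltzmann=total_variation(stationary["reweighted"], boltz),
        tv_unreweighted_vs_boltzmann=total_variation(stationary["biased"], boltz),
        weight_stats=weight_stats,
        n_frames_per_replica=len(direct[0].dtraj),
    )
    if config.out_prefix:
        result.write(config.out_prefix)
    return result


def run_mb_experiment(config: ExperimentConfig | None = None) -> ExperimentResult:
    config = config or mueller_brown_config()
    if config.system != "mueller_brown":
        raise ConfigError("config is not a Mueller-Brown setup")
    return run_experiment(config)


def run_doublewell_surrogate(config: ExperimentConfig | None = None) -> ExperimentResult:
    config = config or double_well_config()
    if config.system != "double_well":
        raise ConfigError("config is not a double-well setup")
    return run_experiment(config)


def bootstrap_interval(values, n_boot: int = 1000, seed: int = 0,
                       levels=(2.5, 97.5)) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of a small sample
    (e.g. per-replica implied timescales)."""
    values = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if values.size == 0:
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, levels)
    return float(lo), float(hi)


def generate_fixtures(seed: int, outdir) -> list[Path]:
    """Deterministic 20-step golden trajectories + reweighting files for the
    certified schemes, on the linearly biased Mueller-Brown surface."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    target = MuellerBrown()
    pair = make_pair(target, make_bias(BiasSpec("linear", 1.0), 2), as_bias=True)
    params = LangevinParams(dt=0.5 * FS_TO_PS, xi=5.0, T=300.0,
                            masses=np.array([1.0, 1.0]))
    for tag, scheme in enumerate(("ABO", "ABOBA")):
        rng = np.random.default_rng([seed, tag])
        q0 = np.array([-0.5, 1.5])
        p0 = maxwell_boltzmann_momenta(params, rng)
        res = simulate(PhaseState(q0, p0), scheme, pair, params, n_steps=20,
                       n_out=2, rng=rng, engine="generic")
        tpath = outdir / f"{scheme.lower()}_traj.tsv"
        rpath = outdir / f"{scheme.lower()}_rw.tsv"
        write_trajectory_file(res.times, res.positions, tpath)
        write_reweighting_file(res.reweighting, rpath)
        written += [tpath, rpath]
    return written
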