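"""Temperature sweeps: many independent samples per temperature, ensemble
statistics, and detectors for the coil–globule transition range.

A sweep runs ``n_samples`` independent seeds at each temperature, averages
the steady-state radius of gyration (with its standard error of the mean
over samples), and optionally fits the center-of-mass displacement exponent
k and the effective dimension D_e from the pooled steady-state structure
factor.  Per-run summaries are cached on disk keyed by a hash of the full
run configuration, so an identical sweep re-reads the cache instead of
re-simulating.

The transition-range detector formalizes what is usually read off a plot:
the interval where the smoothed slope dRg/dT exceeds a threshold fraction
of its maximum, bracketed by the low- and high-T plateaus.  The anomaly
detector looks for interior intervals where Rg *decreases* with rising T
by more than two combined standard errors (the signature reported for
BFKV-type potentials).  Both are reconstructions with configurable
thresholds, not uniquely defined quantities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .engine import SimulationConfig, TrajectoryRecord, run_simulation
from .observables import (
    fit_effective_dimension,
    residue_profiles,
    steady_state_rg,
    structure_factor,
)
from .potentials import ContactMatrix, ProteinSequence

logger = logging.getLogger("bondfluct")

#: Default wave-vector grid for the steady-state structure factor.
DEFAULT_QGRID = np.geomspace(0.2, 1.2, 30)


@dataclass(frozen=True)
class SweepResult:
    """Per-temperature ensemble statistics of a sweep."""

    temperatures: np.ndarray
    rg_mean: np.ndarray
    rg_se: np.ndarray
    n_samples: int
    mcs_total: int
    k: np.ndarray | None = None          # COM displacement exponent per T
    k_stderr: np.ndarray | None = None
    De: np.ndarray | None = None         # effective dimension per T
    De_stderr: np.ndarray | None = None
    profiles: tuple | None = None        # ResidueProfile per T

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be non-empty, strictly increasing")
        if self.n_samples < 1:
            raise ValueError("need at least one sample per temperature")
        if not np.all(np.isfinite(self.rg_mean)) or not np.all(
            np.isfinite(self.rg_se)
        ):
            raise ValueError("non-finite ensemble statistics")

    def grid_step(self) -> float:
        t = np.asarray(self.temperatures)
        return float(np.median(np.diff(t))) if len(t) > 1 else 0.0


def sample_seed(master_seed: int, t_index: int, sample: int) -> int:
    """Deterministic per-(temperature, sample) seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(t_index), int(sample)])
    return int(ss.generate_state(1)[0] % 2**31)


def _config_key(cfg: SimulationConfig, seq: ProteinSequence, matrix: ContactMatrix) -> str:
    payload = {
        "config": cfg.to_dict(),
        "sequence": str(seq),
        "triangle": matrix.triangle().tolist(),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:24]


def _summarize_run(traj: TrajectoryRecord, n_frames_keep: int = 8) -> dict:
    """Compact per-run summary sufficient for sweep aggregation."""
    rg_mean, rg_se = steady_state_rg(traj)
    com = traj.com()
    sq_disp = ((com - com[0]) ** 2).sum(axis=1)
    keep = np.where(traj.steady_mask())[0]
    if len(keep) > n_frames_keep:
        keep = keep[np.linspace(0, len(keep) - 1, n_frames_keep).astype(int)]
    prof = residue_profiles(traj)
    return {
        "rg_mean": rg_mean,
        "rg_se": rg_se,
        "times": traj.times.tolist(),
        "sq_disp": sq_disp.tolist(),
        "steady_frames": traj.positions[keep].tolist(),
        "profile_energy": prof.energy.tolist(),
        "profile_mobility": prof.mobility.tolist(),
    }


def _run_cell(
    cfg: SimulationConfig,
    seq: ProteinSequence,
    matrix: ContactMatrix,
    cache_dir: Path | None,
) -> dict:
    if cache_dir is not None:
        cache_file = cache_dir / f"run_{_config_key(cfg, seq, matrix)}.json"
        if cache_file.exists():
            return json.loads(cache_file.read_text())
    summary = _summarize_run(run_simulation(cfg, seq, matrix))
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_file.write_text(json.dumps(summary))
    return summary


def run_sweep(
    base_cfg: SimulationConfig,
    temperatures: Sequence[float],
    n_samples: int,
    seq: ProteinSequence,
    matrix: ContactMatrix,
    cache_dir: str | Path | None = None,
    fit_dynamics: bool = True,
    fit_dimension: bool = True,
    qgrid: np.ndarray | None = None,
) -> SweepResult:
    """Run ``n_samples`` independent seeds at each temperature and aggregate.

    Each (temperature, sample) cell gets its own deterministic seed derived
    from ``base_cfg.seed``.  A failed cell is logged and skipped; the sweep
    continues with the remaining samples.  Errors are standard errors of
    the mean over samples.
    """
    temps = sorted(float(t) for t in temperatures)
    if any(t <= 0 for t in temps):
        raise ValueError("all temperatures must be > 0")
    cache = Path(cache_dir) if cache_dir is not None else None
    if qgrid is None:
        qgrid = DEFAULT_QGRID

    rg_mean, rg_se = [], []
    k_arr, k_err = [], []
    de_arr, de_err = [], []
    profs = []
    from scipy import stats

    from .observables import ResidueProfile

    for ti, T in enumerate(temps):
        summaries = []
        for s in range(n_samples):
            cfg = dataclasses.replace(
                base_cfg, T=T, seed=sample_seed(base_cfg.seed, ti, s)
            )
            try:
                summaries.append(_run_cell(cfg, seq, matrix, cache))
            except Exception:
                logger.exception("sweep cell failed: T=%g sample=%d", T, s)
        if not summaries:
            raise RuntimeError(f"all {n_samples} samples failed at T={T}")
        rgs = np.array([s["rg_mean"] for s in summaries])
        rg_mean.append(rgs.mean())
        rg_se.append(rgs.std(ddof=1) / np.sqrt(len(rgs)) if len(rgs) > 1 else 0.0)

        if fit_dynamics:
            times = np.asarray(summaries[0]["times"], dtype=float)
            sq = np.mean([s["sq_disp"] for s in summaries], axis=0)
            rc = np.sqrt(sq)
            if rc.max() < 1e-9:
                k_arr.append(0.0)
                k_err.append(float("nan"))
            else:
                sel = (times >= times.max() / 10.0) & (times > 0) & (rc > 0)
                res = stats.linregress(np.log(times[sel]), np.log(rc[sel]))
                k_arr.append(float(res.slope))
                k_err.append(float(res.stderr))

        if fit_dimension:
            frames = np.concatenate(
                [np.asarray(s["steady_frames"], dtype=float) for s in summaries]
            )
            curve = structure_factor(list(frames), qgrid, seed=base_cfg.seed)
            fit = fit_effective_dimension(curve)
            de_arr.append(fit.De)
            de_err.append(fit.De_stderr)

        e = np.mean([s["profile_energy"] for s in summaries], axis=0)
        mob = np.mean([s["profile_mobility"] for s in summaries], axis=0)
        profs.append(ResidueProfile(np.asarray(e), np.asarray(mob)))

    return SweepResult(
        temperatures=np.asarray(temps),
        rg_mean=np.asarray(rg_mean),
        rg_se=np.asarray(rg_se),
        n_samples=n_samples,
        mcs_total=base_cfg.mcs_total,
        k=np.asarray(k_arr) if fit_dynamics else None,
        k_stderr=np.asarray(k_err) if fit_dynamics else None,
        De=np.asarray(de_arr) if fit_dimension else None,
        De_stderr=np.asarray(de_err) if fit_dimension else None,
        profiles=tuple(profs),
    )


# ---------------------------------------------------------------------------
# Transition-range and anomaly detectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionRange:
    """Detected temperature window of the coil–globule transition."""

    T_onset: float
    T_end: float
    conclusive: bool
    uncertainty: float  # grid resolution


def detect_transition_range(
    sr: SweepResult,
    threshold_frac: float = 0.10,
    smooth_window: int = 3,
) -> TransitionRange:
    """Bracket the transition by thresholding the smoothed slope dRg/dT.

    T_onset (T_end) is the lowest (highest) temperature where the smoothed
    derivative exceeds ``threshold_frac`` of its maximum.  The detection is
    flagged inconclusive when the curve shows no significant total rise or
    when the super-threshold region touches a grid endpoint (no plateau on
    that side).
    """
    t = np.asarray(sr.temperatures, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 temperatures spanning both plateaus")
    rg = np.asarray(sr.rg_mean, dtype=float)
    if smooth_window > 1:
        kern = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        rg_s = np.convolve(np.pad(rg, pad, mode="edge"), kern, mode="valid")
    else:
        rg_s = rg
    deriv = np.gradient(rg_s, t)
    step = sr.grid_step()

    rise = rg_s.max() - rg_s.min()
    noise = float(np.median(sr.rg_se)) if np.any(sr.rg_se > 0) else 0.0
    significant_rise = rise > max(4 * noise, 1e-12)
    dmax = deriv.max()
    if not significant_rise or dmax <= 0:
        return TransitionRange(float("nan"), float("nan"), False, step)

    above = deriv >= threshold_frac * dmax
    idx = np.where(above)[0]
    if idx[0] == 0 or idx[-1] == len(t) - 1:
        # no plateau on at least one side: monotone ramp, not a transition
        return TransitionRange(float(t[idx[0]]), float(t[idx[-1]]), False, step)
    return TransitionRange(float(t[idx[0]]), float(t[idx[-1]]), True, step)


def detect_anomaly(
    sr: SweepResult, n_se: float = 2.0, min_steps: int = 2
) -> tuple[float, float] | None:
    """Longest interval where Rg *decreases* with rising T; None when absent.

    Each grid step in the interval must drop by more than ``n_se`` combined
    standard errors, and at least ``min_steps`` consecutive such steps are
    required.  The consecutiveness requirement controls the look-elsewhere
    effect: a single 2-SE step somewhere on a ~20-point grid is expected
    from noise alone, two adjacent ones are not.  Anomalies narrower than
    ``min_steps`` grid intervals are therefore invisible — refine the grid
    to resolve them.
    """
    t = np.asarray(sr.temperatures, dtype=float)
    rg = np.asarray(sr.rg_mean, dtype=float)
    se = np.asarray(sr.rg_se, dtype=float)
    drop = rg[:-1] - rg[1:]
    guard = n_se * np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
    sig = drop > np.maximum(guard, 1e-12)

    best: tuple[float, float] | None = None
    best_len = 0.0
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            span = t[j + 1] - t[i]
            if j - i + 1 >= min_steps and span > best_len:
                best_len = span
                best = (float(t[i]), float(t[j + 1]))
            i = j + 1
        i += 1
    return best


# ---------------------------------------------------------------------------
# Sweep I/O
# ---------------------------------------------------------------------------

def write_sweep_csv(sr: SweepResult, path, header: dict | None = None) -> None:
    from .observables import write_columns_csv

    cols = {
        "T": sr.temperatures,
        "rg_mean": sr.rg_mean,
        "rg_se": sr.rg_se,
    }
    if sr.k is not None:
        cols["k"] = sr.k
        cols["k_stderr"] = sr.k_stderr
    if sr.De is not None:
        cols["De"] = sr.De
        cols["De_stderr"] = sr.De_stderr
    meta = {"n_samples": sr.n_samples, "mcs_total": sr.mcs_total}
    if header:
        meta.update(header)
    write_columns_csv(path, cols, header=meta)
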