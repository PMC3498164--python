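"""Metropolis Monte Carlo dynamics of the tethered chain.

One Monte Carlo step (MCS) is N single-residue move attempts — the unit of
simulation time.  Each attempt picks a residue and one of the six axial
unit directions at random; if excluded volume and the bond constraints
allow the hop, it is accepted with the Boltzmann probability
min(1, exp(-dE/T)), T in reduced units (k_B = 1).  Geometric rejections
consume an attempt, which matters for mobility normalization.

Two attempt schedules are offered: ``random`` (N independent uniform
residue picks per MCS, the default) and ``permuted`` (a fresh random
permutation each MCS, so every residue is attempted exactly once).

The production path is a numba kernel (a few 10^6 attempts/s on one
core); a pure Python reference step (:func:`mcs_step`) built on the
lattice and energetics modules serves as its oracle in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .energetics import _OFF, _OFF_R2, EnergyModel
from .lattice import (
    MOVE_DIRECTIONS,
    ChainConformation,
    bond_lookup_table,
    build_initial_conformation,
)
from .potentials import ContactMatrix, ProteinSequence

logger = logging.getLogger("bondfluct")


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for a single trajectory (one seed, one temperature)."""

    T: float
    mcs_total: int
    L: int = 64
    record_every: int = 100
    equilibration_mcs: int | None = None  # default: first half of mcs_total
    seed: int = 0
    matrix_name: str = "uniform0"
    bondset: str = "classic"
    potential_form: str = "generalized"
    include_bonded: bool = True
    sweep: str = "random"  # 'random' | 'permuted'

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"temperature must be > 0, got {self.T}")
        if self.mcs_total < 0:
            raise ValueError("mcs_total must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.mcs_total and self.record_every > self.mcs_total:
            raise ValueError("record_every must not exceed mcs_total")
        eq = self.equilibration()
        if self.mcs_total and not 0 <= eq < self.mcs_total:
            raise ValueError(f"equilibration_mcs {eq} outside [0, mcs_total)")
        if self.sweep not in ("random", "permuted"):
            raise ValueError(f"unknown sweep schedule {self.sweep!r}")

    def equilibration(self) -> int:
        if self.equilibration_mcs is None:
            return self.mcs_total // 2
        return self.equilibration_mcs

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrajectoryRecord:
    """Recorded time series of one run: frames, tallies, per-residue energies.

    Frames are recorded at t = 0 and every ``record_every`` MCS.  Attempt and
    acceptance tallies are cumulative per residue, so windowed rates follow
    by differencing.  Positions are unwrapped.
    """

    config: SimulationConfig
    sequence: ProteinSequence
    times: np.ndarray          # (n_rec,)
    positions: np.ndarray      # (n_rec, N, 3) unwrapped
    residue_energies: np.ndarray  # (n_rec, N)
    attempts: np.ndarray       # (n_rec, N) cumulative
    accepts: np.ndarray        # (n_rec, N) cumulative

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("record times must be strictly increasing")
        if np.any(self.accepts > self.attempts):
            raise ValueError("acceptance tallies exceed attempts (engine bug)")

    @property
    def n_residues(self) -> int:
        return self.positions.shape[1]

    def total_energy(self) -> np.ndarray:
        """Total contact energy per frame (pairs counted once)."""
        return 0.5 * self.residue_energies.sum(axis=1)

    def com(self) -> np.ndarray:
        """Unwrapped center of mass per frame, shape (n_rec, 3)."""
        return self.positions.mean(axis=1)

    def rg(self) -> np.ndarray:
        """Radius of gyration per frame."""
        d = self.positions - self.com()[:, None, :]
        return np.sqrt(np.einsum("tij,tij->t", d, d) / self.n_residues)

    def steady_mask(self) -> np.ndarray:
        """Frames in the post-equilibration window."""
        return self.times >= self.config.equilibration()

    def final_conformation(self) -> ChainConformation:
        return ChainConformation(
            self.positions[-1].copy(), self.config.L, self.config.bondset
        )


def metropolis_accept(dE: float, T: float, u: float) -> bool:
    """Accept iff u < min(1, exp(-dE/T))."""
    if not T > 0:
        raise ValueError("temperature must be > 0")
    if dE <= 0:
        return True
    return u < math.exp(-dE / T)


def mcs_step(
    c: ChainConformation,
    m: EnergyModel,
    T: float,
    rng: np.random.Generator,
    sweep: str = "random",
):
    """One MCS via the pure-Python path; returns (attempts, accepts) per residue.

    Reference implementation used to validate the compiled kernel; mutates
    ``c`` in place.
    """
    from .energetics import move_delta_energy

    n = c.n
    attempts = np.zeros(n, dtype=np.int64)
    accepts = np.zeros(n, dtype=np.int64)
    order = rng.permutation(n) if sweep == "permuted" else rng.integers(0, n, size=n)
    for i in order:
        i = int(i)
        d = MOVE_DIRECTIONS[rng.integers(0, 6)]
        attempts[i] += 1
        outcome = c.propose_move(i, d)
        if not outcome.ok:
            continue
        dE = move_delta_energy(c, m, i, outcome.new_position)
        if metropolis_accept(dE, T, float(rng.random())):
            c.apply_move(i, outcome.new_position)
            accepts[i] += 1
    return attempts, accepts


# ---------------------------------------------------------------------------
# Compiled kernel
# ---------------------------------------------------------------------------

_DIRS = np.ascontiguousarray(MOVE_DIRECTIONS)
_KOFF = np.ascontiguousarray(_OFF)
_KOFF_R2 = np.ascontiguousarray(_OFF_R2)


@njit(cache=True, inline="always")
def _wrap(x, L):
    # x is within [-3, L+3): one correction suffices
    if x < 0:
        return x + L
    if x >= L:
        return x - L
    return x


@njit(cache=True)
def _local_energy(i, cx, cy, cz, grid, L, seq0, utab, include_bonded):
    e = 0.0
    for k in range(_KOFF.shape[0]):
        x = _wrap(cx + _KOFF[k, 0], L)
        y = _wrap(cy + _KOFF[k, 1], L)
        z = _wrap(cz + _KOFF[k, 2], L)
        j = grid[x, y, z]
        if j >= 0 and j != i:
            if not include_bonded and (j == i - 1 or j == i + 1):
                continue
            e += utab[seq0[i], seq0[j], _KOFF_R2[k]]
    return e


@njit(cache=True)
def _run_kernel(
    upos,      # (N,3) int64 unwrapped, updated in place
    grid,      # (L,L,L) int32 wrapped corner occupancy, updated in place
    L,
    seq0,      # (N,) int64, 0-based alphabet indices
    utab,      # (20,20,9) pair-energy table by squared distance
    bond_tab,  # (7,7,7) bool allowed-bond lookup
    include_bonded,
    permuted,
    T,
    mcs_total,
    record_every,
    seed,
    rec_t, rec_pos, rec_resE, rec_att, rec_acc,
):
    np.random.seed(seed)
    N = upos.shape[0]
    att = np.zeros(N, dtype=np.int64)
    acc = np.zeros(N, dtype=np.int64)
    w = np.empty((N, 3), dtype=np.int64)
    for i in range(N):
        for k in range(3):
            w[i, k] = upos[i, k] % L

    def _record(ridx, t):
        rec_t[ridx] = t
        for i in range(N):
            for k in range(3):
                rec_pos[ridx, i, k] = upos[i, k]
            rec_resE[ridx, i] = _local_energy(
                i, w[i, 0], w[i, 1], w[i, 2], grid, L, seq0, utab, include_bonded
            )
            rec_att[ridx, i] = att[i]
            rec_acc[ridx, i] = acc[i]

    _record(0, 0)
    ridx = 1
    for step in range(1, mcs_total + 1):
        if permuted:
            order = np.random.permutation(N)
        for a in range(N):
            if permuted:
                i = order[a]
            else:
                i = np.random.randint(N)
            d = np.random.randint(6)
            att[i] += 1
            dx = _DIRS[d, 0]
            dy = _DIRS[d, 1]
            dz = _DIRS[d, 2]
            nxu = upos[i, 0] + dx
            nyu = upos[i, 1] + dy
            nzu = upos[i, 2] + dz
            # bond constraints with chain neighbors (unwrapped differences)
            ok = True
            if i > 0:
                bx = upos[i - 1, 0] - nxu
                by = upos[i - 1, 1] - nyu
                bz = upos[i - 1, 2] - nzu
                if bx < -3 or bx > 3 or by < -3 or by > 3 or bz < -3 or bz > 3:
                    ok = False
                elif not bond_tab[bx + 3, by + 3, bz + 3]:
                    ok = False
            if ok and i < N - 1:
                bx = upos[i + 1, 0] - nxu
                by = upos[i + 1, 1] - nyu
                bz = upos[i + 1, 2] - nzu
                if bx < -3 or bx > 3 or by < -3 or by > 3 or bz < -3 or bz > 3:
                    ok = False
                elif not bond_tab[bx + 3, by + 3, bz + 3]:
                    ok = False
            if not ok:
                continue
            nx = _wrap(w[i, 0] + dx, L)
            ny = _wrap(w[i, 1] + dy, L)
            nz = _wrap(w[i, 2] + dz, L)
            # excluded volume: no other corner within Chebyshev distance 1
            for ex in range(-1, 2):
                gx = _wrap(nx + ex, L)
                for ey in range(-1, 2):
                    gy = _wrap(ny + ey, L)
                    for ez in range(-1, 2):
                        gz = _wrap(nz + ez, L)
                        j = grid[gx, gy, gz]
                        if j >= 0 and j != i:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            e_old = _local_energy(
                i, w[i, 0], w[i, 1], w[i, 2], grid, L, seq0, utab, include_bonded
            )
            e_new = _local_energy(i, nx, ny, nz, grid, L, seq0, utab, include_bonded)
            dE = e_new - e_old
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                grid[w[i, 0], w[i, 1], w[i, 2]] = -1
                grid[nx, ny, nz] = i
                w[i, 0] = nx
                w[i, 1] = ny
                w[i, 2] = nz
                upos[i, 0] = nxu
                upos[i, 1] = nyu
                upos[i, 2] = nzu
                acc[i] += 1
        if step % record_every == 0:
            _record(ridx, step)
            ridx += 1


def run_simulation(
    cfg: SimulationConfig,
    seq: ProteinSequence,
    matrix: ContactMatrix,
    initial: ChainConformation | None = None,
) -> TrajectoryRecord:
    """Run one trajectory: build (or take) an initial conformation, run
    ``mcs_total`` MCS through the compiled kernel, record every
    ``record_every`` MCS (plus the t = 0 frame).

    All randomness derives from ``cfg.seed``: one sub-seed drives the
    self-avoiding growth of the initial state, another the kernel's move
    sequence, so identical configs give bit-identical trajectories.
    """
    rng = np.random.default_rng(cfg.seed)
    place_seed = int(rng.integers(2**31))
    kernel_seed = int(rng.integers(2**31))

    if initial is None:
        initial = build_initial_conformation(seq.n, cfg.L, place_seed, cfg.bondset)
    elif initial.L != cfg.L or initial.n != seq.n:
        raise ValueError("initial conformation does not match config/sequence")

    model = EnergyModel(matrix, seq, cfg.include_bonded, cfg.potential_form)
    utab = model.energy_table()
    bond_tab = bond_lookup_table(cfg.bondset)

    n_rec = cfg.mcs_total // cfg.record_every + 1
    N = seq.n
    rec_t = np.zeros(n_rec, dtype=np.int64)
    rec_pos = np.zeros((n_rec, N, 3), dtype=np.int64)
    rec_resE = np.zeros((n_rec, N))
    rec_att = np.zeros((n_rec, N), dtype=np.int64)
    rec_acc = np.zeros((n_rec, N), dtype=np.int64)

    logger.debug(
        "run: N=%d L=%d T=%g mcs=%d matrix=%s seed=%d",
        seq.n, cfg.L, cfg.T, cfg.mcs_total, matrix.name, cfg.seed,
    )
    upos = initial.positions.copy()
    grid = initial.dense_grid()
    _run_kernel(
        upos, grid, cfg.L, seq.indices0(), utab, bond_tab,
        cfg.include_bonded, cfg.sweep == "permuted",
        float(cfg.T), cfg.mcs_total, cfg.record_every, kernel_seed,
        rec_t, rec_pos, rec_resE, rec_att, rec_acc,
    )
    traj = TrajectoryRecord(
        cfg, seq, rec_t, rec_pos, rec_resE, rec_att, rec_acc
    )
    if not np.all(np.isfinite(traj.residue_energies)):
        raise RuntimeError("non-finite energy in trajectory (engine bug)")
    logger.info(
        "run done: T=%g seed=%d final Rg=%.3f acc=%.3f",
        cfg.T, cfg.seed, traj.rg()[-1],
        traj.accepts[-1].sum() / max(traj.attempts[-1].sum(), 1),
    )
    return traj


# ---------------------------------------------------------------------------
# Trajectory I/O: JSON config header + tabular records + optional frames
# ---------------------------------------------------------------------------

def write_trajectory(traj: TrajectoryRecord, path, frames: bool = True) -> None:
    """Plain-text trajectory: ``#`` JSON header, per-record summary table,
    and (optionally) per-frame unwrapped positions."""
    path = Path(path)
    com = traj.com()
    disp = np.linalg.norm(com - com[0], axis=1)
    etot = traj.total_energy()
    rg = traj.rg()
    att = traj.attempts.sum(axis=1)
    acc = traj.accepts.sum(axis=1)
    with open(path, "w") as fh:
        header = {
            "config": traj.config.to_dict(),
            "sequence": str(traj.sequence),
            "n_records": len(traj.times),
            "frames": bool(frames),
        }
        fh.write("# bondfluct trajectory\n")
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("# t\tE_total\tRg\tcom_displacement\tacceptance_fraction\n")
        for k, t in enumerate(traj.times):
            frac = float(acc[k] / att[k]) if att[k] else 0.0
            fh.write(
                f"{t}\t{float(etot[k])!r}\t{float(rg[k])!r}"
                f"\t{float(disp[k])!r}\t{frac!r}\n"
            )
        if frames:
            for k, t in enumerate(traj.times):
                fh.write(f"FRAME {t}\n")
                for i in range(traj.n_residues):
                    x, y, z = traj.positions[k, i]
                    fh.write(f"{i} {x} {y} {z}\n")
                for i in range(traj.n_residues):
                    fh.write(
                        f"R {i} {float(traj.residue_energies[k, i])!r} "
                        f"{traj.attempts[k, i]} {traj.accepts[k, i]}\n"
                    )


def read_trajectory(path) -> TrajectoryRecord:
    """Read a trajectory written with ``frames=True``."""
    from .potentials import parse_sequence

    path = Path(path)
    header = None
    frame_times, frame_pos, frame_resE, frame_att, frame_acc = [], [], [], [], []
    cur_pos = cur_resE = cur_att = cur_acc = None
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("# {"):
                header = json.loads(ln[2:])
            elif ln.startswith("FRAME "):
                frame_times.append(int(ln.split()[1]))
                cur_pos, cur_resE, cur_att, cur_acc = [], [], [], []
                frame_pos.append(cur_pos)
                frame_resE.append(cur_resE)
                frame_att.append(cur_att)
                frame_acc.append(cur_acc)
            elif cur_pos is not None and ln.startswith("R "):
                toks = ln.split()
                cur_resE.append(float(toks[2]))
                cur_att.append(int(toks[3]))
                cur_acc.append(int(toks[4]))
            elif cur_pos is not None and ln and not ln.startswith("#"):
                toks = ln.split()
                cur_pos.append([int(toks[1]), int(toks[2]), int(toks[3])])
    if header is None or not frame_times:
        raise ValueError(f"{path}: not a bondfluct trajectory with frames")
    cfg = SimulationConfig(**header["config"])
    seq = parse_sequence(header["sequence"])
    return TrajectoryRecord(
        cfg,
        seq,
        np.asarray(frame_times, dtype=np.int64),
        np.asarray(frame_pos, dtype=np.int64),
        np.asarray(frame_resE, dtype=float),
        np.asarray(frame_att, dtype=np.int64),
        np.asarray(frame_acc, dtype=np.int64),
    )
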