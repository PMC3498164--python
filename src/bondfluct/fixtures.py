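"""Synthetic inputs with known ground truth.

The published MJ/BT/BFKV contact tables are user-supplied data; every code
path must be testable without them.  This module builds (a) surrogate
contact matrices (zero = athermal homopolymer, uniform attraction, random
symmetric), (b) reference conformations with known geometry (rod, compact
globule) and ideal-coil ensembles for effective-dimension oracles, and
(c) synthetic Rg(T) curves with known transition/anomaly intervals for the
sweep detectors.

Everything here is deterministic given (kind, parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import BOND_VECTORS, ChainConformation
from .potentials import ContactMatrix, triangle_to_square
from .sweep import SweepResult


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def make_matrix(kind: str, value: float = -1.0, seed: int = 0) -> ContactMatrix:
    """Build a synthetic contact matrix.

    kinds: ``zero`` (eps = 0 everywhere), ``uniform`` (eps = value
    everywhere), ``random-symmetric`` (210 independent upper-triangle values
    uniform in [-1, 1] from ``seed``).
    """
    if kind == "zero":
        return ContactMatrix("zero", np.zeros((20, 20)))
    if kind == "uniform":
        return ContactMatrix(f"uniform{value:g}", np.full((20, 20), float(value)))
    if kind == "random-symmetric":
        rng = np.random.default_rng(seed)
        tri = rng.uniform(-1.0, 1.0, size=210)
        return ContactMatrix(f"random{seed}", triangle_to_square(tri))
    raise ValueError(f"unknown matrix kind {kind!r}")


# ---------------------------------------------------------------------------
# Reference conformations
# ---------------------------------------------------------------------------

def make_conformation(kind: str, n: int, L: int | None = None) -> ChainConformation:
    """Build a reference conformation: ``rod`` or ``globule``.

    rod: collinear chain with (3,0,0) bonds — a one-dimensional scatterer.
    globule: space-filling serpentine with (2,0,0)-type bonds inside the
    smallest cube of cells holding ``n`` residues — a compact
    three-dimensional scatterer.  Both satisfy all chain invariants.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "rod":
        pos = np.zeros((n, 3), dtype=np.int64)
        pos[:, 0] = 3 * np.arange(n)
        # periodic box large enough that wrapped images cannot collide
        L_need = max(8, 3 * n + 4)
    elif kind == "globule":
        s = max(1, math.ceil(n ** (1 / 3)))
        while s**3 < n:
            s += 1
        pos = np.empty((n, 3), dtype=np.int64)
        for idx in range(n):
            iz, rem = divmod(idx, s * s)
            iy_raw, ix_raw = divmod(rem, s)
            iy = iy_raw if iz % 2 == 0 else s - 1 - iy_raw
            ix = ix_raw if (iz * s + iy_raw) % 2 == 0 else s - 1 - ix_raw
            pos[idx] = (2 * ix, 2 * iy, 2 * iz)
        L_need = max(8, 2 * s + 4)
    else:
        raise ValueError(f"unknown conformation kind {kind!r}")
    L_use = L_need if L is None else L
    if L_use < L_need:
        raise ValueError(f"lattice edge {L_use} too small for {kind}(n={n}); need >= {L_need}")
    c = ChainConformation(pos, L_use)
    c.validate()
    return c


def make_coil_ensemble(
    n: int, n_chains: int, seed: int = 0, bondset: str = "classic"
) -> list[np.ndarray]:
    """Ideal-chain ensembles: non-self-avoiding random walks over the
    allowed bond set.

    Self-avoidance is deliberately off so the ensemble realizes ideal-coil
    statistics (nu = 1/2, effective dimension 2); the walks are position
    arrays, not ChainConformations, because they may self-overlap.
    """
    rng = np.random.default_rng(seed)
    bonds = np.array(sorted(BOND_VECTORS[bondset]), dtype=np.int64)
    out = []
    for _ in range(n_chains):
        steps = bonds[rng.integers(0, len(bonds), size=n - 1)]
        pos = np.vstack([np.zeros(3, dtype=np.int64), np.cumsum(steps, axis=0)])
        out.append(pos)
    return out


#: Mean squared bond length of the classic bond-fluctuation vector set.
MEAN_SQ_BOND = float(
    np.mean([v[0] ** 2 + v[1] ** 2 + v[2] ** 2 for v in BOND_VECTORS["classic"]])
)


def make_fractal_ensemble(
    n: int,
    nu: float,
    n_chains: int,
    seed: int = 0,
    step_scale: float | None = None,
) -> list[np.ndarray]:
    """Chains with exact internal scaling r(s) ~ s^nu: fractional Brownian
    paths with Hurst exponent H = nu.

    These are the clean scatterer oracles for the effective dimension
    D_e = 1/nu: nu = 1 gives rigid-rod statistics, nu = 1/2 an ideal coil,
    nu = 1/3 crumpled (space-filling, globule-like) statistics.  Unlike a
    rigid uniform object, a crumpled ensemble has no sharp surface, so its
    spherically averaged S(q) shows the mass-scaling power law q^(-1/nu)
    rather than a Porod (surface) decay.

    ``step_scale`` is the RMS step b (default: the RMS bond length of the
    classic bond-fluctuation vector set); the window of length scales the
    power law spans is [b, b n^nu].  Off-lattice position arrays, not
    ChainConformations.
    """
    if not 0 < nu <= 1:
        raise ValueError("nu must be in (0, 1]")
    b = math.sqrt(MEAN_SQ_BOND) if step_scale is None else float(step_scale)
    rng = np.random.default_rng(seed)
    m = n - 1
    k = np.arange(m)
    d = np.abs(k[:, None] - k[None, :]).astype(float)
    h2 = 2.0 * nu
    # per-coordinate variance is b^2/3 so the RMS 3-D step length is b
    cov = (b * b / 6.0) * ((d + 1) ** h2 + np.abs(d - 1) ** h2 - 2 * d**h2)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(m))
    out = []
    for _ in range(n_chains):
        steps = chol @ rng.standard_normal((m, 3))
        out.append(np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]))
    return out


# ---------------------------------------------------------------------------
# Synthetic Rg(T) curves for the sweep detectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture description: fully determined by (kind, params).

    kinds: ``zero-matrix``, ``uniform-matrix``, ``random-matrix``, ``rod``,
    ``globule``, ``ideal-coil-ensemble``, ``fractal-ensemble``,
    ``sigmoid-curve``, ``dip-curve``, ``flat-curve``, ``linear-curve``.
    ``params`` are forwarded to the corresponding ``make_*`` function.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def build(self):
        k, p = self.kind, dict(self.params)
        if k == "zero-matrix":
            return make_matrix("zero")
        if k == "uniform-matrix":
            return make_matrix("uniform", **p)
        if k == "random-matrix":
            return make_matrix("random-symmetric", **p)
        if k in ("rod", "globule"):
            return make_conformation(k, **p)
        if k == "ideal-coil-ensemble":
            return make_coil_ensemble(**p)
        if k == "fractal-ensemble":
            return make_fractal_ensemble(**p)
        if k.endswith("-curve"):
            temps = p.pop("temperatures")
            return make_curve(k[: -len("-curve")], temps, **p)
        raise ValueError(f"unknown fixture kind {k!r}")


@dataclass(frozen=True)
class SyntheticCurve:
    """A synthetic sweep plus the ground truth its detectors should find."""

    sweep: SweepResult
    truth: dict = field(default_factory=dict)


def sigmoid_threshold_halfwidth(scale: float, threshold_frac: float = 0.10) -> float:
    """Half-width of the region where a logistic curve's slope exceeds
    ``threshold_frac`` of its peak slope."""
    f = (1.0 - math.sqrt(1.0 - threshold_frac)) / 2.0
    return -scale * math.log(f / (1.0 - f))


def make_curve(
    kind: str,
    temperatures,
    *,
    center: float = 0.016,
    scale: float = 0.001,
    lo: float = 10.0,
    hi: float = 26.0,
    dip_lo: float = 0.015,
    dip_hi: float = 0.018,
    dip_depth: float = 6.0,
    level: float = 12.0,
    slope: float = 500.0,
    noise: float = 0.0,
    n_samples: int = 10,
    seed: int = 0,
) -> SyntheticCurve:
    """Synthetic Rg(T) sweeps from a named functional family.

    kinds:

    * ``sigmoid`` — logistic rise from ``lo`` to ``hi`` around ``center``
      with logistic scale ``scale``; spans the Rg ~ 10-26 range typical of
      a 136-residue chain between globule and coil.  Ground truth records
      the 10%-slope onset/end temperatures.
    * ``dip`` — rising baseline with a linear decrease of ``dip_depth``
      over [dip_lo, dip_hi]; ground truth records that interval.
    * ``flat`` — constant ``level``.
    * ``linear`` — straight ramp ``level + slope * (T - T_min)``.

    Gaussian noise of scale ``noise`` (the per-point standard error, as if
    from ``n_samples`` samples) is added with the given seed.
    """
    t = np.asarray(sorted(float(x) for x in temperatures))
    truth: dict = {"kind": kind}
    if kind == "sigmoid":
        rg = lo + (hi - lo) / (1.0 + np.exp(-(t - center) / scale))
        hw = sigmoid_threshold_halfwidth(scale)
        truth.update(center=center, scale=scale, onset=center - hw, end=center + hw)
    elif kind == "dip":
        ramp = lo + (hi - lo) * (t - t[0]) / max(t[-1] - t[0], 1e-12)
        dip = np.clip((t - dip_lo) / max(dip_hi - dip_lo, 1e-12), 0.0, 1.0)
        rg = ramp - dip_depth * dip
        truth.update(dip_lo=dip_lo, dip_hi=dip_hi, depth=dip_depth)
        decr = np.where(np.diff(rg) < 0)[0]
        if len(decr) == 0:
            raise ValueError(
                "dip too shallow: steepen it (dip_depth / (dip_hi - dip_lo) "
                "must exceed the baseline slope) so Rg actually decreases"
            )
        truth.update(grid_dip_lo=float(t[decr[0]]), grid_dip_hi=float(t[decr[-1] + 1]))
    elif kind == "flat":
        rg = np.full_like(t, level)
        truth.update(level=level)
    elif kind == "linear":
        rg = level + slope * (t - t[0])
        truth.update(level=level, slope=slope)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")

    rng = np.random.default_rng(seed)
    if noise > 0:
        rg = rg + rng.normal(scale=noise, size=len(t))
    se = np.full_like(t, float(noise))
    sr = SweepResult(
        temperatures=t,
        rg_mean=rg,
        rg_se=se,
        n_samples=n_samples,
        mcs_total=0,
    )
    return SyntheticCurve(sr, truth)
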