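"""Contact energies: pair, per-residue, total, and move-delta bookkeeping.

Residue pairs closer than the cutoff r_c = sqrt(8) (lattice units) interact
through a generalized Lennard-Jones potential built on the contact-matrix
entry eps_ij for their amino-acid types:

    U_ij(r) = |eps_ij| (sigma/r)^12 + eps_ij (sigma/r)^6,   r <= r_c,

with sigma = 1.  The repulsive core is always positive while the r^-6 tail
carries the sign of eps_ij, so attractive matrix entries are attractive at
every accessible separation.  This functional form is the convention of the
coarse-grained contact-potential model family; the classic
eps*[(sigma/r)^12 - (sigma/r)^6] shape is available as
``potential_form='lj'`` for comparison.

Distances are Euclidean between cube corner sites under the minimum-image
convention.  Excluded volume guarantees r^2 >= 4 for any distinct pair, so
on the lattice only r^2 in {4, 5, 6, 8} ever contributes (7 is not a sum of
three squares).  Pairs exactly at the cutoff (r^2 = 8) do interact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .lattice import ChainConformation
from .potentials import ContactMatrix, ProteinSequence

#: Squared interaction cutoff, lattice units.
R_CUT_SQ = 8

#: LJ length scale, lattice units.
SIGMA = 1.0

POTENTIAL_FORMS = ("generalized", "lj")

# All minimum-image offsets that can separate two interacting residues:
# 4 <= |d|^2 <= 8 (smaller separations violate excluded volume).
_OFF = np.array(
    [
        d
        for d in itertools.product(range(-2, 3), repeat=3)
        if 4 <= d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= R_CUT_SQ
    ],
    dtype=np.int64,
)
_OFF_R2 = np.einsum("ij,ij->i", _OFF, _OFF)


def pair_energy(r2: float, eps: float, potential_form: str = "generalized") -> float:
    """Energy of one residue pair at squared separation ``r2``.

    Zero beyond the cutoff; raises on r2 = 0 (excluded volume makes overlap
    impossible, so it signals an engine bug).
    """
    if r2 == 0:
        raise ValueError("zero separation: residues overlap (engine bug)")
    if r2 > R_CUT_SQ:
        return 0.0
    s6 = (SIGMA * SIGMA / r2) ** 3
    if potential_form == "generalized":
        return abs(eps) * s6 * s6 + eps * s6
    if potential_form == "lj":
        return eps * (s6 * s6 - s6)
    raise ValueError(f"unknown potential_form {potential_form!r}")


@dataclass(frozen=True)
class EnergyModel:
    """Contact matrix bound to a specific sequence, with cutoff conventions.

    include_bonded=True means covalently bonded neighbors (i, i+1) also feel
    the contact potential when within range; bonds of squared length 9 or 10
    are beyond the cutoff either way.
    """

    matrix: ContactMatrix
    sequence: ProteinSequence
    include_bonded: bool = True
    potential_form: str = "generalized"
    _eps_pairs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.potential_form not in POTENTIAL_FORMS:
            raise ValueError(f"unknown potential_form {self.potential_form!r}")
        idx = self.sequence.indices0()
        eps_pairs = self.matrix.eps[np.ix_(idx, idx)]
        object.__setattr__(self, "_eps_pairs", eps_pairs)

    @property
    def n(self) -> int:
        return self.sequence.n

    def eps_of_pair(self, i: int, j: int) -> float:
        """eps for the residue *chain positions* i, j (0-based)."""
        return float(self._eps_pairs[i, j])

    def energy_table(self) -> np.ndarray:
        """(20, 20, 9) table U[a-1, b-1, r2] used by the fast kernels.

        Entries below r^2 = 4 are zero: excluded volume makes them
        unreachable and keeping them inert protects the delta bookkeeping.
        """
        tab = np.zeros((20, 20, R_CUT_SQ + 1))
        for r2 in range(4, R_CUT_SQ + 1):
            if r2 == 7:
                continue
            for a in range(20):
                for b in range(20):
                    tab[a, b, r2] = pair_energy(
                        r2, self.matrix.eps[a, b], self.potential_form
                    )
        return tab


def _neighbor_terms(c: ChainConformation, m: EnergyModel, i: int, corner: np.ndarray):
    """Yield (j, r2) for residues within cutoff of ``corner``, excluding i."""
    cx, cy, cz = (int(v) % c.L for v in corner)
    L = c.L
    for off, r2 in zip(_OFF, _OFF_R2):
        key = ((cx + off[0]) % L, (cy + off[1]) % L, (cz + off[2]) % L)
        j = c.occ.get(key, -1)
        if j >= 0 and j != i:
            yield j, int(r2)


def residue_energy(c: ChainConformation, m: EnergyModel, i: int) -> float:
    """Interaction energy of residue ``i`` with everything within the cutoff."""
    e = 0.0
    for j, r2 in _neighbor_terms(c, m, i, c.positions[i]):
        if not m.include_bonded and abs(j - i) == 1:
            continue
        e += pair_energy(r2, m.eps_of_pair(i, j), m.potential_form)
    return e


def total_energy(c: ChainConformation, m: EnergyModel) -> float:
    """Total contact energy; half the sum of residue energies (pairs counted once)."""
    return 0.5 * sum(residue_energy(c, m, i) for i in range(c.n))


def move_delta_energy(
    c: ChainConformation, m: EnergyModel, i: int, candidate: np.ndarray
) -> float:
    """Energy change if residue ``i`` moved to ``candidate`` (local bookkeeping).

    Only pairs involving i change, so the delta is the local energy at the
    candidate corner minus the local energy at the current corner.
    """
    e_old = residue_energy(c, m, i)
    e_new = 0.0
    for j, r2 in _neighbor_terms(c, m, i, candidate):
        if not m.include_bonded and abs(j - i) == 1:
            continue
        e_new += pair_energy(r2, m.eps_of_pair(i, j), m.potential_form)
    return e_new - e_old
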