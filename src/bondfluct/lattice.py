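"""Tethered chain of cube residues on a periodic cubic lattice.

Each residue is a unit cube occupying eight lattice sites, addressed by one
corner site; consecutive residues are joined by a bond vector drawn from a
finite allowed set, so bond lengths fluctuate between 2 and sqrt(10) lattice
constants.  Excluded volume means no two cubes share a site, which for
corner coordinates is exactly: no pair of corners within Chebyshev distance
1 (minimum image).

Two bond sets are offered.  The ``classic`` set takes the sign/permutation
images of (2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0), (3,1,0) — squared
lengths {4,5,6,9,10}.  This is the standard three-dimensional
bond-fluctuation set: together with single-site moves it provably prevents
chains from crossing.  The ``inclusive`` set adds the (2,2,0) images
(squared length 8), admitting every length in [2, sqrt(10)] at the cost of
that guarantee; it exists for sensitivity checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

_BASE_VECTORS = {
    "classic": [(2, 0, 0), (2, 1, 0), (2, 1, 1), (2, 2, 1), (3, 0, 0), (3, 1, 0)],
    "inclusive": [
        (2, 0, 0), (2, 1, 0), (2, 1, 1), (2, 2, 0), (2, 2, 1), (3, 0, 0), (3, 1, 0),
    ],
}

#: The 6 axial unit moves (nearest-neighbor hops).
MOVE_DIRECTIONS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)


def _expand(base: list[tuple[int, int, int]]) -> frozenset[tuple[int, int, int]]:
    out = set()
    for v in base:
        for perm in itertools.permutations(v):
            for signs in itertools.product((1, -1), repeat=3):
                out.add(tuple(p * s for p, s in zip(perm, signs)))
    return frozenset(out)


BOND_VECTORS: dict[str, frozenset[tuple[int, int, int]]] = {
    name: _expand(base) for name, base in _BASE_VECTORS.items()
}


def bond_lookup_table(bondset: str = "classic") -> np.ndarray:
    """Boolean (7,7,7) table indexed by (dx+3, dy+3, dz+3)."""
    tab = np.zeros((7, 7, 7), dtype=bool)
    for v in BOND_VECTORS[bondset]:
        tab[v[0] + 3, v[1] + 3, v[2] + 3] = True
    return tab


def is_valid_bond(v, bondset: str = "classic") -> bool:
    """True iff the integer 3-vector ``v`` is an allowed covalent bond."""
    t = tuple(int(x) for x in v)
    return t in BOND_VECTORS[bondset]


def minimum_image(d: np.ndarray, L: int) -> np.ndarray:
    """Component-wise minimum-image convention on a periodic box of edge L."""
    return (np.asarray(d) + L // 2) % L - L // 2


class PlacementError(RuntimeError):
    """Initial chain growth failed (lattice too small or retries exhausted)."""


@dataclass
class MoveOutcome:
    """Result of a trial single-site move; rejection is a value, not an error."""

    ok: bool
    new_position: np.ndarray | None = None
    reason: str | None = None  # 'overlap' | 'bond' when not ok


@dataclass
class ChainConformation:
    """Positions (unwrapped corner coordinates) plus a wrapped occupancy map.

    ``positions`` are kept unwrapped so size and displacement observables are
    free of periodic-image artifacts; ``occ`` maps each wrapped corner site
    to its 0-based residue id.  The cube footprint is derived: two cubes
    overlap exactly when their corners are within Chebyshev distance 1, so
    the excluded-volume test is an O(27) neighborhood lookup.  Residue ids
    are 0-based throughout this API.
    """

    positions: np.ndarray
    L: int
    bondset: str = "classic"
    occ: dict[tuple[int, int, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64).reshape(-1, 3)
        if self.L < 8:
            raise ValueError(f"lattice edge L={self.L} below hard floor 8")
        self.occ = self._rebuild_occ()

    # -- construction helpers -------------------------------------------------

    def _rebuild_occ(self) -> dict[tuple[int, int, int], int]:
        occ: dict[tuple[int, int, int], int] = {}
        for i, p in enumerate(self.positions % self.L):
            key = (int(p[0]), int(p[1]), int(p[2]))
            if key in occ:
                raise ValueError(f"residues {occ[key]} and {i} share a corner site")
            occ[key] = i
        return occ

    def dense_grid(self) -> np.ndarray:
        """(L, L, L) int32 occupancy array (-1 empty) for the compiled kernel."""
        grid = np.full((self.L, self.L, self.L), -1, dtype=np.int32)
        for key, i in self.occ.items():
            grid[key] = i
        return grid

    @property
    def n(self) -> int:
        return len(self.positions)

    def bond_vectors(self) -> np.ndarray:
        """Bond vectors between consecutive residues (unwrapped, exact)."""
        return np.diff(self.positions, axis=0)

    # -- geometry checks ------------------------------------------------------

    def _overlaps(self, i: int, corner: np.ndarray) -> bool:
        """Would a cube cornered at ``corner`` overlap any residue but i?"""
        cx, cy, cz = (int(c) % self.L for c in corner)
        L = self.L
        occ = self.occ
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    j = occ.get(((cx + ox) % L, (cy + oy) % L, (cz + oz) % L), -1)
                    if j >= 0 and j != i:
                        return True
        return False

    def propose_move(self, i: int, direction) -> MoveOutcome:
        """Trial move of residue ``i`` by one of the 6 axial unit vectors.

        Checks excluded volume against the occupancy grid and bond validity
        with residues i-1 and i+1; touches only residue i's neighborhood.
        """
        d = np.asarray(direction, dtype=np.int64)
        cand = self.positions[i] + d
        for j in (i - 1, i + 1):
            if 0 <= j < self.n:
                if not is_valid_bond(self.positions[j] - cand, self.bondset):
                    return MoveOutcome(False, reason="bond")
        if self._overlaps(i, cand):
            return MoveOutcome(False, reason="overlap")
        return MoveOutcome(True, new_position=cand)

    def apply_move(self, i: int, new_position: np.ndarray) -> "ChainConformation":
        """Commit a candidate that passed :meth:`propose_move`; returns self."""
        old = tuple(int(v) for v in self.positions[i] % self.L)
        if self.occ.get(old) != i:
            raise RuntimeError("occupancy map out of sync (engine bug)")
        del self.occ[old]
        self.positions[i] = new_position
        new = tuple(int(v) for v in np.asarray(new_position) % self.L)
        self.occ[new] = i
        return self

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        """Full invariant audit: bonds, excluded volume, grid consistency.

        O(N^2); meant for tests and debug mode, not the inner loop.
        """
        for k, b in enumerate(self.bond_vectors()):
            if not is_valid_bond(b, self.bondset):
                raise AssertionError(f"bond {k}->{k + 1} invalid: {tuple(b)}")
        w = self.positions % self.L
        for i in range(self.n):
            d = np.abs(minimum_image(w - w[i], self.L))
            cheb = d.max(axis=1)
            cheb[i] = 99
            if cheb.min() <= 1:
                j = int(np.argmin(cheb))
                raise AssertionError(f"residues {i} and {j} overlap")
        if self.occ != self._rebuild_occ():
            raise AssertionError("occupancy map differs from rebuild")

    def copy(self) -> "ChainConformation":
        return ChainConformation(self.positions.copy(), self.L, self.bondset)


def build_initial_conformation(
    n: int,
    L: int,
    rng_seed: int,
    bondset: str = "classic",
    max_restarts: int = 500,
) -> ChainConformation:
    """Grow a self-avoiding chain of ``n`` cube residues on an L^3 lattice.

    Random growth with allowed bonds; a dead end restarts the whole growth
    from a fresh sub-seed, up to ``max_restarts``.  Deterministic given
    ``rng_seed``.
    """
    if L < 8:
        raise PlacementError(f"lattice edge L={L} below hard floor 8")
    if 8 * n > L**3:
        raise PlacementError(
            f"{n} cube residues need {8 * n} sites; an L={L} lattice has {L**3}"
        )
    bonds = np.array(sorted(BOND_VECTORS[bondset]), dtype=np.int64)
    master = np.random.default_rng(rng_seed)
    for attempt in range(max_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        positions = np.empty((n, 3), dtype=np.int64)
        positions[0] = rng.integers(0, L, size=3)
        try:
            conf = ChainConformation(positions[:1].copy(), L, bondset)
        except ValueError:  # pragma: no cover - single cube always fits
            continue
        ok = True
        for i in range(1, n):
            order = rng.permutation(len(bonds))
            for bi in order:
                cand = conf.positions[i - 1] + bonds[bi]
                if not conf._overlaps(-1, cand):
                    conf.positions = np.vstack([conf.positions, cand[None, :]])
                    conf.occ[tuple(int(v) for v in cand % L)] = i
                    break
            else:
                ok = False
                break
        if ok:
            out = ChainConformation(conf.positions.copy(), L, bondset)
            return out
    raise PlacementError(
        f"failed to place {n} residues on L={L} after {max_restarts} restarts"
    )


# -- snapshot I/O (XYZ-like plain text) ---------------------------------------

def write_conformation(c: ChainConformation, path, sequence=None) -> None:
    """Write ``residue_id  code  x y z`` rows; code is 'X' without a sequence."""
    from .potentials import residue_code

    lines = [f"# L={c.L} bondset={c.bondset} n={c.n}"]
    for i, p in enumerate(c.positions):
        code = residue_code(sequence.residues[i]) if sequence is not None else "X"
        lines.append(f"{i} {code} {p[0]} {p[1]} {p[2]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_conformation(path) -> ChainConformation:
    """Read a snapshot written by :func:`write_conformation`."""
    L = None
    bondset = "classic"
    pos = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                for tok in ln[1:].split():
                    if tok.startswith("L="):
                        L = int(tok[2:])
                    elif tok.startswith("bondset="):
                        bondset = tok[8:]
                continue
            toks = ln.split()
            pos.append([int(toks[2]), int(toks[3]), int(toks[4])])
    if L is None:
        raise ValueError(f"{path}: missing '# L=...' header")
    return ChainConformation(np.array(pos, dtype=np.int64), L, bondset)
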