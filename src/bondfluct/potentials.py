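"""Residue alphabet, sequence parsing, and residue–residue contact matrices.

The twenty amino acids are addressed in a fixed hydropathy ordering
(I, V, L, F, C, M, A, G, T, S, W, Y, P, H, Q, N, D, E, K, R) with 1-based
indices.  A contact matrix is a symmetric 20x20 table of pair energies
eps_ij in reduced units; its 210 independent entries are conventionally
linearized row by row along the upper triangle
(eps_11 ... eps_1,20, eps_22 ... eps_20,20).

Knowledge-based matrices of the Miyazawa–Jernigan (MJ), Betancourt–
Thirumalai (BT) and Bastolla et al. (BFKV) type circulate as plain-text
tables; this module loads either a labeled 20x20 table or a two-column
(index, value) upper-triangle listing, and validates symmetry rather than
silently averaging it away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Fixed hydropathy ordering of the one-letter codes; index = position + 1.
HYDROPATHY_ORDER: str = "IVLFCMAGTSWYPHQNDEKR"

_CODE_TO_INDEX = {code: i + 1 for i, code in enumerate(HYDROPATHY_ORDER)}

#: Number of independent entries of a symmetric 20x20 matrix.
N_TRIANGLE = 210

#: Absolute tolerance beyond which a full table is rejected as asymmetric.
SYMMETRY_ATOL = 1e-9


class InvalidResidueError(ValueError):
    """A letter outside the 20-residue alphabet (includes B, Z, X, U)."""


class MatrixFormatError(ValueError):
    """A contact-matrix file with wrong shape, labels, values or symmetry."""


def residue_index(code: str) -> int:
    """Return the 1-based hydropathy index of a one-letter residue code.

    >>> residue_index("I"), residue_index("R")
    (1, 20)
    """
    try:
        return _CODE_TO_INDEX[code]
    except (KeyError, TypeError):
        raise InvalidResidueError(
            f"unknown residue code {code!r}; expected one of {HYDROPATHY_ORDER}"
        ) from None


def residue_code(index: int) -> str:
    """Inverse of :func:`residue_index` over 1..20."""
    if not 1 <= int(index) <= 20:
        raise InvalidResidueError(f"residue index {index} outside 1..20")
    return HYDROPATHY_ORDER[int(index) - 1]


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain as a list of 1-based hydropathy alphabet indices."""

    residues: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("a sequence needs at least one residue")
        for r in self.residues:
            if not 1 <= r <= 20:
                raise InvalidResidueError(f"residue index {r} outside 1..20")

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return "".join(residue_code(r) for r in self.residues)

    def indices0(self) -> np.ndarray:
        """0-based integer array, the layout used by the numeric kernels."""
        return np.asarray(self.residues, dtype=np.int64) - 1


def parse_sequence(text: str) -> ProteinSequence:
    """Parse a FASTA record or a bare letter string into a ProteinSequence.

    Header lines (``>``/``;``), whitespace, digits, and numbering markers
    (``^``, ``*``, dots, commas) are stripped, so a numbered listing such as
    ``"1M 2A 3R"`` parses the same as ``"MAR"``.  Any remaining letter
    outside the alphabet raises :class:`InvalidResidueError` naming its
    position.
    """
    lines = [
        ln for ln in text.splitlines() if not ln.lstrip().startswith((">", ";"))
    ]
    stripped = "".join(lines)
    letters = [
        ch for ch in stripped if not (ch.isdigit() or ch.isspace() or ch in "^*.,-")
    ]
    if not letters:
        raise ValueError("empty sequence after stripping headers and markup")
    residues = []
    for pos, ch in enumerate(letters, start=1):
        try:
            residues.append(residue_index(ch.upper()))
        except InvalidResidueError:
            raise InvalidResidueError(
                f"invalid residue {ch!r} at position {pos}"
            ) from None
    return ProteinSequence(tuple(residues))


def read_sequence(path: str | Path) -> ProteinSequence:
    """Read a sequence file (FASTA or bare/numbered text)."""
    return parse_sequence(Path(path).read_text())


def h3_1_sequence() -> ProteinSequence:
    """The bundled 136-residue histone H3.1 sequence."""
    return read_sequence(Path(__file__).parent / "data" / "h3_1.fasta")


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

def triangle_to_square(values: Sequence[float]) -> np.ndarray:
    """Expand a 210-element upper-triangle listing into a symmetric 20x20.

    The listing order is row-major along the upper triangle including the
    diagonal: eps_11 ... eps_1,20, eps_22 ... eps_2,20, ..., eps_20,20.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (N_TRIANGLE,):
        raise MatrixFormatError(
            f"triangle listing must have {N_TRIANGLE} values, got {v.shape}"
        )
    eps = np.zeros((20, 20))
    iu = np.triu_indices(20)
    eps[iu] = v
    eps.T[iu] = v
    return eps


def square_to_triangle(eps: np.ndarray) -> np.ndarray:
    """Linearize the upper triangle (incl. diagonal) in the canonical order."""
    eps = np.asarray(eps, dtype=float)
    return eps[np.triu_indices(20)].copy()


@dataclass(frozen=True)
class ContactMatrix:
    """A symmetric 20x20 residue-pair energy table in reduced units."""

    name: str
    eps: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        if eps.shape != (20, 20):
            raise MatrixFormatError(f"matrix must be 20x20, got {eps.shape}")
        if not np.all(np.isfinite(eps)):
            raise MatrixFormatError("matrix contains non-finite entries")
        if not np.array_equal(eps, eps.T):
            raise MatrixFormatError("matrix is not exactly symmetric")
        object.__setattr__(self, "eps", eps)
        self.eps.setflags(write=False)

    def pair_epsilon(self, a: int, b: int) -> float:
        """Symmetric lookup eps_ab for 1-based alphabet indices a, b."""
        if not (1 <= a <= 20 and 1 <= b <= 20):
            raise IndexError(f"residue indices ({a}, {b}) outside 1..20")
        return float(self.eps[a - 1, b - 1])

    def triangle(self) -> np.ndarray:
        return square_to_triangle(self.eps)


def pair_epsilon(m: ContactMatrix, a: int, b: int) -> float:
    """Functional alias of :meth:`ContactMatrix.pair_epsilon`."""
    return m.pair_epsilon(a, b)


def _symmetrize_checked(eps: np.ndarray, source: str) -> np.ndarray:
    delta = np.abs(eps - eps.T)
    if delta.max() > SYMMETRY_ATOL:
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        raise MatrixFormatError(
            f"{source}: asymmetric entries eps[{i + 1},{j + 1}]={eps[i, j]!r} "
            f"vs eps[{j + 1},{i + 1}]={eps[j, i]!r} (|diff| {delta[i, j]:.3g} "
            f"> {SYMMETRY_ATOL:g}); fix the transcription, not the loader"
        )
    # quoted matrices are symmetric to printed precision; make it exact
    return (eps + eps.T) / 2.0


def load_contact_matrix(path: str | Path, name: str | None = None) -> ContactMatrix:
    """Load a contact matrix from a plain-text file.

    Two dialects are accepted:

    * a full 20x20 table, whitespace separated, with one-letter residue
      labels as a header row and as the first column (label order may be any
      permutation of the alphabet; rows/columns are reindexed to the
      hydropathy ordering);
    * a two-column (index, value) listing of the 210 upper-triangle elements
      in canonical order, 1-based indices.

    Lines starting with ``#`` are comments.  A full table whose asymmetry
    exceeds ``SYMMETRY_ATOL`` is rejected.
    """
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MatrixFormatError(f"{path}: empty matrix file")
    label = name if name is not None else path.stem
    tokens0 = lines[0].split()

    if len(tokens0) == 2 and _is_number(tokens0[0]):
        return _load_triangle(lines, label, str(path))
    return _load_table(lines, label, str(path))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _load_triangle(lines: list[str], name: str, source: str) -> ContactMatrix:
    if len(lines) != N_TRIANGLE:
        raise MatrixFormatError(
            f"{source}: triangle format needs {N_TRIANGLE} rows, got {len(lines)}"
        )
    values = np.empty(N_TRIANGLE)
    seen = np.zeros(N_TRIANGLE, dtype=bool)
    for ln in lines:
        toks = ln.split()
        if len(toks) != 2:
            raise MatrixFormatError(f"{source}: bad triangle row {ln!r}")
        try:
            idx = int(toks[0])
            val = float(toks[1])
        except ValueError:
            raise MatrixFormatError(f"{source}: non-numeric row {ln!r}") from None
        if not 1 <= idx <= N_TRIANGLE:
            raise MatrixFormatError(f"{source}: triangle index {idx} outside 1..210")
        if seen[idx - 1]:
            raise MatrixFormatError(f"{source}: duplicate triangle index {idx}")
        seen[idx - 1] = True
        values[idx - 1] = val
    return ContactMatrix(name, triangle_to_square(values))


def _load_table(lines: list[str], name: str, source: str) -> ContactMatrix:
    header = [t.upper() for t in lines[0].split()]
    if len(header) != 20 or sorted(header) != sorted(HYDROPATHY_ORDER):
        raise MatrixFormatError(
            f"{source}: header must list the 20 one-letter codes, got {header}"
        )
    if len(lines) != 21:
        raise MatrixFormatError(
            f"{source}: expected 20 data rows after the header, got {len(lines) - 1}"
        )
    raw = np.empty((20, 20))
    row_labels: list[str] = []
    for r, ln in enumerate(lines[1:]):
        toks = ln.split()
        if len(toks) != 21:
            raise MatrixFormatError(f"{source}: row {r + 1} has {len(toks)} fields")
        row_labels.append(toks[0].upper())
        try:
            raw[r] = [float(t) for t in toks[1:]]
        except ValueError:
            raise MatrixFormatError(f"{source}: non-numeric cell in row {toks[0]}") from None
    if sorted(row_labels) != sorted(HYDROPATHY_ORDER):
        raise MatrixFormatError(f"{source}: row labels {row_labels} are not the alphabet")
    # reindex into hydropathy order
    ri = [residue_index(c) - 1 for c in row_labels]
    ci = [residue_index(c) - 1 for c in header]
    eps = np.empty((20, 20))
    eps[np.ix_(ri, ci)] = raw
    return ContactMatrix(name, _symmetrize_checked(eps, source))


def write_contact_matrix(
    m: ContactMatrix, path: str | Path, dialect: str = "table"
) -> None:
    """Serialize a matrix as a labeled ``table`` or 210-row ``triangle``."""
    path = Path(path)
    if dialect == "table":
        # repr keeps full precision so load(write(m)) is exact
        out = ["# contact matrix: " + m.name]
        out.append("  " + " ".join(HYDROPATHY_ORDER))
        for i, c in enumerate(HYDROPATHY_ORDER):
            out.append(c + " " + " ".join(repr(float(v)) for v in m.eps[i]))
    elif dialect == "triangle":
        out = ["# contact matrix (upper-triangle): " + m.name]
        out += [
            f"{i + 1} {float(v)!r}" for i, v in enumerate(square_to_triangle(m.eps))
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(out) + "\n")


def bundled_matrix_path(name: str) -> Path:
    """Path of a bundled matrix file (``uniform0`` or ``uniform_attract``).

    Slots for user-supplied ``mj``, ``bt``, ``bfkv`` files resolve to the
    same data directory but are empty by default: the published MJ/BT/BFKV
    tables are not redistributed here and must be transcribed from their
    original sources by the user.
    """
    p = Path(__file__).parent / "data" / f"{name}.mat"
    if not p.exists():
        raise FileNotFoundError(
            f"no bundled matrix {name!r}; user-supplied matrices (mj, bt, bfkv) "
            f"must be placed at {p} or passed by explicit path"
        )
    return p
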