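"""RNA secondary-structure prediction and representation.

The internal folder is a weighted base-pair maximization (Nussinov-style)
dynamic program rather than a full nearest-neighbour thermodynamic model:
pair weights are G:C = 3, A:T/U = 2, G:T/U (wobble) = 1, with a minimum
hairpin-loop separation ``min_loop`` (default 3).  The traceback is
deterministic (a position is left unpaired whenever that is optimal, and
otherwise pairs with the outermost — rightmost — partner achieving the
optimum, which favours long contiguous stems over equal-score bulged
rearrangements), so folds are reproducible across platforms.  Thermodynamic structures produced by an
external folder can be injected through :func:`import_structure`, which reads
the common Vienna dialect (header / sequence / dot-bracket with an optional
trailing free energy).

The DP matrix ``W`` holds the optimal score of *every* subinterval of the
input, so one call to :class:`FoldedRegion` serves structures for all
candidate precursor windows inside a region — this is what makes sliding
window evaluation in novel-miRNA discovery cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqs import check_alphabet

#: nucleotide codes used by the numba kernels (U folded onto T)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

#: pair weights: G:C=3, A:T=2, G:T=1, everything else unpairable
PAIR_WEIGHTS = np.zeros((4, 4), dtype=np.int64)
PAIR_WEIGHTS[2, 1] = PAIR_WEIGHTS[1, 2] = 3
PAIR_WEIGHTS[0, 3] = PAIR_WEIGHTS[3, 0] = 2
PAIR_WEIGHTS[2, 3] = PAIR_WEIGHTS[3, 2] = 1

DEFAULT_MIN_LOOP = 3


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure over one sequence.

    ``pair_table[i]`` is the 0-based partner of position ``i`` or ``None``.
    ``score`` is the weighted pair sum from the internal folder, or an
    externally supplied free energy for imported structures.
    """

    sequence: str
    dotbracket: str
    pair_table: tuple
    score: float

    def __post_init__(self):
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HairpinDecomposition:
    """Stem-loop anatomy: 5' arm, terminal loop and 3' arm intervals
    (0-based half-open) plus the number of disjoint stem-loops."""

    stem5: tuple
    loop: tuple
    stem3: tuple
    n_stems: int


def encode(sequence: str) -> np.ndarray:
    check_alphabet(sequence)
    return np.array([_CODE[c] for c in sequence.upper()], dtype=np.int64)


@njit(cache=True)
def _fill_matrix(codes, wmat, min_loop):  # pragma: no cover - numba kernel
    n = codes.size
    W = np.zeros((n + 2, n + 2), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                w = wmat[codes[i], codes[k]]
                if w > 0:
                    s = w + W[i + 1, k - 1] + W[k + 1, j]
                    if s > best:
                        best = s
            W[i, j] = best
    return W


@njit(cache=True)
def _traceback(W, codes, wmat, min_loop, i0, j0):  # pragma: no cover
    n = codes.size
    pt = np.full(n, -1, dtype=np.int64)
    stack = np.empty((2 * n + 4, 2), dtype=np.int64)
    top = 0
    stack[top, 0] = i0
    stack[top, 1] = j0
    top += 1
    while top > 0:
        top -= 1
        i = stack[top, 0]
        j = stack[top, 1]
        if i >= j:
            continue
        if W[i, j] == W[i + 1, j]:
            stack[top, 0] = i + 1
            stack[top, 1] = j
            top += 1
            continue
        for k in range(j, i + min_loop, -1):
            w = wmat[codes[i], codes[k]]
            if w > 0 and W[i, j] == w + W[i + 1, k - 1] + W[k + 1, j]:
                pt[i] = k
                pt[k] = i
                stack[top, 0] = i + 1
                stack[top, 1] = k - 1
                top += 1
                stack[top, 0] = k + 1
                stack[top, 1] = j
                top += 1
                break
    return pt


def _pairs_to_structure(sequence, pt_array, offset, length, score):
    pair_table = []
    brackets = []
    for i in range(length):
        p = pt_array[offset + i]
        if p < 0:
            pair_table.append(None)
            brackets.append(".")
        else:
            rel = int(p) - offset
            pair_table.append(rel)
            brackets.append("(" if rel > i else ")")
    return SecondaryStructure(
        sequence=sequence,
        dotbracket="".join(brackets),
        pair_table=tuple(pair_table),
        score=float(score),
    )


class FoldedRegion:
    """Shared fold matrix for one region; structures of any subwindow
    ``[start, end)`` are read out of it without re-running the DP."""

    def __init__(self, sequence: str, min_loop: int = DEFAULT_MIN_LOOP):
        if len(sequence) < min_loop + 2:
            raise ValueError("sequence shorter than min_loop + 2")
        self.sequence = sequence.upper()
        self.min_loop = min_loop
        self._codes = encode(sequence)
        self._W = _fill_matrix(self._codes, PAIR_WEIGHTS, min_loop)

    def score(self, start: int, end: int) -> int:
        return int(self._W[start, end - 1])

    def subfold(self, start: int, end: int) -> SecondaryStructure:
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError("window outside region bounds")
        pt = _traceback(self._W, self._codes, PAIR_WEIGHTS, self.min_loop,
                        start, end - 1)
        return _pairs_to_structure(self.sequence[start:end], pt, start,
                                   end - start, self._W[start, end - 1])


def fold(sequence: str, min_loop: int = DEFAULT_MIN_LOOP) -> SecondaryStructure:
    """Predict the maximum-weight pseudoknot-free structure of ``sequence``.

    Raises ``ValueError`` for alphabets outside {A,C,G,T,U} or sequences
    shorter than ``min_loop + 2``.  The score is invariant under U/T
    representation of the input.
    """
    region = FoldedRegion(sequence, min_loop=min_loop)
    return region.subfold(0, len(sequence))


def parse_dotbracket(text: str) -> tuple:
    """Stack-parse a dot-bracket string into a pair table.

    Raises ``ValueError`` naming the offending index for unbalanced input.
    """
    pt = [None] * len(text)
    stack = []
    for i, c in enumerate(text):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at index {i}")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
        elif c != ".":
            raise ValueError(f"invalid character {c!r} at index {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at index {stack[0]}")
    return tuple(pt)


def render_dotbracket(pair_table) -> str:
    out = []
    for i, p in enumerate(pair_table):
        out.append("." if p is None else ("(" if p > i else ")"))
    return "".join(out)


def structure_from_dotbracket(sequence: str, dotbracket: str,
                              score: float = 0.0) -> SecondaryStructure:
    if len(sequence) != len(dotbracket):
        raise ValueError("sequence and structure lengths differ")
    return SecondaryStructure(sequence=sequence, dotbracket=dotbracket,
                              pair_table=parse_dotbracket(dotbracket),
                              score=score)


def import_structure(path) -> SecondaryStructure:
    """Read the first record of a Vienna-dialect structure file.

    Format: a ``>name`` header line, a sequence line, and a dot-bracket line
    with an optional trailing ``(energy)``; the parsed energy becomes the
    structure score.
    """
    records = read_vienna(path)
    if not records:
        raise ValueError(f"no structure records in {path}")
    return records[0][1]


def read_vienna(path) -> list:
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected FASTA-style header, got {lines[i]!r}")
        name = lines[i][1:].strip()
        seq = lines[i + 1].strip()
        struct_line = lines[i + 2].strip()
        score = 0.0
        db = struct_line
        if "(" in struct_line and struct_line.split()[-1].startswith("("):
            head, _, tail = struct_line.rpartition(" ")
            if head and tail.startswith("(") and tail.endswith(")"):
                try:
                    score = float(tail[1:-1])
                    db = head.strip()
                except ValueError:
                    pass
        records.append((name, structure_from_dotbracket(seq, db, score)))
        i += 3
    return records


def write_vienna(records, path) -> None:
    """Write ``(name, SecondaryStructure)`` pairs in Vienna dialect."""
    with open(path, "w") as fh:
        for name, s in records:
            fh.write(f">{name}\n{s.sequence}\n{s.dotbracket} ({s.score:g})\n")


def count_stems(pair_table) -> int:
    """Number of disjoint stem-loops = number of terminal (hairpin) loops,
    i.e. pairs enclosing no other paired position."""
    n = len(pair_table)
    n_stems = 0
    i = 0
    while i < n:
        p = pair_table[i]
        if p is not None and p > i:
            # innermost iff nothing paired strictly inside
            if all(pair_table[x] is None for x in range(i + 1, p)):
                n_stems += 1
                i = p
                continue
        i += 1
    return n_stems


def decompose_hairpin(structure: SecondaryStructure) -> HairpinDecomposition:
    """Split a structure into 5' arm, terminal loop and 3' arm.

    For multi-stem structures the decomposition describes the first stem-loop
    and reports ``n_stems`` so callers can enforce a single-stem requirement.
    Raises ``ValueError`` when the structure has no pairs at all.
    """
    pt = structure.pair_table
    paired = [i for i, p in enumerate(pt) if p is not None]
    if not paired:
        raise ValueError("no stem: structure has no base pairs")
    n_stems = count_stems(pt)
    # innermost pair of the first stem
    inner = None
    for i in range(len(pt)):
        p = pt[i]
        if p is not None and p > i and all(pt[x] is None for x in range(i + 1, p)):
            inner = (i, p)
            break
    a, b = inner
    # outermost extent of the stem enclosing (a, b)
    lo, hi = a, b
    for i in range(a, -1, -1):
        p = pt[i]
        if p is not None and p >= b:
            lo, hi = i, p
    return HairpinDecomposition(stem5=(lo, a + 1), loop=(a + 1, b),
                                stem3=(b, hi + 1), n_stems=n_stems)
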