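"""Deterministic minimum-energy RNA secondary-structure prediction.

The folder is a simplified nearest-neighbor dynamic program: energy comes
from stacked base pairs (Watson-Crick and G:U wobble), hairpin loops pay a
flat closing penalty (minimum loop 3), and bulges/interior loops pay a
size-dependent penalty. Multibranch loops are not formed inside a helix;
independent stem-loops may sit side by side at the external level, which
is sufficient for hairpin-precursor evaluation. Structures are unique and
deterministic for a given sequence (ties broken toward the innermost /
leftmost choice). A precomputed dot-bracket structure, when supplied,
overrides the built-in folder for that sequence.

Energies are on a kcal/mol-like scale calibrated so that canonical
pre-miRNA hairpins (>=16-pair stems) fall well below the -15 kcal/mol
stability cutoff while random unstructured sequence stays near 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["PrecursorFold", "fold", "pair_table", "HAIRPIN_PENALTY"]

# pair "strength" (stacking half-contribution): GC > AU > GU
_STRENGTH = np.zeros((5, 5), dtype=np.float64)
_PAIRABLE = np.zeros((5, 5), dtype=np.bool_)
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
for _a, _b, _s in (("G", "C", 1.6), ("A", "T", 1.0), ("G", "T", 0.5)):
    _i, _j = _ENC[_a], _ENC[_b]
    _STRENGTH[_i, _j] = _STRENGTH[_j, _i] = _s
    _PAIRABLE[_i, _j] = _PAIRABLE[_j, _i] = True

HAIRPIN_PENALTY = 4.0
INTERIOR_BASE = 3.0
INTERIOR_PER_NT = 0.25
MIN_LOOP = 3
MAX_INTERIOR = 16  # total unpaired nt allowed in one bulge/interior loop
INF = 1e9


@dataclass
class PrecursorFold:
    """A folded candidate precursor with its dot-bracket structure."""

    seq: str
    structure: str
    energy: float
    mature_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.seq):
            raise ValueError("structure length differs from sequence length")
        pair_table(self.structure)  # balance check
        if self.mature_span is not None:
            s, e = self.mature_span
            if not (0 <= s < e <= len(self.seq)):
                raise ValueError("mature span out of bounds")


@njit(cache=True)
def _fill(x, strength, pairable):  # pragma: no cover - exercised via fold()
    n = x.shape[0]
    V = np.full((n, n), INF)
    ci = np.full((n, n), -2, dtype=np.int32)  # inner i (-1 = hairpin closure)
    cj = np.full((n, n), -2, dtype=np.int32)
    for d in range(MIN_LOOP + 1, n):
        for i in range(n - d):
            j = i + d
            if not pairable[x[i], x[j]]:
                continue
            best = HAIRPIN_PENALTY
            bi, bj = -1, -1
            # stack on the immediately inner pair
            if d >= MIN_LOOP + 3 and pairable[x[i + 1], x[j - 1]]:
                e = -(strength[x[i], x[j]] + strength[x[i + 1], x[j - 1]]) + V[i + 1, j - 1]
                if e < best:
                    best = e
                    bi, bj = i + 1, j - 1
            # bulge / interior loop to a more distant inner pair
            for di in range(0, MAX_INTERIOR + 1):
                ii = i + di + 1
                if ii >= j:
                    break
                for dj in range(0, MAX_INTERIOR + 1 - di):
                    if di == 0 and dj == 0:
                        continue
                    jj = j - dj - 1
                    if jj - ii < MIN_LOOP + 1:
                        break
                    if V[ii, jj] >= INF:
                        continue
                    e = INTERIOR_BASE + INTERIOR_PER_NT * (di + dj) + V[ii, jj]
                    if e < best:
                        best = e
                        bi, bj = ii, jj
            V[i, j] = best
            ci[i, j] = bi
            cj[i, j] = bj
    # external level: concatenation of stabilizing stem-loops
    W = np.zeros(n + 1)
    wc = np.full(n, -1, dtype=np.int32)
    for j in range(n):
        W[j + 1] = W[j]
        for i in range(j):
            if V[i, j] < INF:
                e = W[i] + V[i, j]
                if e < W[j + 1] - 1e-12:
                    W[j + 1] = e
                    wc[j] = i
    return V, ci, cj, W, wc


def fold(
    seq: str,
    structures: dict[str, tuple[str, float]] | None = None,
    name: str | None = None,
) -> PrecursorFold:
    """Fold a sequence into its minimum-energy structure.

    If *structures* holds a precomputed (dot-bracket, energy) entry for
    *name*, that structure is used verbatim instead of the built-in folder.
    """
    if structures is not None and name is not None and name in structures:
        struct, energy = structures[name]
        return PrecursorFold(seq, struct, energy)
    s = seq.upper().replace("U", "T")
    if not s or any(c not in _ENC for c in s):
        raise ValueError("sequence must be non-empty over {A,C,G,T,U,N}")
    x = np.array([_ENC[c] for c in s], dtype=np.int8)
    V, ci, cj, W, wc = _fill(x, _STRENGTH, _PAIRABLE)
    n = len(s)
    struct = ["."] * n
    j = n - 1
    stack: list[tuple[int, int]] = []
    while j >= 0:
        i = wc[j]
        if i < 0:
            j -= 1
            continue
        stack.append((i, j))
        j = i - 1
    while stack:
        i, j = stack.pop()
        struct[i] = "("
        struct[j] = ")"
        ii, jj = ci[i, j], cj[i, j]
        if ii >= 0:
            stack.append((ii, jj))
    energy = float(W[n]) if W[n] < 0 else 0.0
    return PrecursorFold(s, "".join(struct), round(energy, 2))


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position (-1 = unpaired); errors on unbalanced input."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt
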