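"""RNA hairpin secondary-structure prediction.

Three interchangeable backends behind :func:`fold_hairpin`:

``nn`` (default)
    A simplified nearest-neighbor free-energy model: Watson-Crick and G:U
    pairs, helix stacking energies from a shipped parameter table, tabulated
    hairpin/bulge/internal-loop length penalties with Jacobson-Stockmayer
    extrapolation, minimum hairpin loop of 3 nt, bounded internal loops and
    no multibranch loops or pseudoknots.  Energies are in kcal/mol at 37 C.
    This is intentionally a *simplified* model: terminal-mismatch, dangling
    end and special-loop terms are omitted, so absolute energies are a few
    kcal/mol from full Turner values while rankings of hairpin-forming
    windows are preserved.

``maxpair``
    Base-pair maximization (Nussinov dynamic programming) with the same pair
    alphabet and minimum loop.  ``delta_g`` is reported as ``-pairs`` in
    arbitrary units; use it only for structure comparisons.

``vienna``
    ViennaRNA minimum free energy, if the ``RNA`` python bindings are
    importable.  The backend in use is recorded on the returned fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

RT37 = 0.6163  # kcal/mol

_BASE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair type indices: CG GC GU UG AU UA  (-1 = cannot pair)
_PAIR_IDX = -np.ones((4, 4), dtype=np.int8)
for _i, (_a, _b) in enumerate([(1, 2), (2, 1), (2, 3), (3, 2), (0, 3), (3, 0)]):
    _PAIR_IDX[_a, _b] = _i

# stacking free energies, kcal/mol: rows = outer pair (i,j), cols = inner (i+1,j-1)
_STACK = np.array(
    [
        #  CG     GC     GU     UG     AU     UA
        [-3.3, -3.4, -2.1, -1.4, -2.1, -2.4],  # CG
        [-2.4, -3.3, -1.4, -2.5, -2.2, -2.1],  # GC
        [-2.5, -2.1, -1.3, +0.5, -1.4, -1.3],  # GU
        [-2.1, -1.4, -0.5, -1.3, -1.0, -0.6],  # UG
        [-2.1, -2.2, -1.4, -0.9, -1.1, -0.9],  # AU
        [-2.4, -2.1, -1.0, -1.3, -1.3, -0.9],  # UA
    ]
)

_MAXLOOP = 12  # maximum total unpaired nt in a bulge/internal loop
_MINLOOP = 3


def _loop_tables(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hairpin/bulge/internal loop penalties for every loop size up to n."""
    hp = np.full(n + 1, np.inf)
    base_hp = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
    for size in range(3, n + 1):
        if size in base_hp:
            hp[size] = base_hp[size]
        else:
            hp[size] = base_hp[9] + 1.75 * RT37 * math.log(size / 9.0)
    bulge = np.full(_MAXLOOP + 1, np.inf)
    base_bulge = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
    for size in range(1, _MAXLOOP + 1):
        bulge[size] = base_bulge.get(size, base_bulge[6] + 1.75 * RT37 * math.log(size / 6.0))
    internal = np.full(_MAXLOOP + 1, np.inf)
    base_int = {2: 1.5, 3: 1.6, 4: 1.7, 5: 2.0, 6: 2.0}
    for size in range(2, _MAXLOOP + 1):
        internal[size] = base_int.get(size, base_int[6] + 1.75 * RT37 * math.log(size / 6.0))
    return hp, bulge, internal


@njit(cache=True)
def _zuker_fill(codes, pidx, stack, hp, bulge, internal, maxloop, minloop):  # pragma: no cover
    n = codes.size
    INF = 1e9
    V = np.full((n, n), INF)
    for span in range(minloop + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pidx[codes[i], codes[j]]
            if pt < 0:
                continue
            best = hp[span - 1]  # hairpin closure, loop size j-i-1
            dmax = maxloop
            for d1 in range(0, dmax + 1):
                k = i + 1 + d1
                if k >= j:
                    break
                for d2 in range(0, dmax + 1 - d1):
                    l = j - 1 - d2
                    if l - k < minloop + 1:
                        break
                    qt = pidx[codes[k], codes[l]]
                    if qt < 0:
                        continue
                    if V[k, l] >= INF:
                        continue
                    if d1 == 0 and d2 == 0:
                        pen = stack[pt, qt]
                    elif d1 == 0 or d2 == 0:
                        pen = bulge[d1 + d2]
                    else:
                        asym = abs(d1 - d2) * 0.5
                        if asym > 3.0:
                            asym = 3.0
                        pen = internal[d1 + d2] + asym
                    e = V[k, l] + pen
                    if e < best:
                        best = e
            V[i, j] = best
    W = np.zeros(n + 1)
    WI = np.full(n + 1, -1, dtype=np.int64)  # start index of helix ending at j, or -1
    for j in range(1, n + 1):
        best = W[j - 1]
        arg = -1
        for i in range(0, j):
            if V[i, j - 1] < INF:
                e = W[i] + V[i, j - 1]
                if e < best - 1e-9:
                    best = e
                    arg = i
        W[j] = best
        WI[j] = arg
    return V, W, WI


@njit(cache=True)
def _nussinov_fill(codes, pidx, minloop):  # pragma: no cover
    n = codes.size
    M = np.zeros((n, n), dtype=np.int64)
    for span in range(minloop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i, j - 1]
            for k in range(i, j - minloop):
                if pidx[codes[k], codes[j]] >= 0:
                    left = M[i, k - 1] if k > i else 0
                    v = left + M[k + 1, j - 1] + 1
                    if v > best:
                        best = v
            M[i, j] = best
    return M


@dataclass
class HairpinFold:
    """A nested secondary structure with its (pseudo-)free energy."""

    sequence: str
    structure: str
    delta_g: float
    pair_table: np.ndarray  # partner index or -1, length == len(sequence)
    backend: str = "nn"

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure length != sequence length")
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced brackets")

    @property
    def n_pairs(self) -> int:
        return int((self.pair_table >= 0).sum()) // 2


def _encode_rna(sequence: str) -> np.ndarray:
    codes = np.empty(len(sequence), dtype=np.int8)
    for i, ch in enumerate(sequence.upper()):
        if ch not in _BASE:
            raise ValueError(f"non-ACGU character {ch!r} at position {i}")
        codes[i] = _BASE[ch]
    return codes


def _pairs_to_structure(n: int, pairs: list[tuple[int, int]]) -> tuple[str, np.ndarray]:
    pt = np.full(n, -1, dtype=np.int64)
    chars = ["."] * n
    for i, j in pairs:
        pt[i], pt[j] = j, i
        chars[i], chars[j] = "(", ")"
    return "".join(chars), pt


def _zuker_traceback(codes, V, W, WI, hp, bulge, internal, stack, pidx) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    n = codes.size
    INF = 1e9
    # exterior loop
    j = n
    helices = []
    while j > 0:
        i = WI[j]
        if i < 0:
            j -= 1
        else:
            helices.append((int(i), j - 1))
            j = int(i)
    # interior decisions
    stack_nodes = list(helices)
    while stack_nodes:
        i, j = stack_nodes.pop()
        pairs.append((i, j))
        pt = pidx[codes[i], codes[j]]
        target = V[i, j]
        if abs(target - hp[j - i - 1]) < 1e-6:
            hp_is_best = True
        else:
            hp_is_best = False
        found = False
        for d1 in range(0, _MAXLOOP + 1):
            k = i + 1 + d1
            if k >= j:
                break
            for d2 in range(0, _MAXLOOP + 1 - d1):
                l = j - 1 - d2
                if l - k < _MINLOOP + 1:
                    break
                qt = pidx[codes[k], codes[l]]
                if qt < 0 or V[k, l] >= INF:
                    continue
                if d1 == 0 and d2 == 0:
                    pen = stack[pt, qt]
                elif d1 == 0 or d2 == 0:
                    pen = bulge[d1 + d2]
                else:
                    pen = internal[d1 + d2] + min(abs(d1 - d2) * 0.5, 3.0)
                if abs(V[k, l] + pen - target) < 1e-6:
                    stack_nodes.append((k, l))
                    found = True
                    break
            if found:
                break
        if not found and not hp_is_best:
            # numerical tie fallback: close as hairpin
            pass
    return pairs


def _nussinov_traceback(codes, M, pidx) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    work = [(0, codes.size - 1)]
    while work:
        i, j = work.pop()
        if i >= j or j - i <= _MINLOOP:
            continue
        if M[i, j] == M[i, j - 1]:
            work.append((i, j - 1))
            continue
        for k in range(i, j - _MINLOOP):
            if pidx[codes[k], codes[j]] >= 0:
                left = M[i, k - 1] if k > i else 0
                if left + M[k + 1, j - 1] + 1 == M[i, j]:
                    pairs.append((k, j))
                    if k > i:
                        work.append((i, k - 1))
                    work.append((k + 1, j - 1))
                    break
    return pairs


def fold_hairpin(
    sequence: str,
    backend: str = "nn",
    min_len: int = 10,
    max_len: int = 700,
) -> HairpinFold:
    """Predict the minimum-energy nested structure of a candidate precursor.

    Parameters
    ----------
    sequence:
        RNA or DNA string (T is read as U); non-ACGTU characters raise.
    backend:
        ``nn`` (default), ``maxpair`` or ``vienna``; see module docstring.
    """
    if not (min_len <= len(sequence) <= max_len):
        raise ValueError(
            f"sequence length {len(sequence)} outside [{min_len}, {max_len}]"
        )
    codes = _encode_rna(sequence)
    rna = sequence.upper().replace("T", "U")
    if backend == "maxpair":
        M = _nussinov_fill(codes, _PAIR_IDX, _MINLOOP)
        pairs = _nussinov_traceback(codes, M, _PAIR_IDX)
        structure, pt = _pairs_to_structure(len(rna), pairs)
        return HairpinFold(rna, structure, -float(len(pairs)), pt, backend="maxpair")
    if backend == "vienna":
        import RNA  # type: ignore

        structure, mfe = RNA.fold(rna)
        pt = np.full(len(rna), -1, dtype=np.int64)
        stack: list[int] = []
        for i, ch in enumerate(structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                pt[i], pt[j] = j, i
        return HairpinFold(rna, structure, float(mfe), pt, backend="vienna")
    if backend != "nn":
        raise ValueError(f"unknown folding backend {backend!r}")
    hp, bulge, internal = _loop_tables(len(rna))
    V, W, WI = _zuker_fill(
        codes, _PAIR_IDX, _STACK, hp, bulge, internal, _MAXLOOP, _MINLOOP
    )
    pairs = _zuker_traceback(codes, V, W, WI, hp, bulge, internal, _STACK, _PAIR_IDX)
    structure, pt = _pairs_to_structure(len(rna), pairs)
    dg = float(W[len(rna)])
    return HairpinFold(rna, structure, min(dg, 0.0), pt, backend="nn")


def max_pair_count(sequence: str) -> int:
    """Number of base pairs in the pair-maximization structure."""
    return fold_hairpin(sequence, backend="maxpair").n_pairs
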