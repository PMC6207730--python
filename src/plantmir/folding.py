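"""RNA secondary-structure prediction backends.

Two engines satisfy the same contract — given an RNA sequence, return a
dot-bracket structure and its minimum free energy (MFE):

* ``"fallback"`` — a built-in base-pair-weighted Nussinov dynamic program.
  Pair energies are GC −3, AU −2, GU −1 kcal/mol, hairpin loops must hold
  at least 3 unpaired bases, and pseudoknots are excluded. The DP returns
  the exact optimum of this model. It exists so the whole pipeline runs
  deterministically with no external thermodynamic engine.
* ``"vienna"`` — ViennaRNA's nearest-neighbor model through its Python
  bindings, when importable. This backend additionally reports ensemble
  quantities (ensemble free energy, diversity, MFE-structure frequency).

Ensemble descriptors are backend-provided only; the fallback never fakes
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from numba import njit

from .seqs import RNA_ALPHABET, encode

#: fallback pair energies, kcal/mol (indexed by code pair)
PAIR_ENERGY = {
    (1, 2): -3.0, (2, 1): -3.0,   # C-G
    (0, 3): -2.0, (3, 0): -2.0,   # A-U
    (2, 3): -1.0, (3, 2): -1.0,   # G-U
}

MIN_HAIRPIN_LOOP = 3


@dataclass(frozen=True)
class FoldResult:
    """A predicted secondary structure with its energy.

    ``ensemble_mfe`` (free energy of the ensemble), ``diversity`` (expected
    base-pair distance) and ``ensemble_frequency`` (Boltzmann probability of
    the MFE structure) are populated only by backends that compute a
    partition function.
    """

    structure: str
    mfe: float
    ensemble_mfe: Optional[float] = None
    diversity: Optional[float] = None
    ensemble_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")


@njit(cache=True)
def _pair_e(a: np.int8, b: np.int8) -> np.int32:
    if (a == 1 and b == 2) or (a == 2 and b == 1):
        return -3
    if (a == 0 and b == 3) or (a == 3 and b == 0):
        return -2
    if (a == 2 and b == 3) or (a == 3 and b == 2):
        return -1
    return 0


@njit(cache=True)
def _nussinov_fill(codes: np.ndarray, min_loop: int) -> np.ndarray:
    n = codes.size
    E = np.zeros((n, n), dtype=np.int32)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j]
            if E[i, j - 1] < best:
                best = E[i, j - 1]
            if j - i - 1 >= min_loop:
                e = _pair_e(codes[i], codes[j])
                if e < 0:
                    v = e + E[i + 1, j - 1]
                    if v < best:
                        best = v
            for k in range(i + 1, j):
                v = E[i, k] + E[k + 1, j]
                if v < best:
                    best = v
            E[i, j] = best
    return E


def _traceback(codes: np.ndarray, E: np.ndarray, min_loop: int) -> str:
    n = codes.size
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if E[i, j] == E[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if E[i, j] == E[i, j - 1]:
            stack.append((i, j - 1))
            continue
        if j - i - 1 >= min_loop:
            e = _pair_e(codes[i], codes[j])
            if e < 0 and E[i, j] == e + E[i + 1, j - 1]:
                struct[i] = "("
                struct[j] = ")"
                stack.append((i + 1, j - 1))
                continue
        for k in range(i + 1, j):
            if E[i, j] == E[i, k] + E[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return "".join(struct)


def fold_fallback(sequence: str) -> FoldResult:
    """Exact optimum of the built-in pair-weighted model."""
    codes = encode(sequence)
    E = _nussinov_fill(codes, MIN_HAIRPIN_LOOP)
    structure = _traceback(codes, E, MIN_HAIRPIN_LOOP)
    return FoldResult(structure=structure, mfe=float(E[0, codes.size - 1]))


def _vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True


def fold_vienna(sequence: str) -> FoldResult:
    """Nearest-neighbor MFE plus ensemble descriptors via ViennaRNA."""
    import RNA

    fc = RNA.fold_compound(sequence)
    structure, mfe = fc.mfe()
    fc.exp_params_rescale(mfe)
    _, ensemble_mfe = fc.pf()
    diversity = fc.mean_bp_distance()
    frequency = fc.pr_structure(structure)
    return FoldResult(
        structure=structure,
        mfe=float(mfe),
        ensemble_mfe=float(ensemble_mfe),
        diversity=float(diversity),
        ensemble_frequency=float(frequency),
    )


Engine = Union[str, Callable[[str], FoldResult]]

_ENGINES = {"fallback": fold_fallback, "nussinov": fold_fallback, "vienna": fold_vienna}


def get_engine(engine: Engine = "fallback") -> Callable[[str], FoldResult]:
    """Resolve an engine handle ("fallback", "vienna", or a callable)."""
    if callable(engine):
        return engine
    try:
        return _ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown folding engine {engine!r}") from None


def fold_mfe(sequence: str, engine: Engine = "fallback") -> FoldResult:
    """Fold an RNA sequence with the selected engine.

    Raises ``ValueError`` for sequences shorter than 10 nt or containing
    characters outside {A,C,G,U,N}.
    """
    seq = sequence.upper()
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"RNA sequence contains invalid characters: {sorted(bad)}")
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} < 10 nt)")
    return get_engine(engine)(seq)
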