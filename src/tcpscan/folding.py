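"""Local mRNA folding-energy backends.

The scanning analyses only need a deterministic map from a 30-nt window to a
minimum-free-energy-like score (kcal/mol, <= 0; more negative = stronger
folding).  Three interchangeable backends satisfy that contract:

``NussinovBackend``
    Base-pair maximization (Nussinov dynamic program) with -1 kcal/mol per
    Watson-Crick or GU pair and a minimum hairpin loop of 3 nt.  Fast,
    dependency-free, and monotone in pairing potential, which is all the
    rank-based analyses downstream consume.
``ViennaBackend``
    Shells out to the ``RNAfold`` executable (batch mode) for true
    thermodynamic MFEs when the ViennaRNA suite is on PATH.
``ConstantBackend`` / ``GCProxyBackend``
    Degenerate backends for tests and closed-form checks.
"""

from __future__ import annotations

import shutil
import subprocess
from functools import lru_cache
from typing import Iterable, Protocol

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# allowed pairs by integer code: AU/UA, GC/CG, GU/UG
_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _i, _j in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _PAIR[_i, _j] = True


class FoldingBackend(Protocol):
    """Contract: deterministic ``mfe(seq) -> float <= 0`` for short windows."""

    def mfe(self, seq: str) -> float: ...


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string (DNA or RNA alphabet) to integer codes 0..3.

    Ambiguous characters map to -1 and can never pair.
    """
    return np.array([_BASE_CODE.get(c, -1) for c in seq.upper()], dtype=np.int8)


@njit(cache=False)
def _nussinov_pairs(codes, pair_ok, min_loop):  # pragma: no cover - jitted
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            ci = codes[i]
            cj = codes[j]
            if ci >= 0 and cj >= 0 and pair_ok[ci, cj]:
                v = dp[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp[0, n - 1]


class NussinovBackend:
    """Pair-maximization folding proxy: energy = -pair_energy per base pair."""

    def __init__(self, pair_energy: float = 1.0, min_loop: int = 3):
        self.pair_energy = float(pair_energy)
        self.min_loop = int(min_loop)
        self._cache: dict[str, float] = {}

    def mfe(self, seq: str) -> float:
        s = seq.upper().replace("U", "T")
        hit = self._cache.get(s)
        if hit is not None:
            return hit
        if len(s) <= self.min_loop + 1:
            val = 0.0
        else:
            npairs = int(_nussinov_pairs(encode(s), _PAIR, self.min_loop))
            val = -self.pair_energy * npairs
        self._cache[s] = val
        return val


class ConstantBackend:
    """Returns the same energy for every window (0 by default)."""

    def __init__(self, value: float = 0.0):
        if value > 0:
            raise ValueError("MFE must be <= 0")
        self.value = float(value)

    def mfe(self, seq: str) -> float:
        return self.value


class GCProxyBackend:
    """mfe(s) = -scale * (#G + #C); a transparent stub for enumeration tests."""

    def __init__(self, scale: float = 0.1):
        self.scale = float(scale)

    def mfe(self, seq: str) -> float:
        s = seq.upper()
        return -self.scale * (s.count("G") + s.count("C"))


class ViennaBackend:
    """Thermodynamic MFE via the RNAfold executable (ViennaRNA suite).

    Sequences are folded in batches through one subprocess call; results are
    memoized.  Raises ``RuntimeError`` at construction when RNAfold is not on
    PATH.
    """

    def __init__(self, executable: str = "RNAfold"):
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable} not found on PATH")
        self.executable = executable
        self._cache: dict[str, float] = {}

    def _fold_batch(self, seqs: list[str]) -> None:
        inp = "\n".join(seqs) + "\n"
        out = subprocess.run(
            [self.executable, "--noPS"],
            input=inp,
            capture_output=True,
            text=True,
            check=True,
        ).stdout.splitlines()
        # output alternates: sequence line, then "structure (energy)"
        energies = []
        for line in out:
            line = line.strip()
            if line.endswith(")") and "(" in line:
                val = line[line.rfind("(") + 1 : -1].strip()
                energies.append(float(val))
        if len(energies) != len(seqs):
            raise RuntimeError("unexpected RNAfold output")
        for s, e in zip(seqs, energies):
            self._cache[s] = min(e, 0.0)

    def mfe_many(self, seqs: Iterable[str]) -> list[float]:
        seqs = [s.upper().replace("T", "U") for s in seqs]
        missing = sorted({s for s in seqs if s not in self._cache})
        if missing:
            self._fold_batch(missing)
        return [self._cache[s] for s in seqs]

    def mfe(self, seq: str) -> float:
        return self.mfe_many([seq])[0]


@lru_cache(maxsize=1)
def default_backend() -> NussinovBackend:
    """The package-wide default folding proxy."""
    return NussinovBackend()
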