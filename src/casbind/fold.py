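"""RNA folding backends for the spacer-unfolding penalty dG_U.

The energy layer only needs an object with an ``mfe(seq) -> float`` method.
:class:`ViennaBackend` wraps the ViennaRNA python bindings when they are
installed; :class:`NussinovBackend` is a dependency-free stand-in that folds
with nearest-neighbour stack energies and a per-loop penalty — adequate for
deterministic desk-scale work, not a substitute for a full thermodynamic
folder.  :class:`TableBackend` serves tests.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Mapping, Protocol

__all__ = ["FoldBackend", "ViennaBackend", "NussinovBackend", "TableBackend",
           "default_backend"]

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


class FoldBackend(Protocol):
    def mfe(self, seq: str) -> float: ...


class ViennaBackend:
    """ViennaRNA MFE; raises at construction if the bindings are missing."""

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "ViennaRNA python bindings not installed; `pip install ViennaRNA` "
                "or use casbind.fold.NussinovBackend()"
            ) from exc
        self._rna = RNA

    def mfe(self, seq: str) -> float:
        _, e = self._rna.fold(seq.upper().replace("T", "U"))
        return float(e)


class NussinovBackend:
    """Simple stacking-energy folding (min loop 3, no dangles, no multiloop terms).

    Recurrence over intervals scoring -1 * stack bonus for helix extension and
    a fixed penalty for opening a loop; returns 0 for structureless input.
    """

    STACK = -1.6  # kcal/mol per stacked pair, crude average
    LOOP_OPEN = 3.5
    MIN_LOOP = 3

    def mfe(self, seq: str) -> float:
        s = seq.upper().replace("T", "U")
        n = len(s)

        @lru_cache(maxsize=None)
        def best(i: int, j: int, stacked: bool) -> float:
            if j - i <= self.MIN_LOOP:
                return 0.0
            options = [best(i + 1, j, False), best(i, j - 1, False)]
            if (s[i], s[j]) in _PAIRS:
                inner = best(i + 1, j - 1, True)
                pair_e = self.STACK if stacked else self.STACK + self.LOOP_OPEN
                options.append(pair_e + inner)
            for k in range(i + 1, j):
                options.append(best(i, k, False) + best(k + 1, j, False))
            return min(options)

        value = best(0, n - 1, False) if n > 1 else 0.0
        best.cache_clear()
        return min(0.0, value)


class TableBackend:
    """Fixed lookup; unknown sequences fold to 0.0."""

    def __init__(self, table: Mapping[str, float]):
        self._table = {k.upper().replace("T", "U"): float(v) for k, v in table.items()}

    def mfe(self, seq: str) -> float:
        return self._table.get(seq.upper().replace("T", "U"), 0.0)


def default_backend() -> FoldBackend:
    """ViennaRNA when available, otherwise the built-in approximation."""
    try:
        return ViennaBackend()
    except RuntimeError:
        return NussinovBackend()
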