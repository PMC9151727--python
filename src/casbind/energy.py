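"""gRNA-DNA interaction geometry and binding free energy changes.

The composite binding free energy change is

    dG_B = delta_PAM * (dG_H - dG_U - dG_O)

where dG_H is the positionally weighted RNA-DNA hybridisation energy of the
PAM-anchored alignment, dG_O the DNA-DNA opening penalty over the engaged
target stretch and dG_U the spacer self-folding minimum free energy.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .params import EnergyParameterSet

log = logging.getLogger(__name__)

__all__ = [
    "ColumnKind",
    "AlignmentColumn",
    "HybridAlignment",
    "Spacer",
    "TargetWindow",
    "EnergyBreakdown",
    "AlignmentError",
    "build_full_alignment",
    "delta_g_h",
    "delta_g_o",
    "delta_g_u",
    "delta_g_b",
    "align_bulged",
    "find_optimal_interaction",
    "enumerate_deletion_variants",
    "rna_complement_of_dna",
    "dna_step_key",
]

_RNA_OF_DNA = {"A": "A", "C": "C", "G": "G", "T": "U", "N": "N"}
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_PAIR_OF_RNA = {"A": "T", "C": "G", "G": "C", "U": "A"}  # DNA partner of an RNA base

MAX_FRAGMENT = 24  # longest DNA stretch upstream of the PAM ever considered


class AlignmentError(ValueError):
    pass


class ColumnKind(str, Enum):
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    RNA_BULGE = "RNA_BULGE"
    DNA_BULGE = "DNA_BULGE"


@dataclass(frozen=True)
class Spacer:
    """A gRNA spacer, 5'->3', RNA alphabet."""

    seq: str
    id: str = ""

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("T", "U")
        object.__setattr__(self, "seq", seq)
        if len(seq) < 2:
            raise AlignmentError(f"spacer {self.id!r} shorter than 2 nt")
        bad = set(seq) - set("ACGU")
        if bad:
            raise AlignmentError(f"spacer {self.id!r} has invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TargetWindow:
    """Protospacer-side (PAM strand) DNA context around one PAM.

    ``pam_offset`` indexes the first base of the 4-nt PAM context
    (N-1 G G N+1 for the canonical case) within ``protospacer_side``.
    """

    protospacer_side: str
    pam_offset: int
    coordinates: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        seq = self.protospacer_side.upper()
        object.__setattr__(self, "protospacer_side", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise AlignmentError(f"target has invalid bases {sorted(bad)}")
        if self.pam_offset < 2:
            raise AlignmentError("pam_offset must be >= 2 (need >= 2 nt upstream of PAM)")
        if self.pam_offset > len(seq):
            raise AlignmentError("pam_offset outside the target string")

    @property
    def upstream(self) -> str:
        """DNA 5' of the PAM on the PAM strand (ends PAM-proximal)."""
        return self.protospacer_side[: self.pam_offset]

    @property
    def pam_context(self) -> str:
        return self.protospacer_side[self.pam_offset : self.pam_offset + 4]

    @property
    def pam(self) -> str:
        """The 3-nt PAM (N-1 plus the binding dinucleotide)."""
        return self.protospacer_side[self.pam_offset : self.pam_offset + 3]

    @classmethod
    def from_30mer(cls, mer30: str, **kw) -> "TargetWindow":
        """Standard 30-mer layout: 4 nt context, 20 nt protospacer, 3 nt PAM, 3 nt."""
        if len(mer30) != 30:
            raise AlignmentError(f"expected a 30-mer, got {len(mer30)} nt")
        return cls(mer30, 24, **kw)


@dataclass(frozen=True)
class AlignmentColumn:
    kind: ColumnKind
    rna_base: str  # "-" for DNA_BULGE columns
    dna_base: str  # base on the strand paired with the gRNA; "-" for RNA_BULGE

    def __post_init__(self) -> None:
        if self.kind is ColumnKind.RNA_BULGE and self.dna_base != "-":
            raise AlignmentError("RNA_BULGE column must have a gap DNA base")
        if self.kind is ColumnKind.DNA_BULGE and self.rna_base != "-":
            raise AlignmentError("DNA_BULGE column must have a gap RNA base")
        if self.kind is ColumnKind.MATCH and _PAIR_OF_RNA.get(self.rna_base) != self.dna_base:
            raise AlignmentError(
                f"MATCH column r{self.rna_base}:d{self.dna_base} is not Watson-Crick"
            )

    def key_token(self) -> str:
        return f"r{self.rna_base}:d{self.dna_base}"


@dataclass(frozen=True)
class HybridAlignment:
    """Ordered columns, PAM-distal -> PAM-proximal."""

    columns: tuple[AlignmentColumn, ...]
    anchored_at_pam: bool = True
    source: str = "custom"  # on_target | sliding_up | sliding_down | custom

    def __post_init__(self) -> None:
        if not self.columns:
            raise AlignmentError("empty alignment")
        for a, b in zip(self.columns, self.columns[1:]):
            if a.kind in (ColumnKind.RNA_BULGE, ColumnKind.DNA_BULGE) and b.kind in (
                ColumnKind.RNA_BULGE,
                ColumnKind.DNA_BULGE,
            ):
                raise AlignmentError("adjacent bulge columns are not allowed")

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def n_mismatches(self) -> int:
        return sum(1 for c in self.columns if c.kind is ColumnKind.MISMATCH)

    @property
    def n_bulges(self) -> int:
        return sum(
            1 for c in self.columns if c.kind in (ColumnKind.RNA_BULGE, ColumnKind.DNA_BULGE)
        )

    @property
    def engaged_dna_length(self) -> int:
        """Number of target nucleotides covered by non-RNA-bulge columns."""
        return sum(1 for c in self.columns if c.kind is not ColumnKind.RNA_BULGE)

    def cigar(self) -> str:
        """Compact per-column string: M/X/I/D (I = RNA bulge, D = DNA bulge)."""
        code = {
            ColumnKind.MATCH: "M",
            ColumnKind.MISMATCH: "X",
            ColumnKind.RNA_BULGE: "I",
            ColumnKind.DNA_BULGE: "D",
        }
        return "".join(code[c.kind] for c in self.columns)


@dataclass(frozen=True)
class EnergyBreakdown:
    dg_h: float
    dg_o: float
    dg_u: float
    delta_pam: float

    @property
    def dg_b(self) -> float:
        return self.delta_pam * (self.dg_h - self.dg_u - self.dg_o)


def _pair_column(rna_base: str, protospacer_base: str) -> AlignmentColumn:
    dna = _DNA_COMP[protospacer_base]
    if protospacer_base != "N" and _PAIR_OF_RNA[rna_base] == dna:
        return AlignmentColumn(ColumnKind.MATCH, rna_base, dna)
    return AlignmentColumn(ColumnKind.MISMATCH, rna_base, dna)


def build_full_alignment(spacer: Spacer, target: TargetWindow) -> HybridAlignment:
    """Ungapped PAM-anchored alignment, one column per spacer position."""
    upstream = target.upstream
    if len(upstream) < len(spacer):
        raise AlignmentError(
            f"target provides {len(upstream)} nt upstream of the PAM; "
            f"spacer needs {len(spacer)}"
        )
    window = upstream[-len(spacer) :]
    cols = tuple(_pair_column(r, d) for r, d in zip(spacer.seq, window))
    return HybridAlignment(cols, anchored_at_pam=True, source="on_target")


def _step_energy(
    a: AlignmentColumn, b: AlignmentColumn, params: EnergyParameterSet
) -> float:
    key = f"{a.key_token()}|{b.key_token()}"
    value = params.rna_dna.get(key)
    if value is not None:
        return value
    # averaging fallback over the homoduplex tables, mirroring the bulge fill
    r_key = key.replace("d", "r").replace("T", "U")
    d_key = "|".join(
        f"d{c.rna_base.replace('U', 'T')}:d{c.dna_base}" for c in (a, b)
    )
    r_val = params.rna_rna.get(r_key)
    d_val = params.dna_dna.get(d_key)
    if r_val is not None and d_val is not None:
        log.debug("step %s resolved by rna_rna/dna_dna averaging", key)
        return (r_val + d_val) / 2.0
    if params.strict_steps:
        raise AlignmentError(f"no stacking energy for step {key!r}")
    log.debug("step %s has no table entry; scored 0.0", key)
    return 0.0


def delta_g_h(alignment: HybridAlignment, params: EnergyParameterSet) -> float:
    """Positionally weighted hybridisation free energy change (kcal/mol).

    Steps are indexed from the PAM-proximal end: the PAM-adjacent step always
    carries weight 19, and indices count down moving PAM-distal, clamped at 1
    for alignments with more than 19 steps.
    """
    cols = alignment.columns
    n_steps = len(cols) - 1
    total = 0.0
    for i in range(n_steps):
        steps_from_proximal = n_steps - 1 - i
        idx = max(1, 19 - steps_from_proximal)
        total += params.weights[idx] * _step_energy(cols[i], cols[i + 1], params)
    return total


def dna_step_key(a: str, b: str) -> str:
    """dna_dna table key for the duplex step 5'-ab-3' (top strand)."""
    return f"d{a}:d{_DNA_COMP[a]}|d{b}:d{_DNA_COMP[b]}"


def delta_g_o(
    target: TargetWindow,
    engaged_span: tuple[int, int],
    params: EnergyParameterSet,
) -> float:
    """DNA-DNA opening free energy over ``engaged_span`` (0-based half-open).

    Unweighted sum of dna_dna nearest-neighbour steps; spans shorter than two
    nucleotides have no stacking step and cost nothing.
    """
    lo, hi = engaged_span
    if lo < 0 or hi > len(target.protospacer_side) or lo > hi:
        raise IndexError(f"span {engaged_span} outside target of length "
                         f"{len(target.protospacer_side)}")
    stretch = target.protospacer_side[lo:hi]
    total = 0.0
    for a, b in zip(stretch, stretch[1:]):
        if "N" in (a, b):
            continue
        total += params.dna_dna[dna_step_key(a, b)]
    return total


def delta_g_u(spacer: Spacer, fold_backend) -> float:
    """Spacer self-folding MFE, passed through from the folding backend."""
    if fold_backend is None:
        raise RuntimeError(
            "no folding backend configured; install ViennaRNA python bindings "
            "or pass casbind.fold.NussinovBackend()/a custom backend"
        )
    return float(fold_backend.mfe(spacer.seq))


def delta_g_b(dg_h: float, dg_u: float, dg_o: float, delta_pam: float) -> float:
    for v in (dg_h, dg_u, dg_o, delta_pam):
        if not math.isfinite(v):
            raise ValueError("energy inputs must be finite")
    return delta_pam * (dg_h - dg_u - dg_o)


def _candidate_alignments(
    spacer: Spacer,
    fragment: str,
    max_bulges: int,
    fixed_bulge: tuple[ColumnKind, int] | None = None,
    full_query: bool = True,
) -> Iterable[tuple[AlignmentColumn, ...]]:
    """All PAM-proximal-anchored column layouts for ``fragment`` vs the spacer.

    The fragment's 3' end abuts the PAM.  With ``full_query`` every spacer
    base must be engaged; otherwise the spacer is engaged from its own 3' end
    and 5' spacer bases may be left out for short fragments.  With
    ``max_bulges``=1 the layouts are: no bulge, one DNA bulge at any of the
    fragment positions, or one RNA bulge at any engaged spacer position.
    """
    m, n = len(spacer), len(fragment)
    rna = spacer.seq

    def pair_cols(rna_part: str, dna_part: str) -> tuple[AlignmentColumn, ...]:
        return tuple(_pair_column(r, d) for r, d in zip(rna_part, dna_part))

    # 0 bulges: engage the last n spacer bases
    if n <= m and not (full_query and n != m):
        yield pair_cols(rna[m - n :], fragment)
    if max_bulges < 1:
        return
    # 1 DNA bulge: n fragment bases, n-1 paired spacer bases
    if n - 1 <= m and n >= 2 and not (full_query and n - 1 != m):
        rna_part = rna[m - (n - 1) :]
        for bulge_at in range(n):  # fragment index carrying the bulge
            if fixed_bulge is not None and fixed_bulge != (ColumnKind.DNA_BULGE, bulge_at):
                continue
            cols = []
            ri = 0
            for di, d in enumerate(fragment):
                if di == bulge_at:
                    cols.append(AlignmentColumn(ColumnKind.DNA_BULGE, "-", _DNA_COMP[d]))
                else:
                    cols.append(_pair_column(rna_part[ri], d))
                    ri += 1
            yield tuple(cols)
    # 1 RNA bulge: n fragment bases, n+1 engaged spacer bases
    if n + 1 <= m and not (full_query and n + 1 != m):
        rna_part = rna[m - (n + 1) :]
        for bulge_at in range(n + 1):  # engaged-spacer index carrying the bulge
            if fixed_bulge is not None and fixed_bulge != (ColumnKind.RNA_BULGE, bulge_at):
                continue
            cols = []
            di = 0
            for ri, r in enumerate(rna_part):
                if ri == bulge_at:
                    cols.append(AlignmentColumn(ColumnKind.RNA_BULGE, r, "-"))
                else:
                    cols.append(_pair_column(r, fragment[di]))
                    di += 1
            yield tuple(cols)


def align_bulged(
    spacer: Spacer,
    fragment: str,
    params: EnergyParameterSet,
    *,
    max_bulges: int = 1,
    source: str = "custom",
    fixed_bulge: tuple[ColumnKind, int] | None = None,
    full_query: bool = True,
) -> HybridAlignment:
    """Minimum weighted-dG_H alignment of the spacer onto a PAM-proximal fragment.

    With the default ``full_query`` every spacer base takes part; the length
    difference between fragment and spacer must then be coverable by bulges.
    """
    fragment = fragment.upper()
    diff = len(fragment) - len(spacer)
    if diff > max_bulges or (full_query and -diff > max_bulges):
        raise AlignmentError(
            f"fragment of {len(fragment)} nt cannot be aligned to a "
            f"{len(spacer)}-nt spacer with <= {max_bulges} bulge(s)"
        )
    best = None
    best_e = math.inf
    for cols in _candidate_alignments(spacer, fragment, max_bulges, fixed_bulge,
                                      full_query):
        aln = HybridAlignment(cols, anchored_at_pam=True, source=source)
        e = delta_g_h(aln, params)
        if e < best_e:
            best, best_e = aln, e
    if best is None:
        raise AlignmentError("no feasible alignment under the given constraints")
    return best


def find_optimal_interaction(
    spacer: Spacer,
    target: TargetWindow,
    params: EnergyParameterSet,
    *,
    dg_u: float = 0.0,
    max_fragment: int = MAX_FRAGMENT,
) -> tuple[HybridAlignment, EnergyBreakdown]:
    """Best-dG_B interaction over candidate fragment lengths ending at the PAM.

    Candidate fragments run from min(``max_fragment``, available context) nt
    down to 2 nt upstream of the PAM, each aligned with :func:`align_bulged`;
    dG_O is recomputed over each candidate's engaged span and the candidate
    with the lowest dG_B wins (ties: longer fragment).
    """
    upstream = target.upstream
    if len(upstream) < 2:
        raise AlignmentError("need >= 2 nt of context upstream of the PAM")
    delta_pam = params.delta_pam(target.pam)
    best = None
    for length in range(min(max_fragment, len(upstream)), 1, -1):
        fragment = upstream[-length:]
        if len(fragment) - len(spacer) > 1:
            continue
        aln = align_bulged(spacer, fragment, params, source="on_target",
                           full_query=False)
        span = (target.pam_offset - length, target.pam_offset)
        breakdown = EnergyBreakdown(
            dg_h=delta_g_h(aln, params),
            dg_o=delta_g_o(target, span, params),
            dg_u=dg_u,
            delta_pam=delta_pam,
        )
        if best is None or breakdown.dg_b < best[1].dg_b:
            best = (aln, breakdown)
    assert best is not None
    return best


def enumerate_deletion_variants(spacer: Spacer) -> list[Spacer]:
    """All single-base deletion variants, labelled by the deleted position (1-based)."""
    label = spacer.id or "spacer"
    return [
        Spacer(spacer.seq[:i] + spacer.seq[i + 1 :], id=f"{label}_del{i + 1}")
        for i in range(len(spacer))
    ]


def rna_complement_of_dna(protospacer: str) -> str:
    """Spacer sequence that matches a protospacer perfectly (same sense, T->U)."""
    return protospacer.upper().replace("T", "U")
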