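"""Desk-scale off-target enumeration over FASTA genomes.

Semantics follow a mismatch-only search ending at a PAM: every position on
either strand whose adjacent 3-nt PAM matches one of the configured patterns
and whose protospacer carries at most ``max_mismatches`` differences to the
spacer is reported.  Windows containing N are skipped; soft-masked bases are
uppercased.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .energy import (
    Spacer,
    TargetWindow,
    build_full_alignment,
    delta_g_h,
    delta_g_o,
)
from .params import EnergyParameterSet
from .sliding import SlidingError, pattern_matches

__all__ = ["OffTargetHit", "scan_offtargets", "resolve_competing_pams", "read_fasta"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class OffTargetHit:
    contig: str
    start: int  # 0-based, protospacer only
    end: int  # half-open
    strand: str  # "+" | "-"
    protospacer: str  # PAM-strand sequence, 5'->3'
    pam_context: str  # 4-mer N-1 X X N+1 (padded with N at contig edges)
    mismatches: int
    dg_b: float = float("nan")

    @property
    def pam(self) -> str:
        return self.pam_context[:3]

    def overlaps(self, other: "OffTargetHit") -> bool:
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _validate_patterns(patterns: Iterable[str]) -> list[str]:
    pats = []
    for p in patterns:
        p = p.upper()
        if len(p) != 3:
            raise SlidingError(f"PAM pattern must be 3 nt, got {p!r}")
        pattern_matches(p, "AAA")  # raises on invalid symbols
        pats.append(p)
    if not pats:
        raise SlidingError("at least one PAM pattern is required")
    return pats


def _mismatches(spacer_seq: str, protospacer: str) -> int:
    return sum(1 for r, d in zip(spacer_seq, protospacer) if r != d.replace("T", "U"))


def _hit_energy(
    spacer: Spacer, window: str, pam_offset: int, params: EnergyParameterSet, dg_u: float
) -> float:
    target = TargetWindow(window, pam_offset)
    aln = build_full_alignment(spacer, target)
    dg_h = delta_g_h(aln, params)
    dg_o = delta_g_o(target, (pam_offset - len(spacer), pam_offset), params)
    delta_pam = params.delta_pam(target.pam)
    return delta_pam * (dg_h - dg_u - dg_o)


def scan_offtargets(
    spacer: Spacer,
    genome: Mapping[str, str] | str | Path,
    params: EnergyParameterSet,
    *,
    max_mismatches: int = 6,
    pam_patterns: Iterable[str] = ("NGG",),
    dg_u: float = 0.0,
) -> list[OffTargetHit]:
    """Enumerate candidate binding sites for ``spacer`` on both strands."""
    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    patterns = _validate_patterns(pam_patterns)
    m = len(spacer)
    hits: list[OffTargetHit] = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else _revcomp(seq)
            for i in range(0, L - m - 2):
                proto = s[i : i + m]
                pam = s[i + m : i + m + 3]
                if "N" in proto or "N" in pam:
                    continue
                if not any(pattern_matches(p, pam) for p in patterns):
                    continue
                mm = _mismatches(spacer.seq, proto)
                if mm > max_mismatches:
                    continue
                context = s[i + m : i + m + 4]
                if len(context) < 4:
                    context = context + "N" * (4 - len(context))
                if strand == "+":
                    start = i
                else:
                    start = L - (i + m)
                window = s[max(0, i - 4) : i + m + 4]
                dg_b = _hit_energy(
                    spacer, window, i + m - max(0, i - 4), params, dg_u
                )
                hits.append(
                    OffTargetHit(
                        contig=contig,
                        start=start,
                        end=start + m,
                        strand=strand,
                        protospacer=proto,
                        pam_context=context,
                        mismatches=mm,
                        dg_b=dg_b,
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def resolve_competing_pams(hits: list[OffTargetHit]) -> list[OffTargetHit]:
    """Collapse overlapping same-strand hits, keeping the lowest-dG_B PAM.

    Ties go to the smallest start coordinate, then to the '+' strand.
    """
    remaining = sorted(hits, key=lambda h: (h.dg_b, h.start, 0 if h.strand == "+" else 1))
    kept: list[OffTargetHit] = []
    for hit in remaining:
        if any(hit.overlaps(k) for k in kept):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.contig, h.start, h.strand))
    return kept
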