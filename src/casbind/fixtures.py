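"""Deterministic synthetic inputs with known ground truth, plus the
brute-force oracles used to cross-check the production algorithms.

Everything is driven by a single seeded ``numpy`` generator captured in a
:class:`FixtureSpec`; identical specs produce byte-identical outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .energy import (
    AlignmentColumn,
    ColumnKind,
    HybridAlignment,
    Spacer,
    TargetWindow,
)
from .params import EnergyParameterSet

__all__ = [
    "FixtureSpec",
    "PlantedSite",
    "make_toy_genome",
    "simulate_efficiency_dataset",
    "brute_force_alignment_oracle",
    "brute_force_interaction_oracle",
    "brute_force_scan_oracle",
    "oracle_weighted_dg_h",
    "random_spacer",
    "random_dna",
]

_DNA = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PlantedSite:
    spacer: str  # RNA, the guide the site belongs to
    mismatches: int
    strand: str
    pam_context: str  # 4-mer, middle dinucleotide GG for canonical plants


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    genome_length: int = 2000
    planted_sites: tuple[PlantedSite, ...] = ()
    efficiency_model: tuple[float, float, float, float] = (10.0, 5.0, -0.5, 0.0)
    # (alpha1 slope on score, beta1 on |up dev|, gamma1 on |down dev|, noise sd)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_DNA), size=length))


def random_spacer(rng: np.random.Generator, length: int = 20, label: str = "g") -> Spacer:
    return Spacer(random_dna(rng, length).replace("T", "U"), id=label)


def make_toy_genome(
    spec: FixtureSpec, *, out_fasta: Optional[Path] = None, out_truth: Optional[Path] = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with planted protospacer+PAM sites at recorded coordinates."""
    rng = np.random.default_rng(spec.seed)
    seq = list(random_dna(rng, spec.genome_length))
    rows = []
    cursor = 10
    for idx, site in enumerate(spec.planted_sites):
        proto = list(site.spacer.replace("U", "T"))
        mm_pos = rng.choice(len(proto), size=site.mismatches, replace=False)
        for p in mm_pos:
            proto[p] = rng.choice([b for b in _DNA if b != proto[p]])
        insert = "".join(proto) + site.pam_context
        if cursor + len(insert) + 10 > spec.genome_length:
            raise ValueError("planted sites do not fit in genome_length without overlap")
        if site.strand == "+":
            start = cursor
            seq[cursor : cursor + len(insert)] = insert
        else:
            start = spec.genome_length - (cursor + len(proto))
            rc = _revcomp(insert)
            seq[cursor : cursor + len(rc)] = rc
            # rc occupies [cursor, cursor+len); protospacer plus-coords:
            start = cursor + 4  # 4-mer context sits first after revcomp
        rows.append(
            {
                "site": idx,
                "contig": "toy",
                "start": start,
                "strand": site.strand,
                "protospacer": "".join(proto),
                "pam_context": site.pam_context,
                "mismatches": site.mismatches,
            }
        )
        cursor += len(insert) + 15
    genome = {"toy": "".join(seq)}
    truth = pd.DataFrame(rows)
    if out_fasta:
        Path(out_fasta).write_text(
            f">toy seed={spec.seed}\n" + "\n".join(
                genome["toy"][i : i + 70] for i in range(0, len(genome["toy"]), 70)
            ) + "\n"
        )
    if out_truth:
        truth.to_csv(out_truth, sep="\t", index=False)
    return genome, truth


def simulate_efficiency_dataset(
    spec: FixtureSpec,
    n: int,
    *,
    alpha0: float = 10.0,
    beta0: float = 4.0,
    gamma0: float = -3.0,
) -> pd.DataFrame:
    """Efficiency records whose response follows the sliding-extended linear form.

    Scores and sliding energies are drawn from seeded distributions; the
    response is alpha0 + alpha1*score (+ sliding addends on flagged rows) plus
    Gaussian noise.  PAM contexts are drawn consistently with the flags.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    alpha1, beta1, gamma1, sigma = spec.efficiency_model
    rng = np.random.default_rng(spec.seed)
    score = rng.uniform(2.0, 12.0, size=n)
    up = rng.random(n) < 0.25
    down = rng.random(n) < 0.25
    dg_up = np.where(up, rng.normal(-25.0, 4.0, size=n), np.nan)
    dg_down = np.where(down, rng.normal(-30.0, 4.0, size=n), np.nan)
    m_up = float(np.median(dg_up[up])) if up.any() else math.nan
    m_down = float(np.median(dg_down[down])) if down.any() else math.nan
    y = alpha0 + alpha1 * score
    if up.any():
        y = y + np.where(up, beta0 + beta1 * np.abs(dg_up - m_up), 0.0)
    if down.any():
        y = y + np.where(down, gamma0 + gamma1 * np.abs(dg_down - m_down), 0.0)
    y = y + rng.normal(0.0, sigma, size=n)

    h = np.array(list("ACT"))
    n1 = np.where(up, "G", rng.choice(h, size=n))
    n2 = np.where(down, "G", rng.choice(h, size=n))
    contexts = [f"{a}GG{b}" for a, b in zip(n1, n2)]
    return pd.DataFrame(
        {
            "gRNA_id": [f"sim{i:05d}" for i in range(n)],
            "pam_context": contexts,
            "crisprspec": score,
            "dg_b_up": dg_up,
            "dg_b_down": dg_down,
            "sliding_up": up,
            "sliding_down": down,
            "indel_frequency": y,
        }
    )


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _oracle_step_energy(a: AlignmentColumn, b: AlignmentColumn,
                        params: EnergyParameterSet) -> float:
    """Independent table lookup (duplicates the production fallback chain)."""
    key = f"r{a.rna_base}:d{a.dna_base}|r{b.rna_base}:d{b.dna_base}"
    if key in params.rna_dna:
        return params.rna_dna[key]
    rr = key.replace("d", "r").replace("T", "U")
    dd = (f"d{a.rna_base}:d{a.dna_base}|d{b.rna_base}:d{b.dna_base}").replace("U", "T")
    if rr in params.rna_rna and dd in params.dna_dna:
        return (params.rna_rna[rr] + params.dna_dna[dd]) / 2.0
    return 0.0


def oracle_weighted_dg_h(columns: Sequence[AlignmentColumn],
                         params: EnergyParameterSet) -> float:
    steps = len(columns) - 1
    total = 0.0
    for i in range(steps):
        idx = max(1, 19 - (steps - 1 - i))
        total += params.weights[idx] * _oracle_step_energy(columns[i], columns[i + 1], params)
    return total


def _oracle_columns(spacer: str, fragment: str, full_query: bool = True):
    """Recursive enumeration of <=1-bulge PAM-anchored column layouts.

    Walks backwards from the PAM-proximal ends of both sequences, consuming a
    spacer and a fragment base per pair column, one bulge allowed anywhere;
    all fragment bases must be consumed.  ``full_query`` additionally requires
    every spacer base to be engaged (no 5' spacer overhang).
    """
    pair_of = {"A": "T", "C": "G", "G": "C", "U": "A"}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def rec(ri: int, di: int, bulges_left: int, last_was_bulge: bool):
        if di == 0:
            if ri == 0 or not full_query:
                yield []
            if ri > 0 and bulges_left and not last_was_bulge:
                # terminal (distal) RNA bulge
                r = spacer[ri - 1]
                for rest in rec(ri - 1, 0, bulges_left - 1, True):
                    yield rest + [AlignmentColumn(ColumnKind.RNA_BULGE, r, "-")]
            return
        d = fragment[di - 1]
        if ri > 0:
            r = spacer[ri - 1]
            dna = comp[d]
            kind = ColumnKind.MATCH if pair_of.get(r) == dna and d != "N" else ColumnKind.MISMATCH
            col = AlignmentColumn(kind, r, dna)
            for rest in rec(ri - 1, di - 1, bulges_left, False):
                yield rest + [col]
        if bulges_left and not last_was_bulge:
            for rest in rec(ri, di - 1, bulges_left - 1, True):
                yield rest + [AlignmentColumn(ColumnKind.DNA_BULGE, "-", comp[d])]
            if ri > 0:
                r = spacer[ri - 1]
                for rest in rec(ri - 1, di, bulges_left - 1, True):
                    yield rest + [AlignmentColumn(ColumnKind.RNA_BULGE, r, "-")]

    for cols in rec(len(spacer), len(fragment), 1, False):
        if cols:
            yield cols


def brute_force_alignment_oracle(
    spacer: Spacer,
    fragment: str,
    params: EnergyParameterSet,
) -> tuple[float, HybridAlignment]:
    """Minimum weighted-dG_H over every <=1-bulge PAM-anchored alignment."""
    best_e, best_cols = math.inf, None
    for cols in _oracle_columns(spacer.seq, fragment.upper()):
        e = oracle_weighted_dg_h(cols, params)
        if e < best_e:
            best_e, best_cols = e, cols
    if best_cols is None:
        raise ValueError("no feasible alignment")
    return best_e, HybridAlignment(tuple(best_cols), anchored_at_pam=True)


def brute_force_interaction_oracle(
    spacer: Spacer,
    target: TargetWindow,
    params: EnergyParameterSet,
    *,
    dg_u: float = 0.0,
    max_fragment: int = 24,
) -> float:
    """Minimum dG_B over all fragment lengths 2..24 and <=1-bulge alignments."""
    from .energy import delta_g_o  # deferred to keep module load light

    upstream = target.upstream
    delta_pam = params.delta_pam(target.pam)
    best = math.inf
    for length in range(2, min(max_fragment, len(upstream)) + 1):
        fragment = upstream[-length:]
        for cols in _oracle_columns(spacer.seq, fragment, full_query=False):
            dg_h = oracle_weighted_dg_h(cols, params)
            dg_o = delta_g_o(target, (target.pam_offset - length, target.pam_offset), params)
            best = min(best, delta_pam * (dg_h - dg_u - dg_o))
    return best


def brute_force_scan_oracle(
    spacer: Spacer,
    genome: dict[str, str],
    *,
    max_mismatches: int = 6,
    pam_patterns: Sequence[str] = ("NGG",),
) -> list[tuple[str, int, str, int]]:
    """Position-by-position rescan; returns (contig, start, strand, mismatches)."""
    from .sliding import pattern_matches

    m = len(spacer)
    out = []
    for contig, seq in genome.items():
        seq = seq.upper()
        for start in range(len(seq) - m + 1):
            for strand in "+-":
                if strand == "+":
                    proto = seq[start : start + m]
                    pam = seq[start + m : start + m + 3]
                else:
                    proto = _revcomp(seq[start : start + m])
                    pam = _revcomp(seq[start - 3 : start]) if start >= 3 else ""
                if len(pam) < 3 or "N" in proto or "N" in pam:
                    continue
                if not any(pattern_matches(p, pam) for p in pam_patterns):
                    continue
                mm = sum(
                    1 for r, d in zip(spacer.seq, proto) if r != d.replace("T", "U")
                )
                if mm <= max_mismatches:
                    out.append((contig, start, strand, mm))
    return sorted(out)
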