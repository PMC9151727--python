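"""Local sliding PAM detection and bulged-binding evaluation.

A 4-nt PAM context 5'-N-1 X X N+1-3' carries the binding dinucleotide in the
middle.  For a canonical GG motif, a guanine at N-1 opens an upstream sliding
PAM (Cas9 anchors 1 nt upstream; the gRNA bulges its PAM-proximal base) and a
guanine at N+1 a downstream one (the gRNA stays fully paired with a DNA bulge
between hybrid and PAM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .energy import (
    AlignmentColumn,
    AlignmentError,
    ColumnKind,
    EnergyBreakdown,
    HybridAlignment,
    Spacer,
    TargetWindow,
    align_bulged,
    delta_g_h,
    delta_g_o,
)
from .params import EnergyParameterSet

__all__ = [
    "PamContext",
    "SlidingAnnotation",
    "SlidingError",
    "pattern_matches",
    "detect_sliding_pams",
    "detect_noncanonical_sliding",
    "evaluate_sliding_binding",
    "classify_pam_context",
    "annotate_target",
]

_H = set("ACT")
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "N": "ACGT", "H": "ACT", "B": "CGT", "D": "AGT", "V": "ACG",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}


class SlidingError(ValueError):
    pass


def pattern_matches(pattern: str, seq: str) -> bool:
    """IUPAC wildcard match (H = A/C/T, N = any); False on length mismatch."""
    if len(pattern) != len(seq):
        return False
    try:
        return all(s in _IUPAC[p] for p, s in zip(pattern.upper(), seq.upper()))
    except KeyError as exc:
        raise SlidingError(f"invalid pattern symbol {exc.args[0]!r} in {pattern!r}") from exc


@dataclass(frozen=True)
class PamContext:
    """The 4-mer 5'-N-1 X X N+1-3' around the binding motif."""

    n_minus1: str
    g1: str
    g2: str
    n_plus1: str

    def __post_init__(self) -> None:
        for b in (self.n_minus1, self.g1, self.g2, self.n_plus1):
            if b not in "ACGT":
                raise SlidingError(f"invalid PAM context base {b!r}")

    @classmethod
    def from_string(cls, context4: str) -> "PamContext":
        context4 = context4.upper()
        if len(context4) != 4:
            raise SlidingError(f"PAM context must be 4 nt, got {context4!r}")
        return cls(*context4)

    @property
    def binding_motif(self) -> str:
        return self.g1 + self.g2

    def __str__(self) -> str:
        return self.n_minus1 + self.g1 + self.g2 + self.n_plus1


@dataclass(frozen=True)
class SlidingAnnotation:
    upstream: bool
    downstream: bool
    dg_b_up: Optional[float] = None
    dg_b_down: Optional[float] = None
    extended_stretch_up: int = 0
    extended_stretch_down: int = 0

    @property
    def condition(self) -> str:
        if self.upstream and self.downstream:
            return "up_and_down"
        if self.upstream:
            return "upstream"
        if self.downstream:
            return "downstream"
        return "none"


def detect_sliding_pams(context: PamContext) -> SlidingAnnotation:
    """Presence of +/-1-nt sliding PAMs for a canonical GG binding motif."""
    if context.binding_motif != "GG":
        raise SlidingError(
            f"binding motif {context.binding_motif!r} is non-canonical; "
            "use detect_noncanonical_sliding"
        )
    return SlidingAnnotation(
        upstream=context.n_minus1 == "G",
        downstream=context.n_plus1 == "G",
    )


_NONCANONICAL_PROFILES = {
    # profile -> list of (direction, shift_nt, 4-mer pattern)
    "SpCas9": [
        ("upstream", 1, "GGNN"),
        ("downstream", 1, "NNGG"),
    ],
    "NG": [
        ("upstream", 1, "GHHH"),
        ("downstream", 1, "HHGH"),
        ("downstream", 2, "HHHG"),
    ],
}


def detect_noncanonical_sliding(
    context: PamContext, variant_profile: str = "SpCas9"
) -> list[tuple[str, int, str]]:
    """Sliding opportunities at non-canonical binding motifs.

    Returns (direction, shift in nt, slid binding motif) tuples.  The SpCas9
    profile looks for a canonical GG reachable 1 nt away; the NG-variant
    profile (SpCas9-NG, xCas9) for a lone G at -1 (upstream) or at +1/+2
    (downstream, 1 or 2 nt).
    """
    try:
        rules = _NONCANONICAL_PROFILES[variant_profile]
    except KeyError:
        raise SlidingError(
            f"unknown variant profile {variant_profile!r}; "
            f"known: {sorted(_NONCANONICAL_PROFILES)}"
        ) from None
    s = str(context)
    hits = []
    for direction, shift, pattern in rules:
        if not pattern_matches(pattern, s):
            continue
        if variant_profile == "SpCas9":
            if context.binding_motif == "GG":
                continue  # canonical rows dispatch to detect_sliding_pams
            motif = "GG"
        else:
            motif = s[0] if direction == "upstream" else s[1 + shift]
        hits.append((direction, shift, motif))
    return hits


def classify_pam_context(context: PamContext) -> str:
    """Label like ``G-1GGH+1``: motif flanked by G/H class symbols."""
    up = "G" if context.n_minus1 == "G" else "H"
    down = "G" if context.n_plus1 == "G" else "H"
    return f"{up}-1{context.binding_motif}{down}+1"


def evaluate_sliding_binding(
    spacer: Spacer,
    target: TargetWindow,
    direction: str,
    params: EnergyParameterSet,
    *,
    dg_u: float = 0.0,
) -> tuple[HybridAlignment, EnergyBreakdown]:
    """Energy breakdown of the bulged binding anchored at a +/-1-nt slid PAM.

    Upstream: the PAM-proximal spacer base is an RNA bulge and the remaining
    spacer pairs with the len(spacer)-1 nt upstream of it.  Downstream: the
    spacer stays fully paired and the on-target PAM's first base becomes a DNA
    bulge between hybrid and slid PAM.
    """
    context = PamContext.from_string(target.pam_context)
    ann = detect_sliding_pams(context)
    m = len(spacer)
    if direction in ("up", "upstream"):
        if not ann.upstream:
            raise SlidingError(f"no upstream sliding PAM in context {context}")
        fragment = target.upstream[-(m - 1) :]
        if len(fragment) < m - 1:
            raise AlignmentError("insufficient upstream context for sliding evaluation")
        aln = align_bulged(
            spacer,
            fragment,
            params,
            source="sliding_up",
            fixed_bulge=(ColumnKind.RNA_BULGE, m - 1),
        )
        span = (target.pam_offset - (m - 1), target.pam_offset)
        slid_pam = target.upstream[-1] + context.n_minus1 + context.g1
    elif direction in ("down", "downstream"):
        if not ann.downstream:
            raise SlidingError(f"no downstream sliding PAM in context {context}")
        if len(target.upstream) < m:
            raise AlignmentError("insufficient upstream context for sliding evaluation")
        fragment = target.upstream[-m:] + context.n_minus1
        aln = align_bulged(
            spacer,
            fragment,
            params,
            source="sliding_down",
            fixed_bulge=(ColumnKind.DNA_BULGE, m),
        )
        span = (target.pam_offset - m, target.pam_offset + 1)
        slid_pam = context.g1 + context.g2 + context.n_plus1
    else:
        raise SlidingError(f"direction must be 'up' or 'down', got {direction!r}")
    breakdown = EnergyBreakdown(
        dg_h=delta_g_h(aln, params),
        dg_o=delta_g_o(target, span, params),
        dg_u=dg_u,
        delta_pam=params.delta_pam(slid_pam),
    )
    return aln, breakdown


def _g_run(seq: str, reverse: bool = False) -> int:
    it = reversed(seq) if reverse else iter(seq)
    n = 0
    for b in it:
        if b != "G":
            break
        n += 1
    return n


def annotate_target(
    spacer: Spacer,
    target: TargetWindow,
    params: EnergyParameterSet,
    *,
    dg_u: float = 0.0,
) -> SlidingAnnotation:
    """Full sliding annotation (flags, energies, reported G-run lengths)."""
    context = PamContext.from_string(target.pam_context)
    ann = detect_sliding_pams(context)
    dg_up = dg_down = None
    if ann.upstream:
        dg_up = evaluate_sliding_binding(spacer, target, "up", params, dg_u=dg_u)[1].dg_b
    if ann.downstream:
        dg_down = evaluate_sliding_binding(spacer, target, "down", params, dg_u=dg_u)[1].dg_b
    tail = target.protospacer_side[target.pam_offset + 4 :]
    return SlidingAnnotation(
        upstream=ann.upstream,
        downstream=ann.downstream,
        dg_b_up=dg_up,
        dg_b_down=dg_down,
        extended_stretch_up=_g_run(target.upstream + context.n_minus1, reverse=True),
        extended_stretch_down=_g_run(context.n_plus1 + tail),
    )
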