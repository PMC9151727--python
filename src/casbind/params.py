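"""Thermodynamic parameter tables and positional weights.

The packaged default (``data/nn_params_v1.json``) carries Watson-Crick
nearest-neighbour stacking free energies for the three duplex types
(RNA-DNA hybrid, DNA-DNA, RNA-RNA) plus single-nucleotide bulge steps for
the DNA-DNA and RNA-RNA tables.  RNA-DNA bulge steps are not tabulated in
the hybrid literature and are completed at load time by averaging the two
homoduplex counterparts (:func:`fill_missing_bulge_steps`).

Step keys are strings of two alignment columns joined by ``|``; each column
is ``<strand-prefixed top base>:<strand-prefixed bottom base>``, read 5'->3'
on the top (RNA or reference) strand.  ``-`` marks a bulged-out position,
e.g. ``"rA:dT|rG:dC"`` (stack of two hybrid pairs) or ``"rA:d-|rG:dC"``
(DNA bulge next to an rG:dC pair).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "ParameterError",
    "StackingTable",
    "PositionalWeights",
    "EnergyParameterSet",
    "load_parameter_set",
    "save_parameter_set",
    "default_parameter_set",
    "fill_missing_bulge_steps",
    "DEFAULT_RT",
]

#: kcal/(mol K) x 310.15 K -- Boltzmann scale at 37 C.
DEFAULT_RT = 1.9872e-3 * 310.15

_N_WEIGHTS = 19
_RNA = set("ACGU")
_DNA = set("ACGT")


class ParameterError(ValueError):
    """Raised when a parameter file is missing entries or malformed."""


def _column_bases(token: str) -> list[tuple[str, str]]:
    out = []
    for part in token.split(":"):
        if len(part) != 2 or part[0] not in "rd":
            raise ParameterError(f"malformed column token {token!r}")
        out.append((part[0], part[1]))
    return out


@dataclass(frozen=True)
class StackingTable:
    """Map from a two-column stacking step key to energy in kcal/mol."""

    duplex: str  # "rna_dna" | "dna_dna" | "rna_rna"
    entries: Mapping[str, float]

    _ALPHABETS = {
        "rna_dna": {"r": _RNA, "d": _DNA},
        "dna_dna": {"d": _DNA},
        "rna_rna": {"r": _RNA},
    }

    def __post_init__(self) -> None:
        allowed = self._ALPHABETS.get(self.duplex)
        if allowed is None:
            raise ParameterError(f"unknown duplex type {self.duplex!r}")
        for key, value in self.entries.items():
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ParameterError(f"non-finite energy for step {key!r}")
            cols = key.split("|")
            if len(cols) != 2:
                raise ParameterError(f"malformed step key {key!r}")
            for col in cols:
                for strand, base in _column_bases(col):
                    if strand not in allowed:
                        raise ParameterError(
                            f"strand prefix {strand!r} not valid in {self.duplex} key {key!r}"
                        )
                    if base != "-" and base not in allowed[strand]:
                        raise ParameterError(
                            f"base {base!r} not valid in {self.duplex} key {key!r}"
                        )

    def __getitem__(self, key: str) -> float:
        return self.entries[key]

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def get(self, key: str, default: float | None = None) -> float | None:
        return self.entries.get(key, default)

    def match_step_count(self) -> int:
        """Number of stacking steps whose four bases are all non-gap."""
        return sum(1 for k in self.entries if "-" not in k)


@dataclass(frozen=True)
class PositionalWeights:
    """19 dimensionless multipliers; index 19 is the PAM-proximal-most step."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.w) != _N_WEIGHTS:
            missing = len(self.w) + 1
            raise ParameterError(
                f"weights must have exactly {_N_WEIGHTS} values; "
                f"weights[{missing}] missing" if len(self.w) < _N_WEIGHTS
                else f"weights must have exactly {_N_WEIGHTS} values"
            )
        for i, v in enumerate(self.w, start=1):
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"weights[{i}] must be finite and >= 0, got {v!r}")

    def __getitem__(self, one_based: int) -> float:
        if not 1 <= one_based <= _N_WEIGHTS:
            raise IndexError(one_based)
        return self.w[one_based - 1]

    def __len__(self) -> int:
        return _N_WEIGHTS


@dataclass(frozen=True)
class EnergyParameterSet:
    rna_dna: StackingTable
    dna_dna: StackingTable
    rna_rna: StackingTable
    weights: PositionalWeights
    pam_factor: Mapping[str, float]
    rt: float = DEFAULT_RT
    version: str = "unversioned"
    weights_version: str = "unversioned"
    strict_steps: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ParameterError(f"rt must be > 0, got {self.rt}")
        if self.pam_factor.get("NGG") != 1.0:
            raise ParameterError("pam_factor must contain the canonical pattern NGG with factor 1")

    def delta_pam(self, pam: str) -> float:
        """PAM compatibility factor for a 3-nt PAM; unlisted patterns score 0."""
        from .sliding import pattern_matches  # local import avoids a cycle

        for pattern, factor in self.pam_factor.items():
            if pattern_matches(pattern, pam):
                return float(factor)
        return 0.0


def _table_from_json(duplex: str, raw: object) -> StackingTable:
    if not isinstance(raw, dict):
        raise ParameterError(f"section {duplex!r} must be an object of step->energy")
    entries = {}
    for key, value in raw.items():
        try:
            entries[str(key)] = float(value)
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"malformed numeric for {duplex} step {key!r}: {value!r}") from exc
    return StackingTable(duplex, entries)


def load_parameter_set(path: str | Path, *, fill_bulges: bool = True) -> EnergyParameterSet:
    """Load and validate a parameter file; refuses files without a version tag."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParameterError(f"cannot parse {path}: {exc}") from exc
    for section in ("rna_dna", "dna_dna", "rna_rna", "weights", "pam_factor"):
        if section not in raw:
            raise ParameterError(f"parameter file {path} lacks required section {section!r}")
    if not raw.get("version"):
        raise ParameterError(f"parameter file {path} is unversioned; refusing to load")
    weights = PositionalWeights(tuple(float(v) for v in raw["weights"]))
    params = EnergyParameterSet(
        rna_dna=_table_from_json("rna_dna", raw["rna_dna"]),
        dna_dna=_table_from_json("dna_dna", raw["dna_dna"]),
        rna_rna=_table_from_json("rna_rna", raw["rna_rna"]),
        weights=weights,
        pam_factor={str(k): float(v) for k, v in raw["pam_factor"].items()},
        rt=float(raw.get("rt", DEFAULT_RT)),
        version=str(raw["version"]),
        weights_version=str(raw.get("weights_version", "unversioned")),
    )
    return fill_missing_bulge_steps(params) if fill_bulges else params


def save_parameter_set(params: EnergyParameterSet, path: str | Path) -> None:
    payload = {
        "version": params.version,
        "weights_version": params.weights_version,
        "rt": params.rt,
        "weights": list(params.weights.w),
        "pam_factor": dict(params.pam_factor),
        "rna_dna": dict(params.rna_dna.entries),
        "dna_dna": dict(params.dna_dna.entries),
        "rna_rna": dict(params.rna_rna.entries),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def default_parameter_set() -> EnergyParameterSet:
    """The packaged versioned parameter set, bulge-completed."""
    with resources.as_file(resources.files("casbind") / "data" / "nn_params_v1.json") as p:
        return load_parameter_set(p)


def fill_missing_bulge_steps(params: EnergyParameterSet) -> EnergyParameterSet:
    """Complete the RNA-DNA table's bulge steps from the two homoduplex tables.

    Every bulge-containing step key derivable from the rna_rna/dna_dna tables
    and absent from rna_dna is added with the arithmetic mean of the two
    counterpart energies.  Existing entries are never overwritten, which makes
    the operation idempotent.
    """
    new_entries = dict(params.rna_dna.entries)
    # enumerate candidate rna_dna bulge keys from the dna_dna bulge entries
    for d_key in params.dna_dna.entries:
        if "-" not in d_key:
            continue
        r_key_cols = []
        hybrid_cols = []
        ok = True
        for col in d_key.split("|"):
            top, bottom = col.split(":")
            tb, bb = top[1], bottom[1]
            r_top = tb.replace("T", "U")
            r_bot = bb.replace("T", "U")
            r_key_cols.append(f"r{r_top}:r{r_bot}")
            hybrid_cols.append(f"r{r_top}:d{bb}")
            if tb == "-" and bb == "-":
                ok = False
        if not ok:
            continue
        hybrid_key = "|".join(hybrid_cols)
        if hybrid_key in new_entries:
            continue
        r_key = "|".join(r_key_cols)
        if r_key not in params.rna_rna:
            raise ParameterError(
                f"cannot fill {hybrid_key!r}: rna_rna counterpart {r_key!r} missing"
            )
        new_entries[hybrid_key] = (params.rna_rna[r_key] + params.dna_dna[d_key]) / 2.0
    return replace(params, rna_dna=StackingTable("rna_dna", new_entries))
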