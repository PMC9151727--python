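"""Recomputation of published summary statistics from their source tables.

The quantities here are defined over two external inputs that cannot be
redistributed with the package:

* ``crisproff_parameters.json`` — a parameter file in this package's format
  transcribed from the CRISPRoff pipeline distribution (fitted 19-weight
  array and full stacking tables).  The packaged default tables carry
  uniform weights and are NOT a substitute when reproducing published
  energy values.
* ``supplementary_data3.tsv`` — the 4-guide HEK293T PAM-context efficiency
  table (columns: gRNA_id, pam_context, treatment, indel_frequency, and
  optionally day/barcode columns that still need averaging).
* ``lin2014_guides.tsv`` — guide sequences of the single-deletion bulge
  dataset (columns: id, spacer, gc_percent).

Each function degrades loudly: a missing input raises ``FileNotFoundError``
with the provenance of what is needed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .energy import Spacer, TargetWindow, build_full_alignment, delta_g_h
from .params import EnergyParameterSet, load_parameter_set
from .stats import average_replicates, context_effect_summary, sliding_condition_summary

__all__ = [
    "external_path",
    "load_crisproff_parameters",
    "load_supplementary_data3",
    "load_lin2014_guides",
    "weighted_hybridisation_energy",
    "supp3_target_statistics",
]

#: repo-level directory where users drop the transcribed external tables
EXTERNAL_DIR = Path(__file__).resolve().parents[2] / "data" / "external"


def external_path(name: str) -> Path:
    import os

    base = Path(os.environ.get("CASBIND_EXTERNAL_DIR", EXTERNAL_DIR))
    path = base / name
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: this quantity is defined over external source "
            "data that is not redistributable with the package; transcribe the "
            "table documented in data/external/README.md and re-run"
        )
    return path


def load_crisproff_parameters() -> EnergyParameterSet:
    return load_parameter_set(external_path("crisproff_parameters.json"))


def load_supplementary_data3() -> pd.DataFrame:
    df = pd.read_csv(external_path("supplementary_data3.tsv"), sep="\t", comment="#")
    required = {"gRNA_id", "pam_context", "treatment", "indel_frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"supplementary_data3.tsv lacks columns {sorted(missing)}")
    if "barcode" in df.columns:
        if "day" not in df.columns:
            df = df.assign(day="pooled")
        df = average_replicates(df)
    return df


def load_lin2014_guides() -> pd.DataFrame:
    df = pd.read_csv(external_path("lin2014_guides.tsv"), sep="\t", comment="#")
    if not {"id", "spacer"} <= set(df.columns):
        raise ValueError("lin2014_guides.tsv needs 'id' and 'spacer' columns")
    return df


def weighted_hybridisation_energy(spacer_seq: str, params: EnergyParameterSet) -> float:
    """dG_H of the fully complementary PAM-anchored interaction of one spacer."""
    spacer = Spacer(spacer_seq)
    proto = spacer.seq.replace("U", "T")
    window = TargetWindow(proto + "AGGA", len(proto))
    return delta_g_h(build_full_alignment(spacer, window), params)


def _motif(context: str) -> str:
    return context[1:3]


def supp3_target_statistics(df: pd.DataFrame) -> dict[str, tuple[float, int]]:
    """The PAM-context dataset summaries, on the percent scale they are printed.

    Keys: explained variance by sliding condition per guide (ADRA2C, PAX5,
    CHRNB2; Dox- GG motif), pooled Dox-/Dox+ motif means, and the relative
    change of the G-1GGH+1 / H-1GGG+1 context means against H-1GGH+1.
    Values are (statistic, number of records it was computed over).
    """
    dox_minus = df[df["treatment"] == "Dox-"]
    dox_plus = df[df["treatment"] == "Dox+"]
    gg_minus = dox_minus[dox_minus["pam_context"].map(_motif) == "GG"]
    out: dict[str, tuple[float, int]] = {}
    for key, gid in (("t1", "ADRA2C"), ("t2", "PAX5"), ("t3", "CHRNB2")):
        sub = gg_minus[gg_minus["gRNA_id"] == gid]
        if not sub.empty:
            out[key] = (100.0 * sliding_condition_summary(sub).explained, len(sub))
    if not gg_minus.empty:
        out["t4"] = (float(gg_minus["indel_frequency"].mean()), len(gg_minus))
        up_none = gg_minus[gg_minus["pam_context"].str[3] != "G"]
        out["t7"] = (context_effect_summary(gg_minus, "GGGH", "HGGH"), len(up_none))
        down_none = gg_minus[gg_minus["pam_context"].str[0] != "G"]
        out["t8"] = (-context_effect_summary(gg_minus, "HGGG", "HGGH"), len(down_none))
    ag_minus = dox_minus[dox_minus["pam_context"].map(_motif) == "AG"]
    if not ag_minus.empty:
        out["t5"] = (float(ag_minus["indel_frequency"].mean()), len(ag_minus))
    gg_plus = dox_plus[dox_plus["pam_context"].map(_motif) == "GG"]
    if not gg_plus.empty:
        out["t6"] = (float(gg_plus["indel_frequency"].mean()), len(gg_plus))
    return out
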