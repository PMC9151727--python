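"""TSV/FASTA readers and writers plus reproducible output headers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__

__all__ = ["RunConfig", "read_batch_tsv", "read_efficiency_tsv", "write_tsv"]


@dataclass
class RunConfig:
    """Run-level configuration echoed into every output header."""

    parameter_set: Optional[str] = None
    rt: Optional[float] = None
    pam_patterns: tuple[str, ...] = ("NGG",)
    max_mismatches: int = 6
    fold_backend: str = "auto"
    percent_mode: str = "relative"
    output_dir: str = "."
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "RunConfig":
        data = json.loads(payload)
        data["pam_patterns"] = tuple(data.get("pam_patterns", ("NGG",)))
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def header_lines(config: RunConfig, parameter_version: str = "n/a") -> list[str]:
    return [
        f"# casbind {__version__}",
        f"# parameter_set {parameter_version}",
        f"# config {config.digest()}",
        f"# seed {config.seed}",
    ]


def write_tsv(df: pd.DataFrame, path: str | Path, config: RunConfig,
              parameter_version: str = "n/a") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines(config, parameter_version):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_batch_tsv(path: str | Path) -> pd.DataFrame:
    """Batch input: id, spacer and either target_30mer or contig/start/end/strand."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "spacer" not in df.columns or "id" not in df.columns:
        raise ValueError(f"{path}: batch TSV needs 'id' and 'spacer' columns, "
                         f"got {list(df.columns)}")
    return df


def read_efficiency_tsv(path: str | Path) -> pd.DataFrame:
    """Efficiency table with at least gRNA_id, pam_context and indel_frequency."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gRNA_id", "pam_context", "indel_frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: efficiency TSV lacks columns {sorted(missing)}")
    return df
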