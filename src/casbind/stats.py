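"""Dataset procedures: indel frequencies, replicate handling, filters,
splits, sweet-spot intervals, logo matrices, GUIDE-seq filtering and the
sliding-condition variance decomposition.

Efficiency tables are plain TSVs with the documented column schema (see
:data:`EFFICIENCY_COLUMNS`); every filter returns both the survivors and a
removal ledger so the provenance of dropped records stays inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sliding import PamContext, detect_sliding_pams, pattern_matches

__all__ = [
    "EFFICIENCY_COLUMNS",
    "SlidingConditionSummary",
    "indel_frequency",
    "select_min_read_threshold",
    "average_replicates",
    "apply_preprocessing_filters",
    "scaffold_structure_filter",
    "similarity_aware_split",
    "efficiency_split",
    "sweet_spot_interval",
    "logo_frequencies",
    "guideseq_filter",
    "sliding_condition_summary",
    "context_effect_summary",
    "pam_pattern_group_stats",
]

EFFICIENCY_COLUMNS = [
    "gRNA_id", "spacer", "target_30mer", "pam_context",
    "indel_reads", "total_reads", "indel_frequency",
    "day", "treatment", "barcode",
]


def indel_frequency(indel_reads: int, total_reads: int) -> float:
    """Percentage of reads carrying indels."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if not 0 <= indel_reads <= total_reads:
        raise ValueError("need 0 <= indel_reads <= total_reads")
    return 100.0 * indel_reads / total_reads


def select_min_read_threshold(
    day6: pd.DataFrame,
    day10: pd.DataFrame,
    *,
    grid: Iterable[int] = range(0, 201, 5),
    keys: Sequence[str] = ("gRNA_id", "pam_context", "barcode"),
) -> int:
    """Read-count threshold minimising the day6-vs-day10 Spearman p value.

    For each candidate n, pairs whose total reads fall below n on either day
    are dropped before correlating the two days' indel frequencies.  Ties and
    the perfectly correlated case resolve to the smallest n.  Grid points with
    fewer than 3 surviving pairs are skipped.
    """
    merged = day6.merge(day10, on=list(keys), suffixes=("_d6", "_d10"))
    if merged.empty:
        raise ValueError("no paired records between the two days")
    best_n, best_p = None, math.inf
    for n in grid:
        ok = (merged["total_reads_d6"] >= n) & (merged["total_reads_d10"] >= n)
        sub = merged[ok]
        if len(sub) < 3:
            continue
        rho, p = sps.spearmanr(sub["indel_frequency_d6"], sub["indel_frequency_d10"])
        if math.isnan(p):
            continue
        if p < best_p:
            best_n, best_p = n, p
    if best_n is None:
        raise ValueError("no grid point left >= 3 surviving pairs")
    return best_n


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Average day replicates, then barcode replicates.

    Day 6/10 frequencies are averaged per (gRNA, pam_context, treatment,
    barcode) first; the resulting barcode replicates are then averaged per
    (gRNA, pam_context, treatment), reporting the normalised standard
    deviation (population std / mean) across barcodes.
    """
    by_day = (
        records.groupby(["gRNA_id", "pam_context", "treatment", "barcode"], sort=False)
        ["indel_frequency"].mean().reset_index()
    )

    def _norm_sd(x: pd.Series) -> float:
        mu = x.mean()
        if mu == 0:
            return 0.0
        return float(x.std(ddof=0) / mu)

    out = (
        by_day.groupby(["gRNA_id", "pam_context", "treatment"], sort=False)
        .agg(
            indel_frequency=("indel_frequency", "mean"),
            normalised_sd=("indel_frequency", _norm_sd),
            n_barcodes=("indel_frequency", "size"),
        )
        .reset_index()
    )
    return out


def apply_preprocessing_filters(
    records: pd.DataFrame,
    spec_scores: Optional[pd.DataFrame] = None,
    *,
    min_spec: Optional[float] = 5.0,
    min_indel: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strict-inequality removal of low-specificity and low-efficiency guides.

    Returns (survivors, removal ledger with a ``reason`` column).  The
    specificity filter only applies when ``spec_scores`` (gRNA_id, crisprspec)
    is given and ``min_spec`` is not None.
    """
    df = records.copy()
    reasons = pd.Series("", index=df.index)
    if spec_scores is not None and min_spec is not None:
        spec = df.merge(spec_scores, on="gRNA_id", how="left")["crisprspec"].to_numpy()
        low = np.isfinite(spec) & (spec < min_spec)
        reasons[low] = "low_specificity"
    low_eff = (df["indel_frequency"] < min_indel) & (reasons == "")
    reasons[low_eff] = "low_efficiency"
    removed = df[reasons != ""].assign(reason=reasons[reasons != ""])
    return df[reasons == ""].copy(), removed


def scaffold_structure_filter(
    unpaired_distance: pd.Series,
    *,
    mode: str = "quantile",
    cutoff: float = 3.41,
    quantile: float = 0.95,
) -> tuple[pd.Index, pd.Index]:
    """Split sgRNAs into (kept, removed) by distance to the optimal scaffold fold.

    ``unpaired_distance`` holds, per sgRNA, the Euclidean distance between the
    observed probability of being unpaired and 1 over the positions unpaired
    in the optimal scaffold structure (see :func:`structure_distances`).  Mode
    ``quantile`` removes the top (1-quantile) fraction; ``threshold`` removes
    strictly greater than ``cutoff``.
    """
    if mode == "quantile":
        cut = float(unpaired_distance.quantile(quantile))
        removed = unpaired_distance[unpaired_distance > cut].index
    elif mode == "threshold":
        removed = unpaired_distance[unpaired_distance > cutoff].index
    else:
        raise ValueError(f"mode must be 'quantile' or 'threshold', got {mode!r}")
    kept = unpaired_distance.index.difference(removed, sort=False)
    return kept, removed


def structure_distances(
    pair_probs: np.ndarray, optimal_pairs: set[tuple[int, int]]
) -> tuple[float, float]:
    """(paired, unpaired) Euclidean distances of one sgRNA to the optimal fold.

    ``pair_probs`` is the symmetric base-pair probability matrix of the folded
    sgRNA.  Positions paired in the optimal structure contribute deviations of
    their pair probability from 1; positions unpaired in the optimal structure
    contribute deviations of (1 - sum of pairing probabilities) from 1.
    """
    n = pair_probs.shape[0]
    in_pair = {i for ij in optimal_pairs for i in ij}
    paired_sq = sum((1.0 - pair_probs[i, j]) ** 2 for i, j in optimal_pairs)
    unpaired_sq = 0.0
    for i in range(n):
        if i in in_pair:
            continue
        p_unbound = 1.0 - float(pair_probs[i].sum())
        unpaired_sq += (1.0 - p_unbound) ** 2
    return math.sqrt(paired_sq), math.sqrt(unpaired_sq)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def similarity_aware_split(
    items: Sequence[str], test_fraction: float
) -> tuple[list[int], list[int]]:
    """Leakage-free index split: Hamming-<4 neighbours stay in one subset.

    Connected components under "distance <= 3" are assigned whole to the test
    side, largest first, until the requested fraction is first reached or
    exceeded.  Returns (train indices, test indices).
    """
    n = len(items)
    if n and any(len(s) != len(items[0]) for s in items):
        raise ValueError("all items must have equal length")
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _hamming(items[i], items[j]) <= 3:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    ordered = sorted(comps.values(), key=lambda c: (-len(c), c[0]))
    want = test_fraction * n
    test: list[int] = []
    for comp in ordered:
        if len(test) >= want:
            break
        test.extend(comp)
    test_set = set(test)
    train = [i for i in range(n) if i not in test_set]
    return train, sorted(test)


def efficiency_split(
    records: pd.DataFrame, fraction: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(high, low) groups of floor(fraction*n) records by indel frequency."""
    if len(records) < 5:
        raise ValueError("need >= 5 records")
    k = int(math.floor(fraction * len(records)))
    ordered = records.sort_values("indel_frequency", kind="stable", ascending=False)
    return ordered.head(k), ordered.tail(k)


def sweet_spot_interval(
    values: Sequence[float], coverage: float = 0.8
) -> tuple[float, float]:
    """Central interval trimming (1-coverage)/2 from each tail (linear percentiles).

    With heavily tied data the interpolated bounds can undershoot the
    requested coverage; the bounds are then widened to the nearest data
    values until at least the coverage fraction lies inside.
    """
    values = np.asarray(values, float)
    if values.size < 10:
        raise ValueError("need >= 10 values")
    tail = 100.0 * (1.0 - coverage) / 2.0
    lo, hi = np.percentile(values, [tail, 100.0 - tail])
    ordered = np.sort(values)
    need = coverage * values.size
    while ((ordered >= lo) & (ordered <= hi)).sum() < need:
        below = ordered[ordered < lo]
        above = ordered[ordered > hi]
        gain_lo = (below == below.max()).sum() if below.size else 0
        gain_hi = (above == above.min()).sum() if above.size else 0
        if gain_lo >= gain_hi and gain_lo:
            lo = float(below.max())
        elif gain_hi:
            hi = float(above.min())
        else:  # pragma: no cover - cannot happen while count < need
            break
    return float(lo), float(hi)


def logo_frequencies(
    foreground: Sequence[str], background: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Position x nucleotide relative-frequency matrices for the two sets."""

    def matrix(seqs: Sequence[str]) -> pd.DataFrame:
        if not seqs:
            raise ValueError("empty sequence set")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("mixed sequence lengths")
        alphabet = sorted({b for s in seqs for b in s})
        counts = pd.DataFrame(0.0, index=range(1, L + 1), columns=alphabet)
        for s in seqs:
            for pos, b in enumerate(s.upper(), start=1):
                counts.loc[pos, b] += 1
        return counts.div(counts.sum(axis=1), axis=0)

    return matrix([s.upper() for s in foreground]), matrix([s.upper() for s in background])


def guideseq_filter(
    on_target: pd.Series,
    off_targets: pd.DataFrame,
    *,
    max_mismatches: int = 3,
    seed_positions: int = 4,
    read_threshold: int = 300,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter GUIDE-seq sites and classify the survivors' activity.

    A site is removed when it has more than ``max_mismatches`` mismatches to
    the on-target protospacer, any mismatch within the ``seed_positions``
    PAM-proximal spacer positions, or any variation in the 3-nt NGG PAM.
    Survivors gain ``activity`` (low/high around ``read_threshold``) and
    ``vs_on_target`` (above/below the on-target read count) columns.
    """
    on_proto = str(on_target["protospacer"]).upper()
    on_reads = float(on_target["reads"])
    m = len(on_proto)
    rows, removed_rows = [], []
    for _, row in off_targets.iterrows():
        proto = str(row["protospacer"]).upper()
        pam = str(row["pam"]).upper()
        mism = [i for i in range(m) if proto[i] != on_proto[i]]
        reason = None
        if not pattern_matches("NGG", pam):
            reason = "pam_variation"
        elif len(mism) > max_mismatches:
            reason = "too_many_mismatches"
        elif any(i >= m - seed_positions for i in mism):
            reason = "seed_mismatch"
        if reason:
            removed_rows.append({**row, "reason": reason})
        else:
            rows.append(
                {
                    **row,
                    "mismatches": len(mism),
                    "activity": "high" if row["reads"] >= read_threshold else "low",
                    "vs_on_target": "above" if row["reads"] > on_reads else "below",
                }
            )
    retained = pd.DataFrame(rows).sort_values(
        ["protospacer", "pam"], kind="stable").reset_index(drop=True) if rows else pd.DataFrame()
    removed = pd.DataFrame(removed_rows)
    return retained, removed


@dataclass(frozen=True)
class SlidingConditionSummary:
    n: dict[str, int]
    mean: dict[str, float]
    grand_mean: float
    ssq_sliding: float
    ssq_tot: float

    @property
    def explained(self) -> float:
        """Between-condition share of the total sum of squares; NaN if SSQ_tot=0."""
        if self.ssq_tot == 0:
            return math.nan
        return self.ssq_sliding / self.ssq_tot


def sliding_condition_summary(records: pd.DataFrame) -> SlidingConditionSummary:
    """Variance decomposition of efficiency over the four sliding conditions.

    ``records`` needs ``pam_context`` (GG binding motif) and
    ``indel_frequency`` columns; each context is classified into
    upstream/downstream/up_and_down/none and the between-group sum of squares
    about the size-weighted grand mean is related to the total sum of squares.
    """
    conds = records["pam_context"].map(
        lambda c: detect_sliding_pams(PamContext.from_string(c)).condition
    )
    x = records["indel_frequency"].to_numpy(float)
    n, mean = {}, {}
    for cond in ("upstream", "downstream", "up_and_down", "none"):
        vals = x[(conds == cond).to_numpy()]
        n[cond] = int(vals.size)
        mean[cond] = float(vals.mean()) if vals.size else math.nan
    gm = float(
        sum(n[c] * mean[c] for c in n if n[c]) / sum(n.values())
    )
    ssq_sliding = float(sum(n[c] * (mean[c] - gm) ** 2 for c in n if n[c]))
    ssq_tot = float(((x - gm) ** 2).sum())
    return SlidingConditionSummary(n, mean, gm, ssq_sliding, ssq_tot)


def context_effect_summary(
    records: pd.DataFrame,
    pattern_a: str,
    pattern_ref: str,
    *,
    mode: str = "relative",
) -> float:
    """Change of mean efficiency of group A vs the reference group, percent.

    ``relative`` returns 100*(mean_a - mean_ref)/mean_ref; ``absolute``
    returns the raw difference of the two means (percentage points).
    """
    a = records[records["pam_context"].map(lambda c: pattern_matches(pattern_a, c))]
    ref = records[records["pam_context"].map(lambda c: pattern_matches(pattern_ref, c))]
    if a.empty or ref.empty:
        raise ValueError("both pattern groups must be non-empty")
    mean_a = a["indel_frequency"].mean()
    mean_ref = ref["indel_frequency"].mean()
    if mode == "absolute":
        return float(mean_a - mean_ref)
    if mode != "relative":
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    if mean_ref == 0:
        raise ValueError("reference mean is 0; relative change undefined")
    return float(100.0 * (mean_a - mean_ref) / mean_ref)


def pam_pattern_group_stats(
    records: pd.DataFrame,
    patterns: Sequence[str],
    *,
    bonferroni: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pattern (n, mean, sd) plus one-sided pairwise Welch t-tests.

    The alternative hypothesis is that the first pattern of each pair has the
    larger mean; p values are multiplied by ``bonferroni`` and clipped at 1.
    Pairs with a group below two members are flagged and skipped.
    """
    groups = {}
    for pat in patterns:
        sel = records[records["pam_context"].map(lambda c: pattern_matches(pat, c))]
        groups[pat] = sel["indel_frequency"].to_numpy(float)
    summary = pd.DataFrame(
        {
            "pattern": list(groups),
            "n": [g.size for g in groups.values()],
            "mean": [g.mean() if g.size else math.nan for g in groups.values()],
            "sd": [g.std(ddof=1) if g.size > 1 else math.nan for g in groups.values()],
        }
    )
    tests = []
    pats = list(groups)
    for i, pa in enumerate(pats):
        for pb in pats[i + 1 :]:
            a, b = groups[pa], groups[pb]
            if a.size < 2 or b.size < 2:
                tests.append({"a": pa, "b": pb, "t": math.nan, "p": math.nan,
                              "skipped": True})
                continue
            t, p = sps.ttest_ind(a, b, equal_var=False, alternative="greater")
            tests.append({"a": pa, "b": pb, "t": float(t),
                          "p": min(1.0, float(p) * bonferroni), "skipped": False})
    return summary, pd.DataFrame(tests)
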