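"""Read-depth CNV allele calling from windowed coverage counts.

For each candidate CNV region, the coverage of an alternate strain is
compared against two reference strains over fixed-width (default 100
bp) windows.  An allele is called a duplication when the one-sided
Wilcoxon rank-sum P value against BOTH references is below 1e-10 AND
the alternate/reference mean-coverage ratio against both references
exceeds 1.8; a deletion analogously with direction reversed and ratio
below 0.2; anything else is reference.  The one-sided direction is
bound to the candidate class: alternate > reference for duplications,
alternate < reference for deletions.

Copy number is estimated as the median over windows of the
alternate count divided by the mean of the reference counts, on a
haploid baseline of 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import ParameterError

log = logging.getLogger(__name__)

P_THRESH = 1e-10
DUP_RATIO = 1.8
DEL_RATIO = 0.2
EXACT_MAX_N = 30  # exact rank-sum enumeration below this per-sample size


@dataclass
class CoverageMatrix:
    """Read counts in fixed-width genomic windows, one column per strain.

    ``windows`` is a DataFrame with columns (chrom, start, end), 0-based
    half-open as in the on-disk TSV; ``counts`` is a windows x strains
    DataFrame of non-negative read counts aligned row-for-row.
    """

    windows: pd.DataFrame
    counts: pd.DataFrame
    window_width: int = 100

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.counts):
            raise ParameterError("windows and counts row counts differ")
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("negative read counts")

    @property
    def strains(self) -> list:
        return list(self.counts.columns)

    def region_counts(self, chrom: str, start1: int, end1: int) -> pd.DataFrame:
        """Counts for windows lying fully inside the 1-based inclusive span.

        Windows overlapping the region boundary are excluded.
        """
        w = self.windows
        mask = (
            (w["chrom"] == chrom)
            & (w["start"] >= start1 - 1)
            & (w["end"] <= end1)
        )
        return self.counts.loc[mask.to_numpy()]

    @classmethod
    def from_tsv(cls, path, window_width: int = 100) -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t")
        if not {"chrom", "start", "end"} <= set(df.columns):
            raise ParameterError(f"{path}: expected chrom/start/end columns")
        windows = df[["chrom", "start", "end"]]
        counts = df.drop(columns=["chrom", "start", "end"])
        return cls(windows=windows, counts=counts, window_width=window_width)

    def to_tsv(self, path) -> None:
        pd.concat([self.windows, self.counts], axis=1).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class AlleleCall:
    """Per-strain, per-region CNV genotype with its supporting evidence."""

    strain: str
    region: tuple
    call: Optional[str]  # "REF" | "DUP" | "DEL" | None when uncallable
    p_ref1: float = float("nan")
    p_ref2: float = float("nan")
    ratio_ref1: float = float("nan")
    ratio_ref2: float = float("nan")
    copy_number: float = float("nan")
    notes: str = ""

    @property
    def callable(self) -> bool:
        return self.call is not None


def rank_sum_one_sided(x, y, direction: str = "greater", method: str = "auto") -> float:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) P value.

    ``direction='greater'`` tests the alternative that x is
    stochastically greater than y.  With ``method='auto'``, exact
    enumeration is used for small tie-free samples (both below 30
    observations) and the normal approximation with tie and continuity
    correction otherwise; 'exact'/'asymptotic' force one path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("rank-sum requires non-empty samples")
    if direction not in ("greater", "less"):
        raise ParameterError(f"bad direction {direction!r}")
    if method == "auto":
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        if max(x.size, y.size) < EXACT_MAX_N and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
    elif method not in ("exact", "asymptotic"):
        raise ParameterError(f"bad method {method!r}")
    res = stats.mannwhitneyu(x, y, alternative=direction, method=method)
    return float(res.pvalue)


def copy_number_estimate(alt_counts, ref_counts) -> float:
    """Median over windows of alt / mean(refs), haploid baseline 1.

    ``ref_counts`` is a 2-D array (windows x reference strains).
    Windows where the reference mean is zero are excluded.
    """
    alt = np.asarray(alt_counts, dtype=float)
    ref_mean = np.asarray(ref_counts, dtype=float).mean(axis=1)
    ok = ref_mean > 0
    if not ok.any():
        return float("nan")
    return float(np.median(alt[ok] / ref_mean[ok]))


def call_cnv_allele(
    region: tuple,
    alt_strain: str,
    ref1: str,
    ref2: str,
    cov: CoverageMatrix,
    p_thresh: float = P_THRESH,
    dup_ratio: float = DUP_RATIO,
    del_ratio: float = DEL_RATIO,
) -> AlleleCall:
    """Call REF/DUP/DEL for one strain over one region.

    ``region`` is (chrom, start, end), 1-based inclusive.  Both
    references must independently pass the P-value and ratio criteria
    for a non-reference call; a region with fewer than two fully
    contained windows, or zero mean reference coverage, is flagged
    uncallable (call=None).
    """
    if alt_strain in (ref1, ref2):
        raise ParameterError("alternate strain must differ from references")
    chrom, start, end = region
    counts = cov.region_counts(chrom, start, end)
    if len(counts) < 2:
        return AlleleCall(alt_strain, region, None, notes="fewer than 2 windows")
    alt = counts[alt_strain].to_numpy(dtype=float)
    refs = [counts[ref1].to_numpy(dtype=float), counts[ref2].to_numpy(dtype=float)]
    means = [r.mean() for r in refs]
    if min(means) == 0:
        return AlleleCall(alt_strain, region, None, notes="zero reference coverage")
    ratios = [alt.mean() / m for m in means]
    cn = copy_number_estimate(alt, np.column_stack(refs))

    def decide() -> tuple:
        if all(r > dup_ratio for r in ratios):
            ps = [rank_sum_one_sided(alt, r, "greater") for r in refs]
            if all(p < p_thresh for p in ps):
                return "DUP", ps
            return "REF", ps
        if all(r < del_ratio for r in ratios):
            ps = [rank_sum_one_sided(alt, r, "less") for r in refs]
            if all(p < p_thresh for p in ps):
                return "DEL", ps
            return "REF", ps
        return "REF", [float("nan")] * 2

    call, ps = decide()
    return AlleleCall(
        strain=alt_strain,
        region=region,
        call=call,
        p_ref1=ps[0],
        p_ref2=ps[1],
        ratio_ref1=ratios[0],
        ratio_ref2=ratios[1],
        copy_number=cn,
    )


def call_matrix(
    regions: list,
    strains: list,
    ref1: str,
    ref2: str,
    cov: CoverageMatrix,
    **kwargs,
) -> pd.DataFrame:
    """Allele calls for every (region, strain) pair, as a tidy DataFrame."""
    rows = []
    for region in regions:
        for s in strains:
            if s in (ref1, ref2):
                continue
            ac = call_cnv_allele(region, s, ref1, ref2, cov, **kwargs)
            rows.append(
                {
                    "chrom": region[0],
                    "start": region[1],
                    "end": region[2],
                    "strain": s,
                    "call": ac.call,
                    "p_ref1": ac.p_ref1,
                    "p_ref2": ac.p_ref2,
                    "ratio_ref1": ac.ratio_ref1,
                    "ratio_ref2": ac.ratio_ref2,
                    "copy_number": ac.copy_number,
                }
            )
    return pd.DataFrame(rows)


def segregating_in_cluster(calls: dict, cluster) -> bool:
    """True when a CNV is not fixed within a clonal cluster.

    ``calls`` maps strain -> AlleleCall for one region; only cluster
    members with callable regions are considered.  At least two
    distinct call values among them means the allele segregates.
    """
    values = {
        calls[s].call
        for s in cluster
        if s in calls and calls[s].callable
    }
    return len(values) >= 2
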