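"""Pairwise genetic distances and the correlation machinery linking them
to offspring viability.

Distances between strain pairs are counts of differing variants
(computed separately for SVs overall, rearrangements and CNVs, and
supplied externally for SNPs).  Viability relationships are tested with
Kendall rank correlation (tau-b, tie-corrected) and, because SNP and
rearrangement distances are themselves correlated, with partial Kendall
correlations that control for the other distance:

    tau_xy.z = (tau_xy - tau_xz * tau_yz) / sqrt((1 - tau_xz^2)(1 - tau_yz^2))

Linkage between an SV and SNPs is the squared Pearson correlation of
their 0/1 genotype vectors across strains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import ParameterError

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """A named correlation statistic with its P value and sample size."""

    statistic: str
    value: Optional[float]
    p_value: Optional[float]
    n: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def _reciprocal_overlap(a: tuple, b: tuple) -> float:
    """Smaller of the two overlap fractions between spans (start, end)."""
    (s1, e1), (s2, e2) = a, b
    inter = min(e1, e2) - max(s1, s2) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (e1 - s1 + 1), inter / (e2 - s2 + 1))


def merge_overlapping_cnvs(
    regions: dict, genotypes: pd.DataFrame, merge_overlap: float = 0.5
) -> pd.DataFrame:
    """Collapse CNVs with reciprocal overlap above the threshold and
    identical allele vectors to a single representative column.

    ``regions`` maps CNV id -> (chrom, start, end); ``genotypes`` has
    strains as rows and CNV ids as columns (0/1/NaN).  Both overlap
    fractions must exceed ``merge_overlap`` (reciprocal rule) and the
    genotype columns must be identical (NaN-equal) to merge.
    """
    ids = [c for c in genotypes.columns if c in regions]
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in combinations(ids, 2):
        ra, rb = regions[a], regions[b]
        if ra[0] != rb[0]:
            continue
        if _reciprocal_overlap(ra[1:3], rb[1:3]) <= merge_overlap:
            continue
        ga, gb = genotypes[a], genotypes[b]
        if ((ga == gb) | (ga.isna() & gb.isna())).all():
            ri, rj = find(a), find(b)
            if ri != rj:
                parent[rj] = ri
    keep = [i for i in ids if find(i) == i]
    keep += [c for c in genotypes.columns if c not in regions]
    dropped = genotypes.shape[1] - len(keep)
    if dropped:
        log.info("merged %d overlapping CNV columns", dropped)
    return genotypes[keep]


def sv_pair_distance(
    genotypes: pd.DataFrame,
    regions: Optional[dict] = None,
    merge_overlap: float = 0.5,
) -> pd.DataFrame:
    """Pairwise count of SVs at which two strains carry different alleles.

    ``genotypes``: strains x SVs, entries 0/1/NaN.  When ``regions`` is
    given, overlapping same-genotype CNVs are merged first.  Only SVs
    typed in both strains of a pair contribute to its count.  Returns a
    symmetric strains x strains DataFrame of integer counts.
    """
    if regions is not None:
        genotypes = merge_overlapping_cnvs(regions, genotypes, merge_overlap)
    g = genotypes.to_numpy(dtype=float)
    n = g.shape[0]
    ok = ~np.isnan(g)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        diff = ((g[i] != g[i + 1 :]) & both).sum(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return pd.DataFrame(d, index=genotypes.index, columns=genotypes.index)


def kendall_tau(x, y) -> CorrelationResult:
    """Kendall tau-b with tie correction.

    P values come from scipy (exact for small tie-free samples, normal
    approximation otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    res = stats.kendalltau(x[ok], y[ok])
    return CorrelationResult("kendall_tau_b", float(res.statistic), float(res.pvalue), int(ok.sum()))


def partial_kendall(x, y, z) -> CorrelationResult:
    """Partial Kendall correlation of x and y controlling for z.

    Uses the first-order partial formula on the three pairwise tau-b
    values, with the normal approximation
    z = 3 * tau_partial * sqrt(n(n-1) / (2(2n+5))) for a two-sided P.
    Undefined (flagged, value None) when either control correlation is
    +-1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[ok], y[ok], z[ok]
    n = x.size
    t_xy = stats.kendalltau(x, y).statistic
    t_xz = stats.kendalltau(x, z).statistic
    t_yz = stats.kendalltau(y, z).statistic
    denom = (1 - t_xz**2) * (1 - t_yz**2)
    if denom <= 1e-12:
        log.warning("partial tau undefined: a control correlation is +-1")
        return CorrelationResult("partial_kendall_tau", None, None, n)
    tau_p = (t_xy - t_xz * t_yz) / math.sqrt(denom)
    tau_p = max(-1.0, min(1.0, tau_p))
    zstat = 3.0 * tau_p * math.sqrt(n * (n - 1) / (2.0 * (2 * n + 5)))
    p = 2.0 * stats.norm.sf(abs(zstat))
    return CorrelationResult("partial_kendall_tau", float(tau_p), float(p), n)


def linkage_r2(sv_genotypes, snp_genotypes) -> float:
    """Squared Pearson correlation between two 0/1 genotype vectors over
    strains genotyped for both."""
    a = np.asarray(sv_genotypes, dtype=float)
    b = np.asarray(snp_genotypes, dtype=float)
    if a.size != b.size:
        raise ParameterError("length mismatch")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def max_linkage_scan(
    sv_genotypes: pd.DataFrame, snp_genotypes: pd.DataFrame
) -> pd.Series:
    """Maximum r-squared over all SNPs, per SV (the SV's best SNP tag)."""
    out = {}
    for sv in sv_genotypes.columns:
        best = 0.0
        for snp in snp_genotypes.columns:
            r2 = linkage_r2(sv_genotypes[sv], snp_genotypes[snp])
            if not math.isnan(r2) and r2 > best:
                best = r2
        out[sv] = best
    return pd.Series(out, name="max_r2")


def build_pair_table(
    viability: pd.DataFrame,
    snp_dist: pd.DataFrame,
    sv_dist: Optional[pd.DataFrame] = None,
    rearr_dist: Optional[pd.DataFrame] = None,
    cnv_dist: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assemble the per-cross table of distances and viability.

    ``viability`` has columns (strain_a, strain_b, viability) and
    optionally min_self_viability; the distance matrices are strain x
    strain.  Rows whose strains are absent from a distance matrix get
    NaN for that distance.
    """
    rows = []
    for _, row in viability.iterrows():
        a, b = row["strain_a"], row["strain_b"]

        def lookup(dm):
            if dm is None or a not in dm.index or b not in dm.columns:
                return float("nan")
            return float(dm.loc[a, b])

        rows.append(
            {
                "strain_a": a,
                "strain_b": b,
                "n_snp_diff": lookup(snp_dist),
                "n_sv_diff": lookup(sv_dist),
                "n_rearrangement_diff": lookup(rearr_dist),
                "n_cnv_diff": lookup(cnv_dist),
                "viability": float(row["viability"]),
                "min_self_viability": float(row.get("min_self_viability", float("nan"))),
            }
        )
    return pd.DataFrame(rows)


def isolation_analysis(pairs: pd.DataFrame) -> dict:
    """Correlations of viability with each distance, plus the two partial
    correlations (SNPs controlling rearrangements and vice versa) and a
    descriptive two-covariate OLS r-squared."""
    out: dict = {}
    v = pairs["viability"].to_numpy(dtype=float)
    for col, key in (
        ("n_sv_diff", "sv"),
        ("n_snp_diff", "snp"),
        ("n_rearrangement_diff", "rearrangement"),
        ("n_cnv_diff", "cnv"),
    ):
        if col in pairs and not pairs[col].isna().all():
            out[f"tau_{key}"] = kendall_tau(pairs[col], v)
    if {"n_snp_diff", "n_rearrangement_diff"} <= set(pairs.columns):
        snp = pairs["n_snp_diff"].to_numpy(dtype=float)
        rea = pairs["n_rearrangement_diff"].to_numpy(dtype=float)
        out["tau_snp_given_rearrangement"] = partial_kendall(snp, v, rea)
        out["tau_rearrangement_given_snp"] = partial_kendall(rea, v, snp)
        ok = ~(np.isnan(snp) | np.isnan(rea) | np.isnan(v))
        X = np.column_stack([np.ones(ok.sum()), snp[ok], rea[ok]])
        beta, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
        pred = X @ beta
        ss_res = ((v[ok] - pred) ** 2).sum()
        ss_tot = ((v[ok] - v[ok].mean()) ** 2).sum()
        out["ols_r2"] = float(1 - ss_res / ss_tot) if ss_tot > 0 else float("nan")
    return out
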