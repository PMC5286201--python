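"""Copy-number transience statistics and distance-based trees.

Per CNV region, two complementary views of strain relatedness are
built: a tree from SNPs flanking the region (20 kb each side), and a
neighbour-joining tree from Euclidean distances between strains' copy
numbers.  The total branch length of each tree summarizes how much
variation each marker class carries; their disagreement is the
signature of copy-number turnover.  Within clonal clusters the
relative transience of a CNV is sigma_rc = sigma_ic / sigma_oc, the
ratio of the within-cluster to the outside-cluster standard deviation
of copy number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .model import ParameterError

log = logging.getLogger(__name__)


def extract_flank_snps(
    snp_genotypes: pd.DataFrame, region: tuple, flank_bp: int = 20000
) -> pd.DataFrame:
    """Genotypes at SNPs flanking a region, concatenated.

    ``snp_genotypes`` has strains as rows and a (chrom, pos) MultiIndex
    (or tuple columns) of 1-based SNP positions as columns.  Sites with
    position in [start - flank, start) or (end, end + flank] on the
    region's chromosome are kept; the boundaries are inclusive at the
    outer ends.  An empty result is legitimate (a CNV with no flanking
    SNPs) and logged.
    """
    chrom, start, end = region
    keep = []
    for col in snp_genotypes.columns:
        c, pos = col
        if c != chrom:
            continue
        if (start - flank_bp) <= pos < start or end < pos <= (end + flank_bp):
            keep.append(col)
    out = snp_genotypes[keep]
    if out.shape[1] == 0:
        log.warning("region %s:%d-%d has no flanking SNPs", chrom, start, end)
    return out


def snp_distance(genotypes: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Hamming distance over shared non-missing sites.

    Missing genotypes are NaN; each pair's distance is the fraction of
    differing calls among sites typed in both strains (0 when no sites
    are shared, with a warning).
    """
    g = genotypes.to_numpy(dtype=float)
    n = g.shape[0]
    d = np.zeros((n, n))
    ok = ~np.isnan(g)
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        diff = (g[i] != g[i + 1 :]) & both
        shared = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(shared > 0, diff.sum(axis=1) / np.maximum(shared, 1), 0.0)
        if (shared == 0).any():
            log.warning("strain pairs with no shared typed sites set to distance 0")
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(d, ids=[str(s) for s in genotypes.index])


def copy_number_distance(
    cn: pd.DataFrame, regions: Optional[list] = None
) -> DistanceMatrix:
    """Euclidean distance between strains over the selected CNV columns."""
    sub = cn if regions is None else cn[regions]
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(sub.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=[str(s) for s in cn.index])


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour joining (Saitou-Nei) on a distance matrix.

    Deterministic: ties in the Q criterion resolve to the lowest index
    pair.  Negative branch lengths are clamped to zero with the deficit
    transferred to the sister edge, preserving the pair's summed
    length.  Additive matrices are recovered exactly (up to float
    precision).  The returned tree is unrooted in the usual NJ sense:
    the root is the final internal node.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ParameterError("neighbour joining requires >= 2 taxa")
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ParameterError("distance matrix must be symmetric")
    nodes = [TreeNode(name=i) for i in ids]
    if n == 2:
        half = d[0, 1] / 2.0
        root = TreeNode()
        for node in nodes:
            node.length = half
            root.append(node)
        return root
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among Q minima
        flat = np.argmin(q)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode()
        ni, nj_ = nodes[active[i]], nodes[active[j]]
        ni.length, nj_.length = float(li), float(lj)
        parent.append(ni)
        parent.append(nj_)
        # distances from the new node to the remaining taxa
        ai, aj = active[i], active[j]
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (ai, aj):
                continue
            dk = 0.5 * (d[ai, k] + d[aj, k] - dij)
            d[new_idx, k] = d[k, new_idx] = dk
        active = [k for k in active if k not in (ai, aj)] + [new_idx]
    a, b = active
    root = TreeNode()
    la = d[a, b] / 2.0
    # attach the last two nodes through the root; give each half the
    # remaining distance so the total branch length is preserved
    for node, length in ((nodes[a], la), (nodes[b], d[a, b] - la)):
        node.length = float(max(length, 0.0))
        root.append(node)
    return root


def total_branch_length(tree: TreeNode) -> float:
    """Sum of all branch lengths in the tree."""
    return float(
        sum(node.length or 0.0 for node in tree.traverse(include_self=False))
    )


def normalize_to_max(values) -> np.ndarray:
    """Divide a vector of branch lengths by its maximum."""
    v = np.asarray(values, dtype=float)
    m = v.max()
    if m <= 0:
        raise ParameterError("cannot normalize: maximum is not positive")
    return v / m


@dataclass
class TransienceResult:
    """Relative transience of one CNV within one clonal cluster."""

    cnv: str
    cluster: str
    sigma_ic: float
    sigma_oc: float
    sigma_rc: Optional[float]  # None when sigma_oc == 0

    @property
    def defined(self) -> bool:
        return self.sigma_rc is not None


def relative_transience(
    cn: pd.DataFrame, cnv, cluster_members, cluster_id: str = ""
) -> TransienceResult:
    """sigma_rc = sigma_ic / sigma_oc for one CNV and one cluster.

    Standard deviations are sample SDs (n-1 denominator) of the copy
    numbers of cluster members (sigma_ic) and of all other strains
    (sigma_oc).  Requires at least two strains on each side; a zero
    sigma_oc leaves the ratio undefined (flagged, never infinite).
    """
    members = [s for s in cluster_members if s in cn.index]
    outside = [s for s in cn.index if s not in set(members)]
    if len(members) < 2 or len(outside) < 2:
        raise ParameterError("need >= 2 strains inside and outside the cluster")
    ic = float(np.std(cn.loc[members, cnv].to_numpy(dtype=float), ddof=1))
    oc = float(np.std(cn.loc[outside, cnv].to_numpy(dtype=float), ddof=1))
    sigma_rc = None if oc == 0 else ic / oc
    if sigma_rc is None:
        log.warning("sigma_rc undefined for %s in cluster %s (sigma_oc=0)", cnv, cluster_id)
    return TransienceResult(
        cnv=str(cnv),
        cluster=cluster_id,
        sigma_ic=ic,
        sigma_oc=oc,
        sigma_rc=sigma_rc,
    )


def branch_length_association(branch_lengths, copy_number_sds) -> tuple:
    """Spearman rank correlation (rho, P) between per-CNV tree branch
    lengths and per-CNV copy-number standard deviations."""
    rho, p = stats.spearmanr(branch_lengths, copy_number_sds)
    return float(rho), float(p)
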