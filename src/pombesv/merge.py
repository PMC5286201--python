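"""Merge SV callsets within and across callers, then filter.

The pipeline follows the consensus strategy: collapse near-duplicate
calls within each caller (same type, same chromosome, start and end
within 1 kb), single-linkage cluster calls across callers under the
same predicate, keep clusters supported by at least two distinct
callers, then drop calls with paired-end support of 10 or less and
calls in unreliable regions (either breakpoint in a low-mapping-quality
region, or both breakpoints inside annotated retrotransposon LTRs).

Consensus coordinates are the per-coordinate median of cluster members
(fractional midpoints floored so coordinates stay integral).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .evaluate import is_match
from .model import IntervalSet, ParameterError, SVCall, SVType

log = logging.getLogger(__name__)


def _median_int(values) -> int:
    v = sorted(values)
    n = len(v)
    if n % 2:
        return int(v[n // 2])
    return int(math.floor((v[n // 2 - 1] + v[n // 2]) / 2))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _single_linkage(calls: list, tolerance_bp: int) -> list[list]:
    """Single-linkage clusters under the match predicate.

    Calls are bucketed by (type, chromosome key) first; within a bucket
    a sort-and-window sweep on start limits pair tests.  Cluster and
    member order follow coordinate-sorted order, so the result is
    independent of input order.
    """
    order = sorted(
        range(len(calls)),
        key=lambda i: (
            calls[i].type.value,
            calls[i].chrom,
            calls[i].start,
            calls[i].end,
            calls[i].caller,
            calls[i].id,
        ),
    )
    buckets: dict[tuple, list] = {}
    for idx in order:
        c = calls[idx]
        chroms = tuple(sorted((c.chrom, c.chrom2))) if c.type is SVType.TRA else (c.chrom,)
        buckets.setdefault((c.type, chroms), []).append(idx)
    uf = _UnionFind(len(calls))
    for members in buckets.values():
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1 :]:
                ci, cj = calls[i], calls[j]
                if (
                    ci.type is not SVType.TRA
                    and cj.start - ci.start > tolerance_bp
                    and ci.start <= cj.start
                ):
                    break
                if is_match(ci, cj, tolerance_bp):
                    uf.union(i, j)
    # dict insertion follows coordinate-sorted member order, so clusters
    # come out in coordinate order regardless of input order
    clusters: dict[int, list] = {}
    for idx in order:
        clusters.setdefault(uf.find(idx), []).append(idx)
    return [[calls[i] for i in members] for members in clusters.values()]


def _consensus_coords(members: list) -> tuple:
    start = _median_int(m.start for m in members)
    end = _median_int(m.end for m in members)
    if members[0].type is SVType.TRA:
        # orient each member's locus pair consistently before the median
        firsts, seconds = [], []
        for m in members:
            loci = sorted(m.loci())
            firsts.append(loci[0])
            seconds.append(loci[1])
        chrom = firsts[0][0]
        chrom2 = seconds[0][0]
        start = _median_int(p for _, p in firsts)
        pos2 = _median_int(p for _, p in seconds)
        return chrom, start, start, chrom2, pos2
    return members[0].chrom, start, end, None, None


def _max_pe(members: list):
    supports = [m.pe_support for m in members if m.pe_support is not None]
    return max(supports) if supports else None


def merge_within_callset(calls: list, tolerance_bp: int = 1000) -> list[SVCall]:
    """Collapse near-duplicate calls of one caller to single representatives.

    Requires a single caller label throughout.  Each single-linkage
    cluster becomes one call at the members' median coordinates with
    pe_support equal to the members' maximum.
    """
    labels = {c.caller for c in calls}
    if len(labels) > 1:
        raise ParameterError(f"mixed caller labels in one callset: {sorted(labels)}")
    out = []
    for members in _single_linkage(calls, tolerance_bp):
        if len(members) == 1:
            out.append(members[0])
            continue
        chrom, start, end, chrom2, pos2 = _consensus_coords(members)
        out.append(
            SVCall(
                id=members[0].id,
                type=members[0].type,
                chrom=chrom,
                start=start,
                end=end,
                chrom2=chrom2,
                pos2=pos2,
                pe_support=_max_pe(members),
                caller=members[0].caller,
            )
        )
    return out


@dataclass
class ConsensusCluster:
    """A cross-caller cluster of matching calls."""

    members: list
    type: SVType
    chrom: str
    consensus_start: int
    consensus_end: int
    chrom2: str = None
    pos2: int = None

    @property
    def n_callers(self) -> int:
        return len({m.caller for m in self.members})


def cluster_across_callsets(
    callsets: list, tolerance_bp: int = 1000
) -> list[ConsensusCluster]:
    """Single-linkage cluster calls pooled across callers.

    Each input callset should already be merged within itself
    (:func:`merge_within_callset`).
    """
    pooled = [c for cs in callsets for c in cs]
    clusters = []
    for members in _single_linkage(pooled, tolerance_bp):
        chrom, start, end, chrom2, pos2 = _consensus_coords(members)
        clusters.append(
            ConsensusCluster(
                members=members,
                type=members[0].type,
                chrom=chrom,
                consensus_start=start,
                consensus_end=end,
                chrom2=chrom2,
                pos2=pos2,
            )
        )
    return clusters


def consensus_filter(clusters: list, min_callers: int = 2) -> list[SVCall]:
    """Keep clusters seen by >= ``min_callers`` distinct callers and emit one
    consensus call per kept cluster."""
    if min_callers < 1:
        raise ParameterError("min_callers must be >= 1")
    out = []
    for i, cl in enumerate(clusters):
        if cl.n_callers < min_callers:
            continue
        out.append(
            SVCall(
                id=f"consensus_{i}",
                type=cl.type,
                chrom=cl.chrom,
                start=cl.consensus_start,
                end=cl.consensus_end,
                chrom2=cl.chrom2,
                pos2=cl.pos2,
                pe_support=_max_pe(cl.members),
                caller="consensus",
            )
        )
    log.info("consensus filter: %d/%d clusters kept", len(out), len(clusters))
    return out


def filter_pe_support(calls: list, min_support: int = 11) -> list[SVCall]:
    """Drop calls with paired-end support below ``min_support``.

    Calls with unknown support (None) are dropped and counted in the
    log -- unknown is not the same as zero, but it cannot satisfy the
    threshold either.
    """
    kept = [c for c in calls if c.pe_support is not None and c.pe_support >= min_support]
    n_absent = sum(1 for c in calls if c.pe_support is None)
    if n_absent:
        log.warning("pe-support filter: dropped %d calls with absent support", n_absent)
    log.info("pe-support filter: %d/%d calls kept", len(kept), len(calls))
    return kept


def filter_by_regions(
    calls: list, ltr: IntervalSet, low_mq: IntervalSet
) -> list[SVCall]:
    """Drop calls with a breakpoint in a low-MQ region, or with BOTH
    breakpoints inside annotated LTR intervals."""
    kept = []
    for c in calls:
        loci = c.loci()
        if any(low_mq.contains_point(ch, p) for ch, p in loci):
            continue
        if all(ltr.contains_point(ch, p) for ch, p in loci):
            continue
        kept.append(c)
    log.info("region filter: %d/%d calls kept", len(kept), len(calls))
    return kept


def merge_pipeline(
    callsets: list,
    tolerance_bp: int = 1000,
    min_callers: int = 2,
    min_pe: int = 11,
    ltr: IntervalSet = None,
    low_mq: IntervalSet = None,
) -> tuple[list, dict]:
    """Full consensus pipeline; returns (calls, per-stage audit counts).

    Stage order: within-caller merge -> cross-caller clustering ->
    consensus support filter -> paired-end support filter -> region
    filter.
    """
    audit: dict = {"input": {cs[0].caller if cs else f"set{i}": len(cs) for i, cs in enumerate(callsets)}}
    merged = [merge_within_callset(cs, tolerance_bp) for cs in callsets]
    audit["after_within_merge"] = [len(cs) for cs in merged]
    clusters = cluster_across_callsets(merged, tolerance_bp)
    audit["n_clusters"] = len(clusters)
    calls = consensus_filter(clusters, min_callers)
    audit["after_consensus"] = len(calls)
    calls = filter_pe_support(calls, min_pe)
    audit["after_pe_filter"] = len(calls)
    if ltr is not None or low_mq is not None:
        calls = filter_by_regions(
            calls, ltr or IntervalSet(), low_mq or IntervalSet()
        )
    audit["after_region_filter"] = len(calls)
    return calls, audit
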