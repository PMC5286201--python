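"""Score an SV callset against a known truth set.

A call matches a truth record when (i) the types agree, (ii) they are on
the same chromosome(s), and (iii) start and stop coordinates agree
within a tolerance (default 1 kb).  For translocations the two loci are
compared as an unordered pair, trying both pairings.  Counting is
many-to-many: a truth record is a true positive if matched by at least
one call, and a call is a false positive if it matches no truth record;
no one-to-one assignment is made, which keeps sensitivity monotonically
non-decreasing and FDR non-increasing in the tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .model import ParameterError, SVType

log = logging.getLogger(__name__)


def _loci_within(a_loci, b_loci, tol: int) -> bool:
    (ac1, ap1), (ac2, ap2) = a_loci
    for (bc1, bp1), (bc2, bp2) in (b_loci, (b_loci[1], b_loci[0])):
        if ac1 == bc1 and ac2 == bc2 and abs(ap1 - bp1) <= tol and abs(ap2 - bp2) <= tol:
            return True
    return False


def is_match(call, truth, tolerance_bp: int = 1000) -> bool:
    """Match predicate between a call and a truth record (or two calls)."""
    if tolerance_bp < 0:
        raise ParameterError("tolerance_bp must be >= 0")
    if call.type is not truth.type:
        return False
    if call.type is SVType.TRA:
        return _loci_within(call.loci(), truth.loci(), tolerance_bp)
    return (
        call.chrom == truth.chrom
        and abs(call.start - truth.start) <= tolerance_bp
        and abs(call.end - truth.end) <= tolerance_bp
    )


@dataclass
class EvaluationMetrics:
    """Sensitivity/FDR summary of one callset-vs-truth comparison."""

    n_truth: int
    n_calls: int
    tp_truth: int
    fp_calls: int
    per_type: dict = field(default_factory=dict)

    @property
    def fn(self) -> int:
        return self.n_truth - self.tp_truth

    @property
    def sensitivity(self) -> float:
        return self.tp_truth / self.n_truth if self.n_truth else math.nan

    @property
    def fdr(self) -> float:
        return self.fp_calls / self.n_calls if self.n_calls else math.nan

    def to_dict(self) -> dict:
        d = {
            "n_truth": self.n_truth,
            "n_calls": self.n_calls,
            "tp_truth": self.tp_truth,
            "fp_calls": self.fp_calls,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "fdr": self.fdr,
        }
        if self.per_type:
            d["per_type"] = {
                t.value: m.to_dict() for t, m in self.per_type.items()
            }
        return d


def evaluate(calls, truth, tolerance_bp: int = 1000) -> EvaluationMetrics:
    """Compute sensitivity and FDR of ``calls`` against ``truth``.

    Empty truth leaves sensitivity undefined (NaN, with a warning);
    empty calls likewise for FDR.  Per-type breakdowns accompany the
    pooled numbers; matches never cross types.
    """
    if tolerance_bp < 0:
        raise ParameterError("tolerance_bp must be >= 0")
    if not truth:
        log.warning("empty truth set: sensitivity undefined")
    if not calls:
        log.warning("empty callset: FDR undefined")
    # bucket by type; chromosome bucketing is handled inside is_match
    truth_by_type: dict[SVType, list] = {}
    for t in truth:
        truth_by_type.setdefault(t.type, []).append(t)
    calls_by_type: dict[SVType, list] = {}
    for c in calls:
        calls_by_type.setdefault(c.type, []).append(c)

    per_type: dict[SVType, EvaluationMetrics] = {}
    tp_truth = 0
    fp_calls = 0
    for svtype in sorted(set(truth_by_type) | set(calls_by_type), key=lambda t: t.value):
        tlist = truth_by_type.get(svtype, [])
        clist = calls_by_type.get(svtype, [])
        t_hit = [False] * len(tlist)
        c_hit = [False] * len(clist)
        for i, t in enumerate(tlist):
            for j, c in enumerate(clist):
                if is_match(c, t, tolerance_bp):
                    t_hit[i] = True
                    c_hit[j] = True
        tp = sum(t_hit)
        fp = len(clist) - sum(c_hit)
        tp_truth += tp
        fp_calls += fp
        per_type[svtype] = EvaluationMetrics(
            n_truth=len(tlist), n_calls=len(clist), tp_truth=tp, fp_calls=fp
        )
    return EvaluationMetrics(
        n_truth=len(truth),
        n_calls=len(calls),
        tp_truth=tp_truth,
        fp_calls=fp_calls,
        per_type=per_type,
    )
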