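"""Simulate structural variants into a reference genome.

The simulator plans a set of non-overlapping SV events (deletions,
insertions, tandem duplications, inversions and reciprocal
translocations) on reference coordinates, applies them to produce an
altered genome, and optionally sprinkles background SNPs/indels.  Truth
is reported on reference coordinates, which is what a truth-vs-calls
comparison needs; the altered genome is a separate artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import CapacityError, ParameterError, SVCall, SVType, TruthRecord

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")
_BASES = b"ACGT"

# type composition of the study system's curated catalogue
# (DEL : DUP : INV : TRA ~ 141 : 112 : 26 : 36)
_PAPERLIKE_PROPS = {SVType.DEL: 0.45, SVType.DUP: 0.35, SVType.INV: 0.08, SVType.TRA: 0.12}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationSpec:
    """Counts, size ranges and rates for one simulation run.

    ``counts`` maps SVType to the number of events; ``size_ranges`` maps
    SVType to an inclusive [min_bp, max_bp] event length range.
    ``snp_rate``/``indel_rate`` are per-bp background mutation rates
    (events per base, each capped at 0.1).
    """

    counts: dict = field(default_factory=dict)
    size_ranges: dict = field(default_factory=dict)
    dup_copies: int = 2
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    min_gap_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.counts = {SVType(k): int(v) for k, v in self.counts.items()}
        self.size_ranges = {
            SVType(k): (int(v[0]), int(v[1])) for k, v in self.size_ranges.items()
        }
        for t, n in self.counts.items():
            if n < 0:
                raise ParameterError(f"negative count for {t}")
            if n > 0 and t not in self.size_ranges:
                raise ParameterError(f"no size range given for {t}")
        for t, (lo, hi) in self.size_ranges.items():
            if lo < 1 or lo > hi:
                raise ParameterError(f"bad size range for {t}: [{lo}, {hi}]")
        for name in ("snp_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.1:
                raise ParameterError(f"{name}={r} outside [0, 0.1]")
        if self.dup_copies < 2:
            raise ParameterError("dup_copies must be >= 2")

    def max_planned_span(self) -> int:
        """Upper bound on reference bp consumed by planned events + gaps."""
        total = 0
        for t, n in self.counts.items():
            if n == 0:
                continue
            hi = self.size_ranges[t][1]
            per = 2 * hi if t is SVType.TRA else hi
            total += n * (per + self.min_gap_bp)
        return total


def paperlike_spec(seed: int = 0, size_range: tuple = (500, 5000)) -> SimulationSpec:
    """Preset drawing a total SV count in the study's simulated range (30-170),
    split across types in the proportions of the curated catalogue."""
    rng = np.random.default_rng(seed)
    total = int(rng.integers(30, 171))
    counts = {t: int(round(total * p)) for t, p in _PAPERLIKE_PROPS.items()}
    return SimulationSpec(
        counts=counts,
        size_ranges={t: size_range for t in counts},
        snp_rate=0.001,
        indel_rate=0.001,
        seed=seed,
    )


@dataclass
class SimulatedGenome:
    """An altered genome plus everything needed to score callers on it."""

    sequences: dict
    provenance: Optional[SimulationSpec]
    truth: list
    point_mutations: list = field(default_factory=list)


class _Occupancy:
    """Tracks reserved reference spans per chromosome (1-based inclusive)."""

    def __init__(self) -> None:
        self.spans: dict[str, list] = {}

    def conflicts(self, chrom: str, start: int, end: int, gap: int) -> bool:
        for s, e in self.spans.get(chrom, ()):
            if start <= e + gap and s <= end + gap:
                return True
        return False

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.spans.setdefault(chrom, []).append((start, end))


def _has_n(seq: str, start: int, end: int) -> bool:
    return "N" in seq[start - 1 : end]


def plan_svs(reference: dict[str, str], spec: SimulationSpec) -> list[TruthRecord]:
    """Randomly place the requested events on the reference.

    Events never overlap each other (separated by >= ``min_gap_bp``),
    never contain N runs, and stay ``min_gap_bp`` clear of chromosome
    ends.  Placement is deterministic for a fixed spec seed.  Each event
    gets up to 1000 placement attempts before a :class:`CapacityError`.
    """
    if not reference:
        raise ParameterError("empty reference")
    genome_span = sum(len(s) for s in reference.values())
    if spec.max_planned_span() >= genome_span:
        raise CapacityError(
            f"planned span {spec.max_planned_span()} bp does not fit in "
            f"{genome_span} bp of reference"
        )
    rng = np.random.default_rng(spec.seed)
    chroms = sorted(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    occ = _Occupancy()
    truth: list[TruthRecord] = []
    counter = 0

    def place_span(size: int) -> tuple[str, int, int]:
        for _ in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            L = len(reference[chrom])
            lo = spec.min_gap_bp + 1
            hi = L - spec.min_gap_bp - size + 1
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            end = start + size - 1
            if occ.conflicts(chrom, start, end, spec.min_gap_bp):
                continue
            if _has_n(reference[chrom], start, end):
                continue
            return chrom, start, end
        raise CapacityError("could not place event after 1000 attempts")

    for svtype in (SVType.DEL, SVType.DUP, SVType.INS, SVType.INV, SVType.TRA):
        n = spec.counts.get(svtype, 0)
        for _ in range(n):
            lo, hi = spec.size_ranges[svtype]
            size = int(rng.integers(lo, hi + 1))
            counter += 1
            rid = f"{svtype.value}_{counter}"
            if svtype is SVType.TRA:
                truth.append(_place_tra(reference, spec, rng, occ, rid, size))
                continue
            if svtype is SVType.INS:
                chrom, start, end = place_span(1)
                seq = "".join(
                    chr(_BASES[i]) for i in rng.integers(0, 4, size=size)
                )
                occ.reserve(chrom, start, end)
                truth.append(
                    TruthRecord(rid, svtype, chrom, start, start, insert_seq=seq)
                )
                continue
            chrom, start, end = place_span(size)
            occ.reserve(chrom, start, end)
            truth.append(
                TruthRecord(
                    rid,
                    svtype,
                    chrom,
                    start,
                    end,
                    copies=spec.dup_copies if svtype is SVType.DUP else None,
                )
            )
    return truth


def _place_tra(reference, spec, rng, occ, rid, size) -> TruthRecord:
    """Reserve two internal segments on distinct chromosomes for a
    reciprocal exchange."""
    chroms = sorted(reference)
    if len(chroms) < 2:
        raise CapacityError("translocation requires >= 2 chromosomes")
    lo, hi = spec.size_ranges[SVType.TRA]
    gap = spec.min_gap_bp
    for _ in range(1000):
        size2 = int(rng.integers(lo, hi + 1))
        ca, cb = (chroms[i] for i in rng.choice(len(chroms), size=2, replace=False))
        La, Lb = len(reference[ca]), len(reference[cb])
        if La - gap - size <= gap + 1 or Lb - gap - size2 <= gap + 1:
            continue
        s1 = int(rng.integers(gap + 1, La - gap - size + 1))
        s2 = int(rng.integers(gap + 1, Lb - gap - size2 + 1))
        e1, e2 = s1 + size - 1, s2 + size2 - 1
        if occ.conflicts(ca, s1, e1, gap) or occ.conflicts(cb, s2, e2, gap):
            continue
        if _has_n(reference[ca], s1, e1) or _has_n(reference[cb], s2, e2):
            continue
        occ.reserve(ca, s1, e1)
        occ.reserve(cb, s2, e2)
        return TruthRecord(
            rid, SVType.TRA, ca, s1, e1, chrom2=cb, start2=s2, end2=e2
        )
    raise CapacityError("could not place translocation after 1000 attempts")


def _check_disjoint(truth: list) -> None:
    occ = _Occupancy()
    for r in truth:
        spans = [(r.chrom, r.start, r.end)]
        if r.type is SVType.TRA:
            spans.append((r.chrom2, r.start2, r.end2))
        for chrom, s, e in spans:
            if occ.conflicts(chrom, s, e, 0):
                raise ParameterError(f"truth records overlap at {chrom}:{s}-{e}")
            occ.reserve(chrom, s, e)


def apply_svs(reference: dict[str, str], truth: list) -> SimulatedGenome:
    """Apply planned events to the reference and return the altered genome.

    Deletions remove their span; insertions add sequence after their
    position; duplications are tandem (copies-1 extra copies inserted
    immediately after the source segment); inversions reverse-complement
    in place; translocations reciprocally exchange their two segments.
    """
    _check_disjoint(truth)
    # every event becomes a local edit (start, end, replacement) on
    # reference coordinates; a TRA contributes one edit per chromosome,
    # each splicing in the partner segment taken from the reference
    edits: dict[str, list] = {c: [] for c in reference}
    for r in truth:
        if r.type is SVType.DEL:
            edits[r.chrom].append((r.start, r.end, ""))
        elif r.type is SVType.INS:
            # insert after position start: replace the empty slice at start+1
            edits[r.chrom].append((r.start + 1, r.start, r.insert_seq))
        elif r.type is SVType.DUP:
            seg = reference[r.chrom][r.start - 1 : r.end]
            edits[r.chrom].append((r.start, r.end, seg * r.copies))
        elif r.type is SVType.INV:
            seg = reference[r.chrom][r.start - 1 : r.end]
            edits[r.chrom].append((r.start, r.end, reverse_complement(seg)))
        elif r.type is SVType.TRA:
            seg_a = reference[r.chrom][r.start - 1 : r.end]
            seg_b = reference[r.chrom2][r.start2 - 1 : r.end2]
            edits[r.chrom].append((r.start, r.end, seg_b))
            edits[r.chrom2].append((r.start2, r.end2, seg_a))
    seqs = {}
    for chrom, seq in reference.items():
        for s, e, repl in sorted(edits[chrom], reverse=True):
            seq = seq[: s - 1] + repl + seq[e:]
        seqs[chrom] = seq
    return SimulatedGenome(sequences=seqs, provenance=None, truth=list(truth))


def expected_lengths(reference: dict[str, str], truth: list) -> dict[str, int]:
    """Closed-form per-chromosome lengths after applying ``truth``."""
    out = {c: len(s) for c, s in reference.items()}
    for r in truth:
        if r.type is SVType.DEL:
            out[r.chrom] -= r.length
        elif r.type is SVType.INS:
            out[r.chrom] += len(r.insert_seq)
        elif r.type is SVType.DUP:
            out[r.chrom] += (r.copies - 1) * r.length
        elif r.type is SVType.TRA:
            delta = (r.end2 - r.start2) - (r.end - r.start)
            out[r.chrom] += delta
            out[r.chrom2] -= delta
    return out


def add_point_mutations(
    genome, snp_rate: float, indel_rate: float, seed: int
) -> SimulatedGenome:
    """Add background SNPs and small (1-10 bp) indels at the given rates.

    Substitution counts per chromosome are Binomial(L, snp_rate) and a
    substituted base never equals the reference base.  Every change is
    recorded as (chrom, pos, ref, alt) on pre-mutation coordinates; for
    an insertion ref is empty, for a deletion alt is empty.
    """
    for name, rate in (("snp_rate", snp_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate <= 0.1:
            raise ParameterError(f"{name}={rate} outside [0, 0.1]")
    sequences = genome.sequences if isinstance(genome, SimulatedGenome) else genome
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    mutations: list[tuple] = []
    for chrom in sorted(sequences):
        seq = bytearray(sequences[chrom], "ascii")
        L = len(seq)
        n_snp = int(rng.binomial(L, snp_rate)) if snp_rate > 0 else 0
        if n_snp:
            positions = rng.choice(L, size=n_snp, replace=False)
            positions.sort()
            for p in positions:
                ref = chr(seq[p])
                choices = [b for b in "ACGT" if b != ref.upper()]
                alt = choices[int(rng.integers(0, len(choices)))]
                mutations.append((chrom, int(p) + 1, ref, alt))
                seq[p] = ord(alt)
        n_ind = int(rng.binomial(L, indel_rate)) if indel_rate > 0 else 0
        indels = []
        if n_ind:
            pos = np.sort(rng.choice(L - 11, size=min(n_ind, L - 11), replace=False))
            sizes = rng.integers(1, 11, size=len(pos))
            is_ins = rng.integers(0, 2, size=len(pos)).astype(bool)
            for p, k, ins in zip(pos, sizes, is_ins):
                if ins:
                    alt = "".join(chr(_BASES[i]) for i in rng.integers(0, 4, size=k))
                    indels.append((int(p), "", alt))
                else:
                    indels.append((int(p), seq[p : p + k].decode(), ""))
        # right-to-left so earlier coordinates stay valid
        for p, ref, alt in sorted(indels, reverse=True):
            mutations.append((chrom, p + 1, ref, alt))
            if alt:
                seq[p:p] = alt.encode()
            else:
                del seq[p : p + len(ref)]
        out[chrom] = seq.decode()
    truth = genome.truth if isinstance(genome, SimulatedGenome) else []
    prov = genome.provenance if isinstance(genome, SimulatedGenome) else None
    return SimulatedGenome(
        sequences=out, provenance=prov, truth=truth, point_mutations=mutations
    )


def run_simulation(reference: dict[str, str], spec: SimulationSpec) -> SimulatedGenome:
    """Plan, apply and mutate in one call."""
    truth = plan_svs(reference, spec)
    sim = apply_svs(reference, truth)
    sim.provenance = spec
    if spec.snp_rate > 0 or spec.indel_rate > 0:
        sim = add_point_mutations(sim, spec.snp_rate, spec.indel_rate, spec.seed + 1)
        sim.provenance = spec
    return sim


def perfect_callset(truth: list, pe_support: int = 20) -> list[SVCall]:
    """One SVCall per truth record at identical coordinates (for round-trip
    benchmarks)."""
    calls = []
    for r in truth:
        kwargs = {}
        if r.type is SVType.TRA:
            kwargs = dict(chrom2=r.chrom2, pos2=r.start2)
            end = r.start
        else:
            end = r.end
        calls.append(
            SVCall(
                id=f"call_{r.id}",
                type=r.type,
                chrom=r.chrom,
                start=r.start,
                end=end,
                pe_support=pe_support,
                caller="perfect",
                **kwargs,
            )
        )
    return calls
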