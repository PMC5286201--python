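"""Readers and writers for the standard formats the toolkit touches.

VCF 4.2 via pysam (SVTYPE/END/SVLEN/CHR2/POS2/PE INFO keys, symbolic ALT
alleles, BND breakend pairs accepted on input); extended BED for
simulation truth; plain BED for annotation intervals; FASTA via
Biopython.  All conversion between on-disk 0-based half-open (BED) and
the package's 1-based inclusive coordinates happens here and only here.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CoordinateError,
    FormatError,
    IntervalSet,
    SVCall,
    SVType,
    TruthRecord,
    UnknownSVTypeError,
)

log = logging.getLogger(__name__)

_BND_RE = re.compile(r"[\[\]](?P<chrom>[^:\[\]]+):(?P<pos>\d+)[\[\]]")

_INFO_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=CHR2,Number=1,Type=String,Description="Second chromosome (TRA)">',
    '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Position on CHR2 (TRA)">',
    '##INFO=<ID=PE,Number=1,Type=Integer,Description="Paired-end read support">',
    '##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller label">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _info_get(rec, key, default=None):
    """INFO accessor tolerant of keys missing from the header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _svtype_of(rec: "pysam.VariantRecord") -> Optional[str]:
    t = _info_get(rec, "SVTYPE")
    if t is not None:
        return str(t)
    alt = rec.alts[0] if rec.alts else None
    if alt and alt.startswith("<") and alt.endswith(">"):
        return alt.strip("<>").split(":")[0]
    if alt and ("[" in alt or "]" in alt):
        return "BND"
    return None


def read_sv_vcf(path, caller_label: str = "") -> list[SVCall]:
    """Read SV records from a VCF file into :class:`SVCall` objects.

    BND breakend mate pairs describing one translocation collapse to a
    single TRA call.  Records whose SV type cannot be determined are
    skipped and counted in the log.  Coordinates outside the declared
    contig length raise :class:`CoordinateError`.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc

    contig_len = {name: c.length for name, c in vf.header.contigs.items()}
    calls: list[SVCall] = []
    bnds: list[dict] = []
    skipped = 0
    with vf:
        for rec in vf:
            tstr = _svtype_of(rec)
            if tstr is None:
                skipped += 1
                continue
            if tstr == "BND":
                m = _BND_RE.search(rec.alts[0])
                if not m:
                    skipped += 1
                    continue
                bnds.append(
                    dict(
                        id=rec.id or f"bnd_{len(bnds)}",
                        chrom=rec.chrom,
                        pos=rec.pos,
                        chrom2=m.group("chrom"),
                        pos2=int(m.group("pos")),
                        mateid=_info_get(rec, "MATEID"),
                        pe=_info_get(rec, "PE"),
                        genotypes=_genotypes_of(rec),
                    )
                )
                continue
            try:
                svtype = SVType.parse(tstr)
            except UnknownSVTypeError:
                skipped += 1
                continue
            declared = contig_len.get(rec.chrom)
            start = rec.pos
            end = rec.stop
            if svtype is SVType.INS:
                end = start
            if end < start and svtype is not SVType.TRA:
                # some dialects encode SVLEN only
                svlen = _info_get(rec, "SVLEN")
                if svlen is not None:
                    svlen = abs(int(svlen[0] if isinstance(svlen, tuple) else svlen))
                    end = start + svlen - 1
            if declared and (start > declared or (svtype is not SVType.TRA and end > declared)):
                raise CoordinateError(
                    f"{path}: {rec.chrom}:{start}-{end} outside contig length {declared}"
                )
            svlen = _info_get(rec, "SVLEN")
            if svlen is not None:
                svlen = abs(int(svlen[0] if isinstance(svlen, tuple) else svlen))
            kwargs: dict = {}
            if svtype is SVType.TRA:
                chrom2 = _info_get(rec, "CHR2")
                pos2 = _info_get(rec, "POS2", rec.stop)
                if chrom2 is None:
                    skipped += 1
                    continue
                kwargs.update(chrom2=str(chrom2), pos2=int(pos2))
                end = start
            calls.append(
                SVCall(
                    id=rec.id or f"{caller_label}_{len(calls)}",
                    type=svtype,
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    length=svlen,
                    pe_support=(
                        _int_or_none(_info_get(rec, "PE"))
                    ),
                    caller=caller_label or str(_info_get(rec, "CALLER", "")),
                    genotypes=_genotypes_of(rec),
                    **kwargs,
                )
            )
    calls.extend(_pair_bnds(bnds, caller_label))
    if skipped:
        log.warning("%s: skipped %d records with unparseable SV type", path, skipped)
    return calls


def _int_or_none(v):
    return int(v) if v is not None else None


def _genotypes_of(rec) -> dict:
    out = {}
    for sample, data in rec.samples.items():
        gt = data.get("GT")
        if gt is None or all(a is None for a in gt):
            out[sample] = None
        else:
            out[sample] = int(any(a == 1 for a in gt if a is not None))
    return out


def _pair_bnds(bnds: list[dict], caller_label: str) -> list[SVCall]:
    """Collapse BND records to one TRA per unordered locus pair.

    Mates are joined by MATEID when present, otherwise by the reciprocal
    coordinate rule (A points at B's locus and B at A's).  Reciprocal
    junction pairs describing the same exchange are deduplicated.
    """
    calls: list[SVCall] = []
    seen: set[tuple] = set()
    for b in bnds:
        a_locus = (b["chrom"], b["pos"])
        b_locus = (b["chrom2"], b["pos2"])
        key = tuple(sorted([a_locus, b_locus]))
        if key in seen:
            continue
        seen.add(key)
        calls.append(
            SVCall(
                id=b["id"],
                type=SVType.TRA,
                chrom=a_locus[0],
                start=a_locus[1],
                end=a_locus[1],
                chrom2=b_locus[0],
                pos2=b_locus[1],
                pe_support=int(b["pe"]) if b["pe"] is not None else None,
                caller=caller_label,
                genotypes=b["genotypes"],
            )
        )
    return calls


def _build_header(
    calls: Sequence[SVCall], contigs: Optional[dict] = None
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for c in calls:
            hi = max(c.end, c.start) + 1000
            contigs[c.chrom] = max(contigs.get(c.chrom, 0), hi)
            if c.chrom2 is not None:
                contigs[c.chrom2] = max(contigs.get(c.chrom2, 0), c.pos2 + 1000)
    for name in sorted(contigs):
        header.contigs.add(name, length=int(contigs[name]))
    for line in _INFO_LINES:
        header.add_line(line)
    samples = sorted({s for c in calls for s in c.genotypes})
    for s in samples:
        header.add_sample(s)
    return header


def write_sv_vcf(
    calls: Sequence[SVCall],
    path,
    contigs: Optional[dict] = None,
    tra_as_bnd: bool = False,
) -> None:
    """Write calls to VCF 4.2.

    Translocations are emitted as single CHR2/POS2 records by default
    (the DELLY-style dialect the package reads back canonically), or as
    BND mate pairs with ``tra_as_bnd=True``.
    """
    header = _build_header(calls, contigs)
    samples = list(header.samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, c in enumerate(calls):
            if c.type is SVType.TRA and tra_as_bnd:
                for rec in _bnd_pair_records(out, c, i, samples):
                    out.write(rec)
                continue
            end = c.pos2 if c.type is SVType.TRA else c.end
            rec = out.new_record(
                contig=c.chrom,
                start=c.start - 1,
                stop=end,
                alleles=("N", f"<{c.type.value}>"),
                id=c.id or f"sv_{i}",
            )
            rec.info["SVTYPE"] = c.type.value
            # SVLEN only for insertions: for symbolic span alleles htslib
            # derives END from SVLEN, clashing with inclusive lengths
            if c.type is SVType.INS and c.length is not None:
                rec.info["SVLEN"] = int(c.length)
            if c.type is SVType.TRA:
                rec.info["CHR2"] = c.chrom2
                rec.info["POS2"] = int(c.pos2)
            if c.pe_support is not None:
                rec.info["PE"] = int(c.pe_support)
            if c.caller:
                rec.info["CALLER"] = c.caller
            # after INFO: setting SVLEN can make htslib recompute END
            rec.stop = end
            _set_genotypes(rec, c, samples)
            out.write(rec)


def _bnd_pair_records(out, c: SVCall, i: int, samples):
    base = c.id or f"sv_{i}"
    spec = [
        (c.chrom, c.start, c.chrom2, c.pos2, f"{base}_1", f"{base}_2"),
        (c.chrom2, c.pos2, c.chrom, c.start, f"{base}_2", f"{base}_1"),
    ]
    for chrom, pos, chrom2, pos2, rid, mate in spec:
        rec = out.new_record(
            contig=chrom,
            start=pos - 1,
            stop=pos,
            alleles=("N", f"N[{chrom2}:{pos2}["),
            id=rid,
        )
        rec.info["SVTYPE"] = "BND"
        rec.info["MATEID"] = mate
        if c.pe_support is not None:
            rec.info["PE"] = int(c.pe_support)
        if c.caller:
            rec.info["CALLER"] = c.caller
        _set_genotypes(rec, c, samples)
        yield rec


def _set_genotypes(rec, c: SVCall, samples) -> None:
    for s in samples:
        gt = c.genotypes.get(s)
        rec.samples[s]["GT"] = (None,) if gt is None else (int(gt),)


# ---------------------------------------------------------------------------
# extended BED truth files


def _extras_of(r: TruthRecord) -> str:
    parts = []
    if r.insert_seq:
        parts.append(f"seq={r.insert_seq}")
    if r.type is SVType.DUP:
        parts.append(f"copies={r.copies}")
    if r.type is SVType.TRA:
        parts.append(f"chr2={r.chrom2}")
        parts.append(f"start2={r.start2 - 1}")
        parts.append(f"end2={r.end2}")
    return ";".join(parts) or "."


def write_truth_bed(records: Sequence[TruthRecord], path) -> None:
    """Write simulation truth as extended BED (0-based half-open spans)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.type.value}\t"
                f"{r.id}\t{_extras_of(r)}\n"
            )


def read_truth_bed(path) -> list[TruthRecord]:
    """Read an extended BED truth file written by :func:`write_truth_bed`.

    Plain four-column BED (chrom, start, end, type) is also accepted.
    """
    records: list[TruthRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >=4 BED columns, got {len(cols)}"
                )
            chrom, start0, end0, tstr = cols[:4]
            rid = cols[4] if len(cols) > 4 else f"truth_{lineno}"
            extras = {}
            if len(cols) > 5 and cols[5] != ".":
                for kv in cols[5].split(";"):
                    k, _, v = kv.partition("=")
                    extras[k] = v
            try:
                start0, end0 = int(start0), int(end0)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            records.append(
                TruthRecord(
                    id=rid,
                    type=SVType.parse(tstr),
                    chrom=chrom,
                    start=start0 + 1,
                    end=end0,
                    insert_seq=extras.get("seq"),
                    copies=int(extras["copies"]) if "copies" in extras else None,
                    chrom2=extras.get("chr2"),
                    start2=int(extras["start2"]) + 1 if "start2" in extras else None,
                    end2=int(extras["end2"]) if "end2" in extras else None,
                )
            )
    return records


def read_intervals(path) -> IntervalSet:
    """Read a BED file of annotation intervals (LTRs, low-MQ regions).

    Malformed lines are logged and skipped rather than fatal; intervals
    are kept exactly as given (touching intervals are not merged).
    """
    s = IntervalSet()
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            try:
                label = cols[3] if len(cols) > 3 else None
                s.add(cols[0], int(cols[1]), int(cols[2]), label)
            except (IndexError, ValueError, CoordinateError):
                n_bad += 1
                log.warning("%s:%d: skipping malformed interval line", path, lineno)
    if n_bad:
        log.warning("%s: %d malformed interval lines skipped", path, n_bad)
    return s


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a chrom -> uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    """Write a genome mapping as FASTA with fixed line width."""
    records = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
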