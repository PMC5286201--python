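"""Synthetic data generators with known ground truth.

These generators give every stage of the toolkit a self-contained test
surface: random genomes, error-profiled mock callers standing in for
external SV callers, Poisson/negative-binomial windowed coverage at a
target depth, clonal strain populations with segregating CNVs, and
cross tables in which viability responds to SNP and rearrangement
distance but not to CNV distance.

Everything is seed-deterministic and emits its ground truth alongside
the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cnv import CoverageMatrix
from .model import ParameterError, SVCall, SVType, TruthRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(
    chrom_lengths, gc: float = 0.36, seed: int = 0, names: Optional[list] = None
) -> dict:
    """Random genome with the given chromosome lengths and GC content.

    The default GC fraction matches a yeast-like genome.  Deterministic
    for a fixed seed.
    """
    if not 0.0 <= gc <= 1.0:
        raise ParameterError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for i, L in enumerate(chrom_lengths):
        name = names[i] if names else f"chr{i + 1}"
        idx = rng.choice(4, size=int(L), p=p)
        genome[name] = _BASES[idx].tobytes().decode()
    return genome


@dataclass
class MockCallerProfile:
    """Three-parameter error model for a stand-in SV caller."""

    label: str
    sensitivity: float = 0.8
    n_false_positives: int = 0
    breakpoint_jitter_sd: float = 150.0
    pe_range: tuple = (11, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ParameterError("sensitivity must be in [0, 1]")
        if self.n_false_positives < 0 or self.breakpoint_jitter_sd < 0:
            raise ParameterError("negative error parameter")


def _chrom_lengths(genome: dict) -> dict:
    return {
        c: (len(s) if isinstance(s, str) else int(s)) for c, s in genome.items()
    }


def _truncated_jitter(rng, sd: float, size: int) -> np.ndarray:
    """Rounded zero-mean Gaussian noise truncated at +-3 SD."""
    if sd == 0:
        return np.zeros(size, dtype=int)
    x = rng.normal(0.0, sd, size=size)
    x = np.clip(x, -3 * sd, 3 * sd)
    return np.rint(x).astype(int)


def mock_caller(
    truth: list, profile: MockCallerProfile, genome: dict
) -> list[SVCall]:
    """Emulate an error-prone SV caller on a known truth set.

    Each truth event is emitted independently with probability
    ``sensitivity``, with breakpoints jittered by truncated rounded
    Gaussian noise.  ``n_false_positives`` additional calls of random
    type and size are placed uniformly, avoiding truth loci by at least
    1 kb.  ``genome`` may map chromosome names to sequences or plain
    lengths.
    """
    rng = np.random.default_rng(profile.seed)
    lengths = _chrom_lengths(genome)
    chroms = sorted(lengths)
    calls: list[SVCall] = []
    detected = rng.random(len(truth)) < profile.sensitivity
    jit = _truncated_jitter(rng, profile.breakpoint_jitter_sd, 2 * len(truth))
    for i, (t, hit) in enumerate(zip(truth, detected)):
        if not hit:
            continue
        j1, j2 = int(jit[2 * i]), int(jit[2 * i + 1])
        pe = int(rng.integers(profile.pe_range[0], profile.pe_range[1] + 1))
        rid = f"{profile.label}_{t.id}"
        if t.type is SVType.TRA:
            calls.append(
                SVCall(
                    id=rid,
                    type=SVType.TRA,
                    chrom=t.chrom,
                    start=max(1, t.start + j1),
                    end=max(1, t.start + j1),
                    chrom2=t.chrom2,
                    pos2=max(1, t.start2 + j2),
                    pe_support=pe,
                    caller=profile.label,
                )
            )
            continue
        start = max(1, t.start + j1)
        end = max(start, t.end + j2)
        calls.append(
            SVCall(
                id=rid,
                type=t.type,
                chrom=t.chrom,
                start=start,
                end=end,
                pe_support=pe,
                caller=profile.label,
            )
        )
    calls.extend(_false_positives(rng, profile, truth, lengths, chroms))
    return calls


def _false_positives(rng, profile, truth, lengths, chroms) -> list[SVCall]:
    truth_spans: dict[str, list] = {}
    for t in truth:
        truth_spans.setdefault(t.chrom, []).append((t.start, t.end))
        if t.type is SVType.TRA:
            truth_spans.setdefault(t.chrom2, []).append((t.start2, t.end2))
    fp_types = [SVType.DEL, SVType.DUP, SVType.INV]
    out = []
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    for k in range(profile.n_false_positives):
        for _ in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            size = int(rng.integers(200, 5001))
            if lengths[chrom] <= size + 2:
                continue
            start = int(rng.integers(1, lengths[chrom] - size))
            end = start + size - 1
            near = any(
                start <= e + 1000 and s <= end + 1000
                for s, e in truth_spans.get(chrom, ())
            )
            if near:
                continue
            out.append(
                SVCall(
                    id=f"{profile.label}_fp_{k}",
                    type=fp_types[int(rng.integers(0, len(fp_types)))],
                    chrom=chrom,
                    start=start,
                    end=end,
                    pe_support=int(
                        rng.integers(profile.pe_range[0], profile.pe_range[1] + 1)
                    ),
                    caller=profile.label,
                )
            )
            break
    return out


def synth_coverage(
    regions: list,
    true_copy_numbers: dict,
    depth: float = 40.0,
    noise: str = "poisson",
    dispersion: float = 0.1,
    window: int = 100,
    seed: int = 0,
) -> CoverageMatrix:
    """Windowed read counts with per-strain, per-region copy numbers.

    ``regions`` is a list of (chrom, start, end) 1-based inclusive
    spans; ``true_copy_numbers`` maps strain -> {region_index: copy
    number} (unspecified regions default to copy 1).  Window counts are
    Poisson with mean depth * copy_number, or negative binomial with
    the same mean and the given dispersion (variance = mu + dispersion
    * mu^2).
    """
    if noise not in ("poisson", "negbin"):
        raise ParameterError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    strains = sorted(true_copy_numbers)
    win_rows = []
    region_of_row = []
    for ridx, (chrom, start, end) in enumerate(regions):
        w0 = start - 1
        while w0 + window <= end:
            win_rows.append((chrom, w0, w0 + window))
            region_of_row.append(ridx)
            w0 += window
    counts = np.zeros((len(win_rows), len(strains)), dtype=int)
    for j, s in enumerate(strains):
        cn_by_region = true_copy_numbers[s]
        mu = np.array(
            [depth * float(cn_by_region.get(r, 1.0)) for r in region_of_row]
        )
        if noise == "poisson":
            counts[:, j] = rng.poisson(mu)
        else:
            nz = mu > 0
            out = np.zeros_like(mu)
            r = 1.0 / dispersion
            p = r / (r + mu[nz])
            out[nz] = rng.negative_binomial(r, p)
            counts[:, j] = out
    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end"])
    return CoverageMatrix(
        windows=windows,
        counts=pd.DataFrame(counts, columns=strains),
        window_width=window,
    )


def synth_clonal_population(
    n_clusters: int = 5,
    strains_per_cluster: int = 6,
    n_cnvs: int = 20,
    n_snp_sites: int = 2000,
    cnv_gain_loss_rate: float = 0.2,
    max_intra_snps: int = 150,
    seed: int = 0,
) -> tuple:
    """Clonal clusters with cluster-private SNP backgrounds and CNVs that
    flip state along the clonal pedigree.

    Returns (copy-number DataFrame strains x CNVs, SNP genotype
    DataFrame strains x sites, cluster assignment dict).  Within a
    cluster, pairwise SNP distances stay below ``max_intra_snps`` by
    construction (each member carries at most ``max_intra_snps // 2``
    private mutations).  Each CNV of each member flips away from the
    founder state with probability ``cnv_gain_loss_rate``, so a
    positive rate produces segregating CNVs.
    """
    rng = np.random.default_rng(seed)
    strains, clusters = [], {}
    snp_rows, cn_rows = [], []
    founder_states = [0.0, 2.0, 4.0]
    for c in range(n_clusters):
        cid = f"cluster{c + 1}"
        founder_snp = rng.integers(0, 2, size=n_snp_sites)
        founder_cn = np.ones(n_cnvs)
        # a few CNVs start non-reference in this cluster's founder
        n_seed_cnv = rng.integers(0, max(1, n_cnvs // 4) + 1)
        for idx in rng.choice(n_cnvs, size=n_seed_cnv, replace=False):
            founder_cn[idx] = founder_states[int(rng.integers(0, 3))]
        for m in range(strains_per_cluster):
            name = f"{cid}_s{m + 1}"
            strains.append(name)
            clusters[name] = cid
            snp = founder_snp.copy()
            n_private = int(rng.integers(0, max_intra_snps // 2 + 1))
            flip = rng.choice(n_snp_sites, size=n_private, replace=False)
            snp[flip] = 1 - snp[flip]
            snp_rows.append(snp)
            cn = founder_cn.copy()
            flips = rng.random(n_cnvs) < cnv_gain_loss_rate
            for i in np.nonzero(flips)[0]:
                choices = [s for s in (0.0, 1.0, 2.0, 4.0) if s != cn[i]]
                cn[i] = choices[int(rng.integers(0, len(choices)))]
            cn_rows.append(cn)
    cn_df = pd.DataFrame(
        np.array(cn_rows), index=strains, columns=[f"cnv{i + 1}" for i in range(n_cnvs)]
    )
    snp_df = pd.DataFrame(np.array(snp_rows), index=strains)
    return cn_df, snp_df, clusters


def synth_viability_crosses(
    n_crosses: int = 58,
    snp_effect: float = 0.4,
    rearr_effect: float = 0.4,
    noise_sd: float = 0.15,
    snp_scale: int = 70000,
    rearr_scale: int = 12,
    cnv_scale: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross table where viability declines with SNP and rearrangement
    distance while CNV distance is independent noise.

    Viability = clip(1 - snp_effect * u_snp - rearr_effect * u_rearr +
    Gaussian noise, 0, 1) with u ~ Uniform(0, 1); distances are the u
    values scaled to realistic integer counts.  Effect sizes default to
    values with high power at n = 58 (see the methods note).
    """
    rng = np.random.default_rng(seed)
    u_snp = rng.random(n_crosses)
    u_rearr = rng.random(n_crosses)
    u_cnv = rng.random(n_crosses)
    viability = np.clip(
        1.0
        - snp_effect * u_snp
        - rearr_effect * u_rearr
        + rng.normal(0.0, noise_sd, size=n_crosses),
        0.0,
        1.0,
    )
    return pd.DataFrame(
        {
            "strain_a": [f"sA{i}" for i in range(n_crosses)],
            "strain_b": [f"sB{i}" for i in range(n_crosses)],
            "n_snp_diff": np.rint(u_snp * snp_scale).astype(int),
            "n_rearrangement_diff": np.rint(u_rearr * rearr_scale).astype(int),
            "n_cnv_diff": np.rint(u_cnv * cnv_scale).astype(int),
            "n_sv_diff": np.rint(u_rearr * rearr_scale + u_cnv * cnv_scale).astype(int),
            "viability": viability,
        }
    )
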