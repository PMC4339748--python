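"""Seeded synthetic PAR-CLIP and matched RNA-Seq data with known truth.

The generator emulates the transition structure of a 4SU PAR-CLIP
experiment on a random genome:

* *binding sites*: rectangular read pile-ups (default depth 50, width 30,
  read length 36) over sites placed in short transcripts; within a site,
  every transcript-orientation T converts to C independently per read with
  the site's crosslink probability, drawn from a signal range (default
  Uniform(0.25, 0.6));
* *transcript background*: low-coverage reads over the site-containing
  transcripts plus a set of abundant background transcripts with no sites
  (non-specific RNA carried through the immunoprecipitation);
* *SNPs*: fixed alternate alleles (RSF ~ 1) with ref->alt pairs drawn
  uniformly over the 12 ordered substitutions, shared with the RNA-Seq
  simulation;
* *sequencing errors*: i.i.d. per-base errors plus per-position error
  hotspots (elevated recurrent error probability toward a fixed alternate
  base) shared between the PAR-CLIP and RNA-Seq simulations — recurrent
  artifacts are what makes matched RNA-Seq informative about false
  positives.

The matched RNA-Seq simulation covers every transcript uniformly with the
same SNP and error model but no crosslink conversions. Reads are emitted
pre-aligned at their true positions as coordinate-sorted, indexed BAM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .errors import ParclipError
from .ingest import reverse_complement

_BASES = "ACGT"
_OTHER = {b: [c for c in _BASES if c != b] for b in _BASES}


@dataclass
class BindingSite:
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    p: float  # per-read per-T crosslink conversion probability


@dataclass
class Transcript:
    chrom: str
    strand: str
    start: int
    end: int
    parclip_coverage: float
    rnaseq_coverage: float


@dataclass
class Snp:
    chrom: str
    pos: int
    alt: str  # forward-strand alternate base


@dataclass
class ErrorHotspot:
    chrom: str
    pos: int
    alt: str  # forward-strand alternate base
    rate: float  # per-read substitution probability


@dataclass
class SimTruth:
    """Complete description of a simulated experiment."""

    genome: Dict[str, str]
    sites: List[BindingSite]
    transcripts: List[Transcript]
    snps: List[Snp] = field(default_factory=list)
    hotspots: List[ErrorHotspot] = field(default_factory=list)
    error_rate: float = 0.002
    read_length: int = 36
    site_depth: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.sites:
            if not 0.0 <= s.p <= 1.0:
                raise ParclipError("site conversion probability outside [0,1]")
        by_strand: Dict[Tuple[str, str], List[BindingSite]] = {}
        for s in self.sites:
            by_strand.setdefault((s.chrom, s.strand), []).append(s)
        for group in by_strand.values():
            group = sorted(group, key=lambda s: s.start)
            for a, b in zip(group, group[1:]):
                if b.start < a.end:
                    raise ParclipError("binding sites overlap on one strand")

    @cached_property
    def snp_map(self) -> Dict[str, Dict[int, str]]:
        out: Dict[str, Dict[int, str]] = {}
        for s in self.snps:
            out.setdefault(s.chrom, {})[s.pos] = s.alt
        return out

    @cached_property
    def hotspot_map(self) -> Dict[str, Dict[int, Tuple[str, float]]]:
        out: Dict[str, Dict[int, Tuple[str, float]]] = {}
        for h in self.hotspots:
            out.setdefault(h.chrom, {})[h.pos] = (h.alt, h.rate)
        return out

    def sites_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "strand": s.strand,
                    "start": s.start,
                    "end": s.end,
                    "p": s.p,
                }
                for s in self.sites
            ]
        )

    def write_genome(self, path: str) -> str:
        import pyfaidx

        with open(path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        pyfaidx.Faidx(str(path))
        return str(path)


def simulate_genome(
    n_chroms: int = 1,
    length: int = 150_000,
    gc: float = 0.45,
    seed: int = 0,
) -> Dict[str, str]:
    """Seeded i.i.d. random genome with the requested GC content."""
    if length < 1000:
        raise ParclipError("chromosome length must be >= 1000")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for c in range(n_chroms):
        idx = rng.choice(4, size=length, p=probs)
        genome[f"chr{c + 1}"] = "".join(np.array(list(_BASES))[idx])
    return genome


def default_truth(
    seed: int = 0,
    n_sites: int = 200,
    n_background_transcripts: int = 30,
    genome_length: int = 150_000,
    gc: float = 0.45,
    site_width: int = 30,
    site_depth: int = 50,
    read_length: int = 36,
    transcript_length: int = 150,
    background_transcript_length: int = 300,
    site_transcript_parclip_coverage: float = 3.0,
    background_parclip_coverage: float = 25.0,
    rnaseq_coverage: float = 30.0,
    signal_rsf_range: Tuple[float, float] = (0.25, 0.6),
    n_snps: int = 20,
    error_rate: float = 0.002,
    hotspot_fraction: float = 0.01,
    hotspot_rate_range: Tuple[float, float] = (0.02, 0.10),
) -> SimTruth:
    """The study conditions used throughout the test suite.

    Lays transcripts down left to right with gaps >= 100 nt, centres one
    binding site in each of the first ``n_sites`` transcripts, then appends
    abundant background transcripts without sites.
    """
    if site_width > read_length:
        raise ParclipError("site width must not exceed read length")
    rng = np.random.default_rng(seed)
    genome = simulate_genome(1, genome_length, gc, seed=int(rng.integers(2**31)))
    chrom = "chr1"
    transcripts: List[Transcript] = []
    sites: List[BindingSite] = []
    cursor = int(rng.integers(50, 150))
    for _ in range(n_sites):
        strand = "+" if rng.random() < 0.5 else "-"
        t_start = cursor
        t_end = t_start + transcript_length
        transcripts.append(
            Transcript(
                chrom, strand, t_start, t_end,
                parclip_coverage=site_transcript_parclip_coverage,
                rnaseq_coverage=rnaseq_coverage,
            )
        )
        s_start = t_start + (transcript_length - site_width) // 2
        sites.append(
            BindingSite(
                chrom, strand, s_start, s_start + site_width,
                p=float(rng.uniform(*signal_rsf_range)),
            )
        )
        cursor = t_end + 100 + int(rng.integers(0, 100))
    for _ in range(n_background_transcripts):
        strand = "+" if rng.random() < 0.5 else "-"
        t_start = cursor
        t_end = t_start + background_transcript_length
        transcripts.append(
            Transcript(
                chrom, strand, t_start, t_end,
                parclip_coverage=background_parclip_coverage,
                rnaseq_coverage=rnaseq_coverage,
            )
        )
        cursor = t_end + 100 + int(rng.integers(0, 100))
    if cursor >= genome_length:
        raise ParclipError(
            f"genome too short for layout (need >= {cursor}, have {genome_length})"
        )

    seq = genome[chrom]
    in_site = np.zeros(genome_length, dtype=bool)
    for s in sites:
        in_site[s.start : s.end] = True
    transcript_pos: List[Tuple[int, str]] = []
    for t in transcripts:
        for pos in range(t.start, t.end):
            if not in_site[pos]:
                transcript_pos.append((pos, t.strand))
    snps: List[Snp] = []
    snp_idx = rng.choice(len(transcript_pos), size=n_snps, replace=False)
    for i in sorted(snp_idx):
        pos, _ = transcript_pos[i]
        ref = seq[pos]
        alt = _OTHER.get(ref, ["A"])[int(rng.integers(3))]
        snps.append(Snp(chrom, pos, alt))
    snp_positions = {s.pos for s in snps}

    hotspots: List[ErrorHotspot] = []
    n_hot = int(round(hotspot_fraction * len(transcript_pos)))
    hot_idx = rng.choice(len(transcript_pos), size=n_hot, replace=False)
    for i in sorted(hot_idx):
        pos, _ = transcript_pos[i]
        if pos in snp_positions:
            continue
        ref = seq[pos]
        alt = _OTHER.get(ref, ["A"])[int(rng.integers(3))]
        hotspots.append(
            ErrorHotspot(chrom, pos, alt, float(rng.uniform(*hotspot_rate_range)))
        )

    return SimTruth(
        genome=genome,
        sites=sites,
        transcripts=transcripts,
        snps=snps,
        hotspots=hotspots,
        error_rate=error_rate,
        read_length=read_length,
        site_depth=site_depth,
        seed=seed,
    )


# ------------------------------------------------------------- read emission


def _mutate(
    truth: SimTruth,
    chrom: str,
    start: int,
    bases: List[str],
    rng: np.random.Generator,
    site: Optional[BindingSite] = None,
) -> List[str]:
    """Apply SNPs, crosslink conversions, hotspot and i.i.d. errors in place.

    Crosslink conversions act on transcript-orientation T: forward T->C on
    plus-strand sites, forward A->G on minus-strand sites.
    """
    snps = truth.snp_map.get(chrom, {})
    hots = truth.hotspot_map.get(chrom, {})
    L = len(bases)
    for i in range(L):
        pos = start + i
        alt = snps.get(pos)
        if alt is not None:
            bases[i] = alt
    if site is not None:
        ref, conv = ("T", "C") if site.strand == "+" else ("A", "G")
        lo = max(start, site.start)
        hi = min(start + L, site.end)
        for pos in range(lo, hi):
            i = pos - start
            if bases[i] == ref and rng.random() < site.p:
                bases[i] = conv
    for i in range(L):
        pos = start + i
        hot = hots.get(pos)
        if hot is not None and rng.random() < hot[1]:
            bases[i] = hot[0]
        if rng.random() < truth.error_rate:
            bases[i] = _OTHER[bases[i]][int(rng.integers(3))] if bases[i] in _OTHER else bases[i]
    return bases


def _transcript_reads(
    truth: SimTruth,
    t: Transcript,
    coverage: float,
    rng: np.random.Generator,
    tag: str,
    with_crosslink: bool,
) -> List[Tuple[str, int, str, str, str]]:
    """Uniformly placed reads over a transcript at the requested coverage."""
    L = truth.read_length
    span = t.end - t.start
    if span < L or coverage <= 0:
        return []
    n_reads = int(round(coverage * span / L))
    seq = truth.genome[t.chrom]
    site = None
    if with_crosslink:
        for s in truth.sites:
            if s.chrom == t.chrom and s.strand == t.strand and s.start >= t.start and s.end <= t.end:
                site = s
                break
    reads = []
    starts = rng.integers(t.start, t.end - L + 1, size=n_reads)
    for j, rstart in enumerate(sorted(starts.tolist())):
        bases = list(seq[rstart : rstart + L])
        _mutate(truth, t.chrom, rstart, bases, rng, site=site)
        reads.append((t.chrom, rstart, t.strand, "".join(bases), f"{tag}_{t.start}_{j}"))
    return reads


def _site_reads(
    truth: SimTruth, site: BindingSite, rng: np.random.Generator, tag: str
) -> List[Tuple[str, int, str, str, str]]:
    """``site_depth`` reads, each fully containing the site (rectangular
    pile-up with ragged read edges)."""
    L = truth.read_length
    seq = truth.genome[site.chrom]
    lo = site.end - L
    hi = site.start
    reads = []
    for j in range(truth.site_depth):
        rstart = int(rng.integers(lo, hi + 1))
        bases = list(seq[rstart : rstart + L])
        _mutate(truth, site.chrom, rstart, bases, rng, site=site)
        reads.append(
            (site.chrom, rstart, site.strand, "".join(bases), f"{tag}_{site.start}_{j}")
        )
    return reads


def _write_bam(
    reads: Sequence[Tuple[str, int, str, str, str]],
    genome: Dict[str, str],
    path: str,
) -> str:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    }
    chrom_ids = {c: i for i, c in enumerate(genome)}
    ordered = sorted(reads, key=lambda r: (chrom_ids[r[0]], r[1], r[4]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for chrom, start, strand, seq, name in ordered:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 16 if strand == "-" else 0
            a.reference_id = chrom_ids[chrom]
            a.reference_start = start
            a.mapping_quality = 255
            a.cigartuples = [(0, len(seq))]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            bam.write(a)
    pysam.index(str(path))
    return str(path)


def simulate_parclip(
    truth: SimTruth, out_bam: str, truth_tsv: Optional[str] = None
) -> str:
    """Emit the PAR-CLIP alignment: site pile-ups with crosslink conversions
    plus transcript background, SNPs and sequencing errors."""
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    reads: List[Tuple[str, int, str, str, str]] = []
    for site in truth.sites:
        reads.extend(_site_reads(truth, site, rng, "pc_site"))
    for t in truth.transcripts:
        reads.extend(
            _transcript_reads(
                truth, t, t.parclip_coverage, rng, "pc_bg", with_crosslink=True
            )
        )
    if truth_tsv is not None:
        self_table = truth.sites_table()
        self_table.to_csv(truth_tsv, sep="\t", index=False)
    return _write_bam(reads, truth.genome, out_bam)


def simulate_rnaseq(truth: SimTruth, out_bam: str) -> str:
    """Matched RNA-Seq: uniform transcript coverage, shared SNPs and error
    model, no crosslink-induced conversions."""
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
    reads: List[Tuple[str, int, str, str, str]] = []
    for t in truth.transcripts:
        reads.extend(
            _transcript_reads(
                truth, t, t.rnaseq_coverage, rng, "rna", with_crosslink=False
            )
        )
    return _write_bam(reads, truth.genome, out_bam)
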