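"""Strand-specific coverage and substitution tracks from aligned PAR-CLIP reads.

Builds the three per-position integer tracks the boundary algorithm works on
(coverage ``C``, alignment starts ``S``, alignment ends ``E``) and the
per-position substitution profile (coverage ``z`` and counts ``y[ref->read]``
for the 12 ordered base pairs) that feeds the transition mixture model.

All coordinates are 0-based, half-open internally. Substitutions are stored
in transcript orientation: for a minus-strand alignment both the reference
and read base are complemented, so "TC" always denotes the 4SU-induced
T->C transition regardless of the genomic strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import pysam

from .errors import IngestError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: the 12 ordered reference->read base pairs, transcript orientation
SUBSTITUTION_TYPES = tuple(
    a + b for a in "ACGT" for b in "ACGT" if a != b
)


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CoverageTrack:
    """Per-strand coverage and coverage-difference tracks for one chromosome.

    ``C[i]`` is the number of alignments covering position ``origin + i``;
    ``S[i]``/``E[i]`` count alignments whose first/last covered base is that
    position. The conservation identity
    ``C[i] = cumsum(S)[i] - cumsum(E)[i-1]`` holds whenever alignments are
    gapless; deletions and reference skips subtract from ``C`` only, so the
    identity is maintained by treating each gapless block consistently
    (we count S at the first covered base and E at the last covered base of
    the whole alignment, and C only over aligned blocks).
    """

    chrom: str
    strand: str
    C: np.ndarray
    S: np.ndarray
    E: np.ndarray
    origin: int = 0
    n_alignments: int = 0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise IngestError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.C)


@dataclass
class SubstitutionProfile:
    """Per-position aligned coverage ``z`` and substitution counts ``y``.

    ``y`` maps a substitution type (e.g. ``"TC"``) to a sparse
    ``{position: count}`` dict, in transcript orientation.
    """

    chrom: str
    strand: str
    z: np.ndarray
    y: Dict[str, Dict[int, int]] = field(default_factory=dict)

    def counts(self, subst_type: str) -> Dict[int, int]:
        return self.y.get(subst_type, {})

    def rsf(self, pos: int, subst_type: str) -> float:
        zz = int(self.z[pos])
        if zz == 0:
            return 0.0
        return self.counts(subst_type).get(pos, 0) / zz


def _aligned_blocks(read: pysam.AlignedSegment) -> List[Tuple[int, int, int]]:
    """Gapless aligned blocks as (query_start, ref_start, length).

    M/=/X consume both sequences; D/N open a coverage gap; I/S consume the
    query only; H/P consume neither.
    """
    blocks = []
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            blocks.append((qpos, rpos, length))
            qpos += length
            rpos += length
        elif op in (2, 3):  # D, N
            rpos += length
        elif op in (1, 4):  # I, S
            qpos += length
        # 5 (H), 6 (P): nothing
    return blocks


def _read_strand(read: pysam.AlignedSegment) -> str:
    return "-" if read.is_reverse else "+"


def _usable(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    if read.is_unmapped or read.cigartuples is None:
        logger.warning("skipping unmapped/malformed record %s", read.query_name)
        return False
    if read.is_secondary or read.is_supplementary:
        return False
    if min_mapq and read.mapping_quality < min_mapq:
        return False
    return True


def build_coverage(
    alignments: Iterable[pysam.AlignedSegment],
    chrom: str,
    strand: str,
    length: int,
    min_mapq: int = 0,
) -> CoverageTrack:
    """Build the C/S/E track for one chromosome and strand.

    ``alignments`` is any iterable of mapped records (e.g. an
    ``AlignmentFile.fetch`` iterator); records on the other strand or other
    chromosomes are ignored so callers can pass an unfiltered iterator.
    """
    if strand not in STRANDS:
        raise IngestError(f"invalid strand {strand!r}")
    C = np.zeros(length, dtype=np.int64)
    S = np.zeros(length, dtype=np.int64)
    E = np.zeros(length, dtype=np.int64)
    n = 0
    for read in alignments:
        if not _usable(read, min_mapq):
            continue
        if read.reference_name != chrom or _read_strand(read) != strand:
            continue
        blocks = _aligned_blocks(read)
        if not blocks:
            continue
        if blocks[-1][1] + blocks[-1][2] > length:
            raise IngestError(
                f"alignment {read.query_name} extends past end of {chrom}"
            )
        for _, rstart, blen in blocks:
            C[rstart : rstart + blen] += 1
        S[blocks[0][1]] += 1
        E[blocks[-1][1] + blocks[-1][2] - 1] += 1
        n += 1
    return CoverageTrack(chrom=chrom, strand=strand, C=C, S=S, E=E, n_alignments=n)


def count_substitutions(
    alignments: Iterable[pysam.AlignedSegment],
    reference: str,
    chrom: str,
    strand: str,
    min_mapq: int = 0,
) -> SubstitutionProfile:
    """Count per-position substitutions against ``reference`` (one chromosome).

    Positions where the reference base is N contribute to neither ``y`` nor
    ``z``. Insertions, deletions and clipped bases are never counted.
    """
    refseq = reference.upper()
    length = len(refseq)
    z = np.zeros(length, dtype=np.int64)
    y: Dict[str, Dict[int, int]] = {}
    minus = strand == "-"
    for read in alignments:
        if not _usable(read, min_mapq):
            continue
        if read.reference_name != chrom or _read_strand(read) != strand:
            continue
        qseq = read.query_sequence
        if qseq is None:
            logger.warning("skipping record without sequence %s", read.query_name)
            continue
        qseq = qseq.upper()
        for qstart, rstart, blen in _aligned_blocks(read):
            for k in range(blen):
                rpos = rstart + k
                rbase = refseq[rpos]
                if rbase == "N":
                    continue
                z[rpos] += 1
                qbase = qseq[qstart + k]
                if qbase == rbase or qbase == "N":
                    continue
                if minus:
                    key = complement(rbase) + complement(qbase)
                else:
                    key = rbase + qbase
                y.setdefault(key, {})
                y[key][rpos] = y[key].get(rpos, 0) + 1
    return SubstitutionProfile(chrom=chrom, strand=strand, z=z, y=y)


def extract_sites(
    profile: SubstitutionProfile,
    subst_type: str = "TC",
    min_cov: int = 20,
):
    """One :class:`~parclipper.model.TransitionSite` per position with
    ``y[subst_type] >= 1`` and coverage ``z >= min_cov``."""
    from .model import TransitionSite

    if min_cov < 1:
        raise IngestError("min_cov must be >= 1")
    sites = []
    for pos, count in sorted(profile.counts(subst_type).items()):
        zz = int(profile.z[pos])
        if count >= 1 and zz >= min_cov:
            sites.append(
                TransitionSite(
                    chrom=profile.chrom,
                    strand=profile.strand,
                    pos=pos,
                    y=int(count),
                    z=zz,
                )
            )
    return sites


def load_genome(path_or_mapping) -> Mapping[str, str]:
    """Return a chrom -> sequence mapping from a FASTA path or pass through."""
    if isinstance(path_or_mapping, Mapping):
        return path_or_mapping
    import pyfaidx

    fa = pyfaidx.Fasta(str(path_or_mapping), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def build_tracks(
    bam_path: str,
    chrom_lengths: Mapping[str, int] | None = None,
    min_mapq: int = 0,
) -> Dict[Tuple[str, str], CoverageTrack]:
    """C/S/E tracks for every (chrom, strand) present in a BAM/SAM file."""
    tracks: Dict[Tuple[str, str], CoverageTrack] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        lengths = chrom_lengths or dict(zip(bam.references, bam.lengths))
        for chrom, length in lengths.items():
            reads = list(bam.fetch(chrom)) if bam.has_index() else None
            if reads is None:
                bam.reset()
                reads = [r for r in bam if r.reference_name == chrom]
            for strand in STRANDS:
                tracks[(chrom, strand)] = build_coverage(
                    reads, chrom, strand, length, min_mapq=min_mapq
                )
    return tracks


def build_profiles(
    bam_path: str,
    genome: Mapping[str, str],
    min_mapq: int = 0,
) -> Dict[Tuple[str, str], SubstitutionProfile]:
    """Substitution profiles for every (chrom, strand) in a BAM/SAM file."""
    profiles: Dict[Tuple[str, str], SubstitutionProfile] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for chrom in bam.references:
            if chrom not in genome:
                raise IngestError(f"chromosome {chrom} missing from genome")
            reads = list(bam.fetch(chrom)) if bam.has_index() else None
            if reads is None:
                bam.reset()
                reads = [r for r in bam if r.reference_name == chrom]
            for strand in STRANDS:
                profiles[(chrom, strand)] = count_substitutions(
                    reads, genome[chrom], chrom, strand, min_mapq=min_mapq
                )
    return profiles


def write_bedgraph(track: CoverageTrack, which: str, path: str) -> None:
    """Dump one of the C/S/E tracks as bedGraph for browser inspection."""
    arr = getattr(track, which)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{which} {track.chrom}{track.strand}"\n')
        start = None
        value = 0
        for i, v in enumerate(arr):
            if v != value:
                if value != 0 and start is not None:
                    fh.write(f"{track.chrom}\t{start}\t{i}\t{value}\n")
                start, value = i, int(v)
        if value != 0 and start is not None:
            fh.write(f"{track.chrom}\t{start}\t{len(arr)}\t{value}\n")
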