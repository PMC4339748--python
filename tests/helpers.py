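"""Shared test utilities: independent oracles and truth bookkeeping."""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pysam

from parclipper.ingest import CoverageTrack
from parclipper.simulate import SimTruth

# ------------------------------------------------------------ read building


def make_header(chroms: Dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": n} for c, n in chroms.items()],
        }
    )


def make_read(
    header: pysam.AlignmentHeader,
    chrom: str,
    start: int,
    seq: str,
    strand: str = "+",
    cigar=None,
    name: str = "r",
    mapq: int = 60,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 16 if strand == "-" else 0
    a.reference_id = list(header.references).index(chrom)
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigartuples = cigar or [(0, len(seq))]
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


# ----------------------------------------------- brute-force MRN oracle


def brute_force_optimal(
    S: Sequence[int],
    E: Sequence[int],
    i_t: int,
    delta_s: int,
    delta_e: int,
) -> Tuple[int, int]:
    """Exhaustive reference solution for the boundary search on one window.

    Recomputes candidate enumeration, rank vectors and the norm/width/start
    tie-breaking with plain loops, independent of the library implementation.
    Returns the winning (start, end) pair (inclusive coordinates).
    """
    n = len(S)
    starts = [i for i in range(0, i_t + 1) if S[i] >= delta_s] or [0]
    ends = [i for i in range(i_t, n) if E[i] >= delta_e] or [n - 1]
    cands = [(k, l) for k in starts for l in ends]

    # start ranks: decreasing S, ties by increasing position
    start_rank = {}
    remaining = list(dict.fromkeys(starts))
    rank = 0
    while remaining:
        best = remaining[0]
        for p in remaining[1:]:
            if S[p] > S[best] or (S[p] == S[best] and p < best):
                best = p
        start_rank[best] = rank
        remaining.remove(best)
        rank += 1
    # end ranks: decreasing E, ties by decreasing position
    end_rank = {}
    remaining = list(dict.fromkeys(ends))
    rank = 0
    while remaining:
        best = remaining[0]
        for p in remaining[1:]:
            if E[p] > E[best] or (E[p] == E[best] and p > best):
                best = p
        end_rank[best] = rank
        remaining.remove(best)
        rank += 1
    # width ranks: increasing width, ties share the minimum rank
    widths = [l - k + 1 for k, l in cands]
    width_rank = [sum(1 for w2 in widths if w2 < w) for w in widths]

    best_pair = None
    best_key = None
    for (k, l), rw in zip(cands, width_rank):
        norm2 = start_rank[k] ** 2 + end_rank[l] ** 2 + rw**2
        key = (norm2, l - k + 1, k)
        if best_key is None or key < best_key:
            best_key = key
            best_pair = (k, l)
    return best_pair


def random_window(rng: np.random.Generator):
    """A random small S/E window plus thresholds for oracle comparison."""
    n = int(rng.integers(3, 61))
    S = rng.poisson(1.0, size=n).astype(int)
    E = rng.poisson(1.0, size=n).astype(int)
    hot = rng.integers(0, n, size=4)
    S[hot[:2] % n] += rng.integers(2, 9, size=2).astype(int)
    E[hot[2:] % n] += rng.integers(2, 9, size=2).astype(int)
    i_t = int(rng.integers(0, n))
    delta_s = int(rng.integers(1, 5))
    delta_e = int(rng.integers(1, 5))
    return S, E, i_t, delta_s, delta_e


def track_from_se(S, E, chrom="chr1", strand="+") -> CoverageTrack:
    """CoverageTrack with all-positive C so the whole array is one window."""
    S = np.asarray(S, dtype=np.int64)
    E = np.asarray(E, dtype=np.int64)
    C = np.ones_like(S)
    return CoverageTrack(chrom=chrom, strand=strand, C=C, S=S, E=E)


# ----------------------------------------------------------- truth helpers


def signal_positions(truth: SimTruth) -> Set[Tuple[str, str, int]]:
    """(chrom, strand, pos) of every crosslinkable base inside planted sites."""
    out = set()
    for s in truth.sites:
        ref = "T" if s.strand == "+" else "A"
        seq = truth.genome[s.chrom][s.start : s.end]
        for i, b in enumerate(seq):
            if b == ref:
                out.add((s.chrom, s.strand, s.start + i))
    return out


def true_lambda(truth: SimTruth, target_sites) -> float:
    """Fraction of observed target-transition sites not explained by
    planted crosslinking."""
    sig = signal_positions(truth)
    labels = [(t.chrom, t.strand, t.pos) in sig for t in target_sites]
    return 1.0 - float(np.mean(labels))


def recovery_stats(truth: SimTruth, clusters) -> Tuple[float, float]:
    """(fraction of planted sites overlapped by >=1 cluster,
    median per-side boundary error of the overlapping clusters)."""
    by_key: Dict[Tuple[str, str], List] = {}
    for cl in clusters:
        by_key.setdefault((cl.chrom, cl.strand), []).append(cl)
    recovered = 0
    errors: List[int] = []
    for s in truth.sites:
        hit = None
        for cl in by_key.get((s.chrom, s.strand), []):
            if cl.start < s.end and cl.end > s.start:
                hit = cl
                break
        if hit is not None:
            recovered += 1
            errors.append(abs(hit.start - s.start))
            errors.append(abs(hit.end - s.end))
    frac = recovered / len(truth.sites)
    med = float(np.median(errors)) if errors else float("nan")
    return frac, med
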