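"""Mini-Rank-Norm (MRN) cluster boundary identification.

Binding-site coverage is expected to look like a sharply peaked rectangle:
many alignments start just upstream and end just downstream of the protected
region. The algorithm therefore works on the coverage-difference tracks
S (alignment starts) and E (alignment ends) around each high-confidence
transition (hcT):

1. *Noise threshold.* Normalized non-zero coverage fluctuations D+ are
   sampled in windows of +-n around a random subset of hcTs and modelled as
   a two-component unequal-variance Gaussian mixture (k=1 noise, k=2 sharp
   jumps). The crossover coefficient c — the smallest observed fluctuation
   whose responsibility favours the jump component — scales a per-window
   threshold delta_s = ceil(c * max S(w)), delta_e = ceil(c * max E(w)).
   Alternatively a global threshold floor(0.1 * max(m1, m2)) can be used.
2. *Candidate enumeration.* Within the largest non-zero coverage window
   containing the hcT, every suprathreshold start upstream and end
   downstream of the hcT defines a candidate cluster (k, l).
3. *Rank vectors.* Candidates are represented by the ranks of their boundary
   signal (start count, end count, both 0 = strongest) and width
   (0 = shortest, ties share the minimum rank).
4. *Optimal solution.* The candidate closest to the ideal rectangle
   O = (0, 0, 0) in Euclidean norm wins; norm ties go to the shortest
   candidate, remaining ties to the 5'-most start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.mixture import GaussianMixture

from .errors import MrnError
from .ingest import CoverageTrack
from .model import MixtureModel, TransitionSite

logger = logging.getLogger(__name__)


@dataclass
class NoiseModel:
    """Two-Gaussian fit of normalized coverage fluctuations.

    Component 1 (mu1, sd1) models noise, component 2 sharp jumps; ``c`` is
    the crossover coefficient min{x in D+ : p(k=2|x) >= p(k=1|x)}.
    """

    mu1: float
    sd1: float
    mu2: float
    sd2: float
    w1: float
    c: float


@dataclass
class MrnConfig:
    """Tunables of the boundary search.

    ``n_sample``: number of hcTs sampled for noise estimation (N);
    ``half_window``: half-width of the sampling windows (n);
    ``m1``/``m2``: minimum coverage requirement and coverage mode at hcTs
    used by the global threshold (m2 is measured from the data when unset).
    """

    n_sample: int = 1000
    half_window: int = 25
    threshold_mode: str = "local"
    m1: int = 20
    m2: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sample < 1 or self.half_window < 1:
            raise MrnError("n_sample and half_window must be >= 1")
        if self.threshold_mode not in ("local", "global"):
            raise MrnError(f"unknown threshold mode {self.threshold_mode!r}")


@dataclass
class CandidateCluster:
    k: int  # start position (genomic, inclusive)
    l: int  # end position (genomic, inclusive)
    n_s: int
    n_e: int
    r_s: int = -1
    r_e: int = -1
    r_w: int = -1

    @property
    def width(self) -> int:
        return self.l - self.k + 1

    @property
    def rank_vector(self) -> Tuple[int, int, int]:
        return (self.r_s, self.r_e, self.r_w)

    @property
    def norm2(self) -> int:
        return self.r_s**2 + self.r_e**2 + self.r_w**2


@dataclass
class Cluster:
    """A called binding site: strand-specific interval with its member hcTs.

    Coordinates are 0-based half-open. ``rel_log_odds`` is the sum of member
    log-odds normalized by the number of crosslinkable bases (T in transcript
    orientation) in the cluster sequence; ``None`` when the sequence contains
    no crosslinkable base.
    """

    chrom: str
    strand: str
    start: int
    end: int
    hcts: List[TransitionSite] = field(default_factory=list)
    n_crosslinkable: int = 0
    rel_log_odds: Optional[float] = None
    rank_vector: Optional[Tuple[int, int, int]] = None

    @property
    def width(self) -> int:
        return self.end - self.start


def nonzero_window(track: CoverageTrack, pos: int) -> Tuple[int, int]:
    """Maximal run of consecutive positions with C > 0 containing ``pos``
    (inclusive bounds)."""
    C = track.C
    if pos < 0 or pos >= len(C) or C[pos] <= 0:
        raise MrnError(f"hcT at {track.chrom}:{pos} outside covered region")
    lo = pos
    while lo > 0 and C[lo - 1] > 0:
        lo -= 1
    hi = pos
    while hi < len(C) - 1 and C[hi + 1] > 0:
        hi += 1
    return lo, hi


def fit_noise(dplus: Sequence[float]) -> NoiseModel:
    """EM fit of the two-component Gaussian mixture on D+ and its crossover.

    Initialized from the 25th/75th percentiles, log-likelihood tolerance
    1e-8, at most 500 iterations, variance floor 1e-6.
    """
    d = np.asarray(dplus, dtype=float)
    d = d[d > 0]
    if d.size < 10:
        raise MrnError("insufficient fluctuation data (|D+| < 10)")
    X = d.reshape(-1, 1)
    means_init = np.percentile(d, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=1e-8,
        reg_covar=1e-6,
        max_iter=500,
        means_init=means_init,
        weights_init=np.array([0.5, 0.5]),
        random_state=0,
    ).fit(X)
    if not gm.converged_:
        raise MrnError(
            "noise EM did not converge after 500 iterations "
            f"(lower bound {gm.lower_bound_:.6g})"
        )
    mus = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    order = np.argsort(mus)
    mu1, mu2 = float(mus[order[0]]), float(mus[order[1]])
    sd1, sd2 = float(sds[order[0]]), float(sds[order[1]])
    w1 = float(gm.weights_[order[0]])
    if abs(mu2 - mu1) < max(sd1, sd2):
        raise MrnError(
            "noise mixture degenerate: components are not separated "
            f"(mu1={mu1:.4g}, mu2={mu2:.4g}, sd1={sd1:.4g}, sd2={sd2:.4g})"
        )
    resp = gm.predict_proba(X)
    k2 = resp[:, order[1]]
    crossing = d[k2 >= 0.5]
    if crossing.size == 0:
        raise MrnError("no responsibility crossover found in D+")
    return NoiseModel(mu1=mu1, sd1=sd1, mu2=mu2, sd2=sd2, w1=w1, c=float(crossing.min()))


def estimate_noise(
    tracks: Mapping[Tuple[str, str], CoverageTrack],
    hcts: Sequence[TransitionSite],
    cfg: MrnConfig,
) -> NoiseModel:
    """Sample fluctuations around hcTs and fit the noise mixture.

    Draws min(N, |hcTs|) hcTs without replacement (seeded); in each window
    (pos - n, pos + n) the S and E values are normalized by the single
    window maximum over both tracks and non-zero ratios are pooled into D+.
    """
    if not hcts:
        raise MrnError("no hcTs to estimate noise from")
    rng = np.random.default_rng(cfg.seed)
    idx = np.arange(len(hcts))
    if len(hcts) > cfg.n_sample:
        idx = rng.choice(idx, size=cfg.n_sample, replace=False)
    dplus: List[float] = []
    n = cfg.half_window
    for i in sorted(idx):
        s = hcts[i]
        track = tracks[(s.chrom, s.strand)]
        lo = max(0, s.pos - n)
        hi = min(len(track.C), s.pos + n + 1)
        sv = track.S[lo:hi]
        ev = track.E[lo:hi]
        m = max(sv.max(initial=0), ev.max(initial=0))
        if m <= 0:
            continue
        for arr in (sv, ev):
            nz = arr[arr > 0]
            dplus.extend((nz / m).tolist())
    if len(dplus) < 10:
        raise MrnError("insufficient fluctuation data (|D+| < 10)")
    return fit_noise(dplus)


def local_threshold(
    noise: NoiseModel, track: CoverageTrack, w: Tuple[int, int]
) -> Tuple[int, int]:
    """Side-specific thresholds delta_s/delta_e for a window (clamped >= 1)."""
    lo, hi = w
    max_s = int(track.S[lo : hi + 1].max(initial=0))
    max_e = int(track.E[lo : hi + 1].max(initial=0))
    ds = max(1, math.ceil(noise.c * max_s))
    de = max(1, math.ceil(noise.c * max_e))
    return ds, de


def global_threshold(m1: int, m2: int) -> int:
    """floor(0.1 * max(m1, m2)), clamped to >= 1."""
    if m1 < 0 or m2 < 0:
        raise MrnError("coverage summaries must be non-negative")
    return max(1, math.floor(0.1 * max(m1, m2)))


def enumerate_candidates(
    track: CoverageTrack,
    pos: int,
    w: Tuple[int, int],
    delta_s: int,
    delta_e: int,
) -> List[CandidateCluster]:
    """All (start, end) pairs of suprathreshold boundaries flanking the hcT.

    When no start (end) reaches the threshold, the window start (end) is the
    sole boundary on that side, so every hcT yields at least one candidate.
    """
    lo, hi = w
    if not (lo <= pos <= hi):
        raise MrnError("hcT outside its window")
    starts = [i for i in range(lo, pos + 1) if track.S[i] >= delta_s]
    ends = [i for i in range(pos, hi + 1) if track.E[i] >= delta_e]
    if not starts:
        starts = [lo]
    if not ends:
        ends = [hi]
    return [
        CandidateCluster(k=k, l=l, n_s=int(track.S[k]), n_e=int(track.E[l]))
        for k in starts
        for l in ends
    ]


def rank_candidates(cands: List[CandidateCluster]) -> List[CandidateCluster]:
    """Attach the rank vector (r_s, r_e, r_w) to every candidate.

    Start positions are ranked by decreasing start count, ties 5'->3';
    end positions by decreasing end count, ties 3'->5'; widths by increasing
    width with ties sharing the minimum rank. All ranks are 0-based with
    0 = best.
    """
    if not cands:
        raise MrnError("no candidates to rank")
    start_info = {c.k: c.n_s for c in cands}
    end_info = {c.l: c.n_e for c in cands}
    start_order = sorted(start_info, key=lambda p: (-start_info[p], p))
    end_order = sorted(end_info, key=lambda p: (-end_info[p], -p))
    r_s = {p: r for r, p in enumerate(start_order)}
    r_e = {p: r for r, p in enumerate(end_order)}
    widths = np.array([c.width for c in cands])
    r_w = rankdata(widths, method="min").astype(int) - 1
    for c, rw in zip(cands, r_w):
        c.r_s = r_s[c.k]
        c.r_e = r_e[c.l]
        c.r_w = int(rw)
    return cands


def select_optimal(cands: Sequence[CandidateCluster]) -> CandidateCluster:
    """Candidate with minimal ||r||2; ties -> shortest, then 5'-most start."""
    if not cands:
        raise MrnError("no candidates to select from")
    return min(cands, key=lambda c: (c.norm2, c.width, c.k))


def _coverage_mode(tracks, hcts) -> int:
    vals = [int(tracks[(s.chrom, s.strand)].C[s.pos]) for s in hcts]
    values, counts = np.unique(vals, return_counts=True)
    return int(values[np.argmax(counts)])


def call_clusters(
    tracks: Mapping[Tuple[str, str], CoverageTrack],
    hcts: Sequence[TransitionSite],
    model: Optional[MixtureModel],
    genome: Mapping[str, str],
    cfg: Optional[MrnConfig] = None,
) -> List[Cluster]:
    """Run the full MRN boundary search for every hcT and merge duplicates.

    hcTs whose boundary search resolves to the identical interval are merged
    into one cluster. Clusters are scored with the relative log-odds (sum of
    member log-odds over crosslinkable-base count) and sorted by decreasing
    score; clusters without crosslinkable bases sort last.
    """
    cfg = cfg or MrnConfig()
    if not hcts:
        return []
    noise = None
    delta_global = None
    if cfg.threshold_mode == "local":
        noise = estimate_noise(tracks, hcts, cfg)
    else:
        m2 = cfg.m2 if cfg.m2 is not None else _coverage_mode(tracks, hcts)
        delta_global = global_threshold(cfg.m1, m2)

    by_interval: Dict[Tuple[str, str, int, int], Cluster] = {}
    for s in sorted(hcts, key=lambda t: (t.chrom, t.strand, t.pos)):
        track = tracks[(s.chrom, s.strand)]
        w = nonzero_window(track, s.pos)
        if noise is not None:
            ds, de = local_threshold(noise, track, w)
        else:
            ds = de = delta_global
        cands = enumerate_candidates(track, s.pos, w, ds, de)
        best = select_optimal(rank_candidates(cands))
        key = (s.chrom, s.strand, best.k, best.l)
        cl = by_interval.get(key)
        if cl is None:
            cl = Cluster(
                chrom=s.chrom,
                strand=s.strand,
                start=best.k,
                end=best.l + 1,
                rank_vector=best.rank_vector,
            )
            by_interval[key] = cl
        cl.hcts.append(s)

    clusters = list(by_interval.values())
    for cl in clusters:
        seq = genome[cl.chrom][cl.start : cl.end].upper()
        base = "T" if cl.strand == "+" else "A"
        cl.n_crosslinkable = seq.count(base)
        if cl.n_crosslinkable > 0:
            total = sum(s.log_odds or 0.0 for s in cl.hcts)
            cl.rel_log_odds = total / cl.n_crosslinkable
        else:
            logger.warning(
                "cluster %s:%d-%d(%s) has no crosslinkable bases",
                cl.chrom, cl.start, cl.end, cl.strand,
            )
    clusters.sort(
        key=lambda c: (
            c.rel_log_odds is None,
            -(c.rel_log_odds or 0.0),
            c.chrom,
            c.start,
            c.end,
            c.strand,
        )
    )
    return clusters
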