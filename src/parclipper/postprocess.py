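"""Cluster export (BED/TSV/FASTA) and miRNA seed-enrichment analysis.

Seed enrichment follows the standard miRNA targeting convention: the seed is
the 7-mer at miRNA positions 2-8 and a match is its reverse complement in a
cluster sequence. The background is the mean seed count obtained from
dinucleotide-shuffled copies of the miRNA (Altschul-Erickson shuffle, which
preserves the dinucleotide multiset exactly), so enrichment is controlled
for both length and dinucleotide composition.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParclipError
from .ingest import reverse_complement
from .mrn import Cluster

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- exports


def _bed_score(cluster: Cluster) -> int:
    if cluster.rel_log_odds is None:
        return 0
    return int(min(1000, max(0, round(100 * cluster.rel_log_odds))))


def export_clusters(
    clusters: Sequence[Cluster],
    path: str,
    fmt: str = "BED",
    allow_empty: bool = False,
) -> None:
    """Write clusters as BED6 or a full TSV table (0-based half-open)."""
    if not clusters and not allow_empty:
        raise ParclipError("no clusters to export (use allow_empty to force)")
    fmt = fmt.upper()
    if fmt == "BED":
        with open(path, "w") as fh:
            for cl in clusters:
                name = f"{cl.chrom}:{cl.start}-{cl.end}({cl.strand})"
                fh.write(
                    f"{cl.chrom}\t{cl.start}\t{cl.end}\t{name}\t"
                    f"{_bed_score(cl)}\t{cl.strand}\n"
                )
    elif fmt == "TSV":
        rows = [
            {
                "chrom": cl.chrom,
                "start": cl.start,
                "end": cl.end,
                "strand": cl.strand,
                "n_hcT": len(cl.hcts),
                "rel_log_odds": (
                    "" if cl.rel_log_odds is None else f"{cl.rel_log_odds:.6g}"
                ),
                "width": cl.width,
            }
            for cl in clusters
        ]
        pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "strand", "n_hcT", "rel_log_odds", "width"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ParclipError(f"unknown export format {fmt!r}")


def read_clusters_bed(path: str) -> List[Cluster]:
    """Parse a BED6 written by :func:`export_clusters` back into clusters."""
    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, _name, _score, strand = line.rstrip("\n").split("\t")[:6]
            clusters.append(
                Cluster(chrom=chrom, strand=strand, start=int(start), end=int(end))
            )
    return clusters


def cluster_sequences(
    clusters: Sequence[Cluster], genome: Mapping[str, str]
) -> List[Tuple[str, str]]:
    """(record id, sequence) per cluster; minus-strand clusters are
    reverse-complemented and soft-masked bases uppercased."""
    records = []
    for cl in clusters:
        chromseq = genome[cl.chrom]
        if cl.end > len(chromseq) or cl.start < 0:
            raise ParclipError(
                f"cluster {cl.chrom}:{cl.start}-{cl.end} beyond chromosome end"
            )
        seq = chromseq[cl.start : cl.end].upper()
        if cl.strand == "-":
            seq = reverse_complement(seq)
        records.append((f"{cl.chrom}:{cl.start}-{cl.end}({cl.strand})", seq))
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        path,
        "fasta",
    )


def read_fasta(path: str) -> List[Tuple[str, str]]:
    from Bio.SeqIO import parse

    return [(rec.id, str(rec.seq).upper()) for rec in parse(path, "fasta")]


# ------------------------------------------------------- dinucleotide shuffle


def dinucleotide_shuffle(seq: str, seed: int | None = None, rng=None) -> str:
    """Random sequence with exactly the original dinucleotide multiset.

    Altschul-Erickson Eulerian-path shuffle: pick random terminal edges
    forming an arborescence into the last character's vertex, shuffle the
    remaining edge lists, then walk the path. Sequences with fewer than two
    distinct dinucleotide transitions admit a single arrangement and are
    returned unchanged (with a warning).
    """
    if len(seq) < 3:
        raise ParclipError("sequence too short to shuffle (need >= 3 nt)")
    s = seq.upper()
    if rng is None:
        rng = np.random.default_rng(seed)
    if len({s[i : i + 2] for i in range(len(s) - 1)}) < 2:
        logger.warning("sequence has a single dinucleotide transition; unchanged")
        return s
    edges: Dict[str, List[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    vertices = list(edges)
    while True:
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        ok = True
        for v in vertices:
            u, seen = v, set()
            while u != last and u not in seen:
                seen.add(u)
                u = last_edge.get(u, last if u == last else None)
                if u is None:
                    break
            if u != last:
                ok = False
                break
        if ok:
            break
    order: Dict[str, List[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_edge[v])
        order[v] = rest
    out = [s[0]]
    nxt = {v: 0 for v in vertices}
    u = s[0]
    for _ in range(len(s) - 1):
        w = order[u][nxt[u]]
        nxt[u] += 1
        out.append(w)
        u = w
    return "".join(out)


# ----------------------------------------------------------- seed enrichment


@dataclass
class SeedEnrichment:
    mirna_id: str
    seed: str
    observed: float  # seed matches per kb of cluster sequence
    background: float  # mean over shuffled miRNAs, per kb
    enrichment: float


def _kmer_counter(seqs: Sequence[str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    return counts


def _seed_of(mirna_seq: str, start: int, length: int) -> str:
    return mirna_seq.upper().replace("U", "T")[start : start + length]


def seed_enrichment(
    cluster_seqs: Sequence[Tuple[str, str]] | Sequence[str],
    mirnas: Sequence[Tuple[str, str]],
    n_shuffles: int = 10000,
    seed: int = 0,
    seed_start: int = 1,
    seed_length: int = 7,
) -> List[SeedEnrichment]:
    """Seed-match enrichment of each miRNA over a dinucleotide-shuffled
    background.

    ``observed`` counts reverse-complemented seed occurrences (overlapping)
    in the cluster sequences per kb; ``background`` is the mean of the same
    statistic over ``n_shuffles`` shuffled copies of the miRNA. miRNAs
    shorter than ``seed_start + seed_length`` are skipped with a warning.
    """
    seqs = [
        (t[1] if isinstance(t, tuple) else t).upper() for t in cluster_seqs
    ]
    total_kb = sum(len(q) for q in seqs) / 1000.0
    if total_kb <= 0:
        raise ParclipError("no cluster sequence to scan")
    counts = _kmer_counter(seqs, seed_length)
    rng = np.random.default_rng(seed)
    results = []
    for mid, mseq in mirnas:
        mseq_dna = mseq.upper().replace("U", "T")
        if len(mseq_dna) < seed_start + seed_length:
            logger.warning("miRNA %s shorter than %d nt; skipped", mid, seed_start + seed_length)
            continue
        seed7 = _seed_of(mseq_dna, seed_start, seed_length)
        observed = counts[reverse_complement(seed7)] / total_kb
        bg_total = 0
        for _ in range(n_shuffles):
            shuf = dinucleotide_shuffle(mseq_dna, rng=rng)
            bg_total += counts[reverse_complement(_seed_of(shuf, seed_start, seed_length))]
        background = bg_total / n_shuffles / total_kb
        if background > 0:
            enr = observed / background
        else:
            enr = math.inf if observed > 0 else float("nan")
        results.append(
            SeedEnrichment(
                mirna_id=mid,
                seed=seed7,
                observed=observed,
                background=background,
                enrichment=enr,
            )
        )
    return results


def enrichment_table(results: Sequence[SeedEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna_id,
                "seed": r.seed,
                "observed_per_kb": r.observed,
                "background_per_kb": r.background,
                "enrichment": r.enrichment,
            }
            for r in results
        ]
    )
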