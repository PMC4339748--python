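"""Experimentally based FDR estimation from a matched RNA-Seq profile.

RNA-Seq from the same cells carries SNPs, recurrent sequencing artifacts and
contaminants — but no crosslink-induced transitions. A PAR-CLIP transition
that recurs in RNA-Seq is therefore likely a false positive, which yields

* per-RSF-bin site-level bounds: the upper bound counts any position with
  >=1 RNA-Seq transition of the expected type as FP, the lower bound only
  positions whose RNA-Seq RSF falls in the same bin;
* cluster-level estimates over the top-n clusters ranked by relative
  log-odds: conservative = a single member hcT with RNA-Seq RSF inside the
  model support [a, b] marks the cluster FP; relaxed = every member with
  RNA-Seq evidence must fall inside the support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import FdrError
from .ingest import SubstitutionProfile
from .mrn import Cluster

logger = logging.getLogger(__name__)

ProfileMap = Mapping[Tuple[str, str], SubstitutionProfile]


@dataclass
class FdrTable:
    """FDR estimates: one row per RSF bin (site mode) or per top-n (cluster
    mode); ``lower <= upper`` row-wise (relaxed <= conservative)."""

    mode: str
    table: pd.DataFrame

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _as_map(profiles) -> ProfileMap:
    if isinstance(profiles, SubstitutionProfile):
        return {(profiles.chrom, profiles.strand): profiles}
    return profiles


def _pool_strands(profiles: ProfileMap) -> Dict[str, SubstitutionProfile]:
    """Pool both strands per chromosome (unstranded RNA-Seq libraries).

    Substitution counts are already transcript-oriented per strand, so the
    expected-transition counts can be summed position-wise.
    """
    pooled: Dict[str, SubstitutionProfile] = {}
    for (chrom, _), prof in profiles.items():
        tgt = pooled.get(chrom)
        if tgt is None:
            pooled[chrom] = SubstitutionProfile(
                chrom=chrom,
                strand="+",
                z=prof.z.copy(),
                y={k: dict(v) for k, v in prof.y.items()},
            )
            continue
        tgt.z = tgt.z + prof.z
        for k, posmap in prof.y.items():
            acc = tgt.y.setdefault(k, {})
            for pos, cnt in posmap.items():
                acc[pos] = acc.get(pos, 0) + cnt
    return pooled


def _rnaseq_lookup(rnaseq: ProfileMap, unstranded: bool):
    if unstranded:
        pooled = _pool_strands(rnaseq)
        return lambda chrom, strand: pooled.get(chrom)
    return lambda chrom, strand: rnaseq.get((chrom, strand))


def _bin_index(x: float, n_bins: int) -> int:
    """Index of the half-open decade bin (j/n, (j+1)/n] containing x."""
    idx = math.ceil(x * n_bins - 1e-9) - 1
    return min(max(idx, 0), n_bins - 1)


def site_fdr_bounds(
    parclip: Union[SubstitutionProfile, ProfileMap],
    rnaseq: Union[SubstitutionProfile, ProfileMap],
    subst_type: str = "TC",
    min_cov: int = 20,
    n_bins: int = 10,
    unstranded_rnaseq: bool = False,
) -> FdrTable:
    """Per-RSF-bin upper/lower FDR bounds for candidate interaction sites.

    Considers positions covered by >= ``min_cov`` reads in *both* data sets
    and carrying >=1 expected transition in PAR-CLIP. Bins without members
    are reported with NaN bounds.
    """
    parclip = _as_map(parclip)
    lookup = _rnaseq_lookup(_as_map(rnaseq), unstranded_rnaseq)
    n_p = np.zeros(n_bins, dtype=int)
    n_u = np.zeros(n_bins, dtype=int)
    n_l = np.zeros(n_bins, dtype=int)
    for (chrom, strand), prof in parclip.items():
        rprof = lookup(chrom, strand)
        if rprof is None:
            continue
        ry = rprof.counts(subst_type)
        for pos, cnt in prof.counts(subst_type).items():
            z = int(prof.z[pos])
            if z < min_cov or pos >= len(rprof.z):
                continue
            rz = int(rprof.z[pos])
            if rz < min_cov:
                continue
            b = _bin_index(cnt / z, n_bins)
            n_p[b] += 1
            rcnt = ry.get(pos, 0)
            if rcnt >= 1:
                n_u[b] += 1
                if _bin_index(rcnt / rz, n_bins) == b:
                    n_l[b] += 1
    if n_p.sum() == 0:
        raise FdrError("profiles do not overlap at required coverage")
    with np.errstate(invalid="ignore", divide="ignore"):
        upper = np.where(n_p > 0, n_u / np.maximum(n_p, 1), np.nan)
        lower = np.where(n_p > 0, n_l / np.maximum(n_p, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_low": np.arange(n_bins) / n_bins,
            "bin_high": (np.arange(n_bins) + 1) / n_bins,
            "n_P": n_p,
            "n_U": n_u,
            "n_L": n_l,
            "upper": upper,
            "lower": lower,
        }
    )
    return FdrTable(mode="site", table=table)


def cluster_fdr(
    clusters: Sequence[Cluster],
    rnaseq: Union[SubstitutionProfile, ProfileMap],
    support: Tuple[float, float],
    top_n_list: Sequence[int],
    subst_type: str = "TC",
    min_rnaseq_cov: int = 1,
    unstranded_rnaseq: bool = False,
) -> FdrTable:
    """Conservative and relaxed cluster FDR over top-n ranked clusters.

    A member hcT provides RNA-Seq evidence only when covered by at least
    ``min_rnaseq_cov`` RNA-Seq reads; uncovered members never count toward
    a false positive.
    """
    a, b = support
    if not a <= b:
        raise FdrError("invalid RSF support")
    lookup = _rnaseq_lookup(_as_map(rnaseq), unstranded_rnaseq)
    ranked = sorted(
        clusters,
        key=lambda c: (c.rel_log_odds is None, -(c.rel_log_odds or 0.0)),
    )
    flags: List[Tuple[bool, bool]] = []
    for cl in ranked:
        rprof = lookup(cl.chrom, cl.strand)
        in_support = []
        for s in cl.hcts:
            if rprof is None or s.pos >= len(rprof.z):
                continue
            rz = int(rprof.z[s.pos])
            if rz < min_rnaseq_cov:
                continue
            xt = rprof.counts(subst_type).get(s.pos, 0) / rz
            in_support.append(a <= xt <= b)
        conservative_fp = any(in_support)
        relaxed_fp = bool(in_support) and all(in_support)
        flags.append((conservative_fp, relaxed_fp))

    rows = []
    for top_n in top_n_list:
        if top_n > len(flags):
            logger.warning(
                "top_n=%d exceeds cluster count %d; truncating", top_n, len(flags)
            )
        use = flags[: min(top_n, len(flags))]
        if not use:
            continue
        rows.append(
            {
                "top_n": min(top_n, len(flags)),
                "conservative": sum(f[0] for f in use) / len(use),
                "relaxed": sum(f[1] for f in use) / len(use),
            }
        )
    return FdrTable(mode="cluster", table=pd.DataFrame(rows))


def plot_site_fdr(
    site_table: FdrTable, model=None, path: Optional[str] = None
):
    """Posterior over the RSF grid plus the per-bin FDR bounds (two panels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model import posterior2_on_grid

    fig, axes = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    if model is not None:
        axes[0].plot(model.grid, posterior2_on_grid(model), color="black")
        axes[0].set_ylabel("p(experimental | x)")
    t = site_table.table
    centers = (t["bin_low"] + t["bin_high"]) / 2
    axes[1].step(centers, t["upper"], where="mid", label="upper bound")
    axes[1].step(centers, t["lower"], where="mid", label="lower bound")
    axes[1].set_xlabel("relative substitution frequency")
    axes[1].set_ylabel("FDR")
    axes[1].legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
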