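"""End-to-end helpers wiring ingestion, model, boundary calling and FDR.

These are thin compositions of the module-level operations, shared by the
command-line interface and the reproduction script so that both run the
identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import fdr as fdr_mod
from . import ingest, model as model_mod, mrn

#: expected transition per photoreactive nucleoside chemistry
CHEMISTRY = {"4SU": "TC", "6SG": "GA"}


@dataclass
class PipelineResult:
    model: model_mod.MixtureModel
    support: Tuple[float, float]
    hcts: List[model_mod.TransitionSite]
    clusters: List[mrn.Cluster]
    tracks: Dict[Tuple[str, str], ingest.CoverageTrack]
    profiles: Dict[Tuple[str, str], ingest.SubstitutionProfile]
    site_fdr: Optional[fdr_mod.FdrTable] = None
    cluster_fdr: Optional[fdr_mod.FdrTable] = None


def collect_sites(
    profiles: Mapping[Tuple[str, str], ingest.SubstitutionProfile],
    subst_type: str = "TC",
    min_cov: int = 20,
) -> Tuple[List[model_mod.TransitionSite], List[model_mod.TransitionSite]]:
    """Target-transition sites and pooled other-substitution background sites."""
    target: List[model_mod.TransitionSite] = []
    background: List[model_mod.TransitionSite] = []
    for key in sorted(profiles):
        prof = profiles[key]
        target.extend(ingest.extract_sites(prof, subst_type, min_cov))
        for other in ingest.SUBSTITUTION_TYPES:
            if other == subst_type:
                continue
            background.extend(ingest.extract_sites(prof, other, min_cov))
    return target, background


def fit_model_from_bam(
    bam_path: str,
    genome: Mapping[str, str],
    subst_type: str = "TC",
    min_cov: int = 20,
    grid_step: float = 0.001,
    bandwidth: float = 0.02,
):
    profiles = ingest.build_profiles(bam_path, genome)
    target, background = collect_sites(profiles, subst_type, min_cov)
    fitted = model_mod.fit_mixture(
        target, background, min_cov=min_cov, grid_step=grid_step, bandwidth=bandwidth
    )
    return fitted, profiles, target


def run_pipeline(
    parclip_bam: str,
    genome: Mapping[str, str],
    rnaseq_bam: Optional[str] = None,
    subst_type: str = "TC",
    min_cov: int = 20,
    posterior_cutoff: float = 0.9,
    grid_step: float = 0.001,
    bandwidth: float = 0.02,
    mrn_config: Optional[mrn.MrnConfig] = None,
    top_n_list: Sequence[int] = (75, 125, 250),
    unstranded_rnaseq: bool = False,
) -> PipelineResult:
    """Fit the mixture, classify hcTs, call clusters and (optionally)
    estimate RNA-Seq-based FDRs, all from a PAR-CLIP BAM and a genome."""
    fitted, profiles, target = fit_model_from_bam(
        parclip_bam, genome, subst_type, min_cov, grid_step, bandwidth
    )
    hcts, support = model_mod.classify_hct(
        fitted, target, posterior_cutoff=posterior_cutoff, min_cov=min_cov
    )
    tracks = ingest.build_tracks(parclip_bam)
    clusters = mrn.call_clusters(tracks, hcts, fitted, genome, mrn_config)
    result = PipelineResult(
        model=fitted,
        support=support,
        hcts=hcts,
        clusters=clusters,
        tracks=tracks,
        profiles=profiles,
    )
    if rnaseq_bam is not None:
        rnaseq_profiles = ingest.build_profiles(rnaseq_bam, genome)
        result.site_fdr = fdr_mod.site_fdr_bounds(
            profiles,
            rnaseq_profiles,
            subst_type=subst_type,
            min_cov=min_cov,
            unstranded_rnaseq=unstranded_rnaseq,
        )
        if clusters:
            result.cluster_fdr = fdr_mod.cluster_fdr(
                clusters,
                rnaseq_profiles,
                support,
                top_n_list,
                subst_type=subst_type,
                unstranded_rnaseq=unstranded_rnaseq,
            )
    return result
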