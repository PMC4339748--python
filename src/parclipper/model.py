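"""Non-parametric two-component mixture over relative substitution frequencies.

The observed number of transitions Y at a position with coverage z is modelled
hierarchically: a latent source Theta in {1, 2} (1 = non-experimental, 2 =
crosslink-induced) is drawn with p(Theta=1) = lambda; given Theta, a
substitution probability X is drawn from the component density f_theta on
(0, 1]; given X = x, Y ~ Binomial(z, x). The joint factorizes as
p(Y, X, Theta) = p(Y|X) p(X|Theta) p(Theta), and the source posterior
marginalizes X out:

    p(Theta = theta | Y) ∝ p(theta) * ∫ Binom(Y; z, x) f_theta(x) dx

Densities are estimated non-parametrically: a histogram of observed RSFs on a
fixed grid (default step 0.001), smoothed with a boundary-reflected Gaussian
kernel (default bandwidth 0.02). The non-experimental component f1 is learnt
from substitutions of every type other than the expected one (those cannot be
crosslink-induced); the mixing weight is the largest value keeping
f2 = (fhat - lambda*f1)/(1-lambda) non-negative, i.e. the minimum of fhat/f1
over f1's effective support.

High-confidence transitions (hcTs) are classified with the x-conditional
posterior: the RSF support [a, b] collects grid points whose posterior for
the experimental component reaches the cutoff delta, and sites whose RSF
falls inside [a, b] (at sufficient coverage) are retained and scored with
the Y-marginalized posterior and its log-odds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ModelError

#: relative floor defining the high-density region of f1 over which the
#: mixing-weight minimum is taken; outside it the histogram ratio fhat/f1 is
#: dominated by small-sample noise in the kernel tails and the minimum
#: collapses toward zero
_F1_SUPPORT_FRAC = 0.1


@dataclass
class TransitionSite:
    """A genomic position carrying >=1 substitution of the expected type."""

    chrom: str
    strand: str
    pos: int
    y: int
    z: int
    posterior2: Optional[float] = None
    log_odds: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.y <= self.z):
            raise ModelError(f"invalid site counts y={self.y}, z={self.z}")

    @property
    def x(self) -> float:
        """Relative substitution frequency y/z in (0, 1]."""
        return self.y / self.z


@dataclass
class MixtureModel:
    grid: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    lam: float
    grid_step: float
    bandwidth: float
    delta: Optional[float] = None
    support: Optional[Tuple[float, float]] = None

    def to_json(self, path: Optional[str] = None) -> str:
        doc = {
            "grid_step": self.grid_step,
            "bandwidth": self.bandwidth,
            "lambda": self.lam,
            "grid": self.grid.tolist(),
            "f1": self.f1.tolist(),
            "f2": self.f2.tolist(),
            "delta": self.delta,
            "support": list(self.support) if self.support else None,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "MixtureModel":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        return cls(
            grid=np.asarray(doc["grid"], dtype=float),
            f1=np.asarray(doc["f1"], dtype=float),
            f2=np.asarray(doc["f2"], dtype=float),
            lam=float(doc["lambda"]),
            grid_step=float(doc["grid_step"]),
            bandwidth=float(doc["bandwidth"]),
            delta=doc.get("delta"),
            support=tuple(doc["support"]) if doc.get("support") else None,
        )


def make_grid(grid_step: float = 0.001) -> np.ndarray:
    """Ordered RSF evaluation points (0, 1]: step, 2*step, ..., 1."""
    n = int(round(1.0 / grid_step))
    return np.linspace(grid_step, 1.0, n)


def density_on_grid(
    values: Sequence[float], grid: np.ndarray, bandwidth: float = 0.02
) -> np.ndarray:
    """Histogram density on the grid cells, Gaussian-smoothed with reflection.

    Reflection at both ends keeps mass inside (0, 1]; the result integrates
    to 1 over the grid (trapezoidal rule).
    """
    vals = np.clip(np.asarray(values, dtype=float), grid[0], grid[-1])
    step = grid[1] - grid[0]
    edges = np.concatenate([grid - step / 2, [grid[-1] + step / 2]])
    counts, _ = np.histogram(vals, bins=edges)
    counts = counts.astype(float)
    if bandwidth > 0:
        half = max(1, int(math.ceil(4 * bandwidth / step)))
        half = min(half, len(counts) - 1)
        xs = np.arange(-half, half + 1) * step
        kern = np.exp(-0.5 * (xs / bandwidth) ** 2)
        kern /= kern.sum()
        padded = np.concatenate(
            [counts[:half][::-1], counts, counts[-half:][::-1]]
        )
        counts = np.convolve(padded, kern, mode="same")[half:-half]
    area = np.trapezoid(counts, grid)
    if area <= 0:
        raise ModelError("cannot estimate a density from an empty sample")
    return counts / area


def fit_mixture(
    target_sites: Sequence[TransitionSite],
    background_sites: Sequence[TransitionSite],
    min_cov: int = 20,
    grid_step: float = 0.001,
    bandwidth: float = 0.02,
) -> MixtureModel:
    """Fit the two-component RSF mixture.

    ``target_sites`` carry the expected transition (e.g. T->C for 4SU);
    ``background_sites`` pool every other substitution type and identify the
    non-experimental component f1.
    """
    xt = [s.x for s in target_sites if s.z >= min_cov]
    xb = [s.x for s in background_sites if s.z >= min_cov]
    if not xb:
        raise ModelError(
            "cannot estimate non-experimental component: no background sites"
        )
    if not xt:
        raise ModelError("no target sites after coverage filtering")
    grid = make_grid(grid_step)
    fhat = density_on_grid(xt, grid, bandwidth)
    f1 = density_on_grid(xb, grid, bandwidth)
    # the ratio fhat/f1 estimates the mixing weight only where f1 is backed
    # by data: outside the observed background range (and in low-density
    # regions) both densities are kernel tails and the minimum collapses
    mask = (
        (f1 >= _F1_SUPPORT_FRAC * f1.max())
        & (grid >= min(xb))
        & (grid <= max(xb))
    )
    if not mask.any():
        mask = f1 >= _F1_SUPPORT_FRAC * f1.max()
    lam = float(np.clip(np.min(fhat[mask] / f1[mask]), 0.0, 1.0))
    if lam >= 1.0 - 1e-9:
        raise ModelError("no experimental signal detected (lambda ~ 1)")
    f2 = (fhat - lam * f1) / (1.0 - lam)
    np.clip(f2, 0.0, None, out=f2)
    area = np.trapezoid(f2, grid)
    if area <= 0:
        raise ModelError("experimental component has no mass")
    f2 /= area
    return MixtureModel(
        grid=grid, f1=f1, f2=f2, lam=lam, grid_step=grid_step, bandwidth=bandwidth
    )


def _posterior_from_odds(odds: float, lam: float) -> Tuple[float, float]:
    if math.isnan(odds):  # 0/0: no density information, fall back to prior
        return lam, 1.0 - lam
    if math.isinf(odds):
        return 0.0, 1.0
    p2 = odds / (1.0 + odds)
    return 1.0 / (1.0 + odds), p2


def posterior_given_x(model: MixtureModel, x: float) -> Tuple[float, float]:
    """Mixture responsibilities (p1, p2) at an observed RSF value."""
    if not (0.0 < x <= 1.0):
        raise ModelError(f"RSF {x} outside (0, 1]")
    f1x = float(np.interp(x, model.grid, model.f1))
    f2x = float(np.interp(x, model.grid, model.f2))
    lam = model.lam
    if lam <= 0.0:
        return (0.0, 1.0) if f2x > 0 else (lam, 1.0 - lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        # density ratio first: equal densities give exactly the prior odds
        odds = ((1.0 - lam) / lam) * (np.float64(f2x) / np.float64(f1x))
    return _posterior_from_odds(float(odds), lam)


def _marginal_odds(model: MixtureModel, y: int, z: int) -> float:
    if z < 1 or not (0 <= y <= z):
        raise ModelError(f"invalid counts y={y}, z={z}")
    pmf = stats.binom.pmf(y, z, model.grid)
    i1 = np.trapezoid(pmf * model.f1, model.grid)
    i2 = np.trapezoid(pmf * model.f2, model.grid)
    lam = model.lam
    if lam <= 0.0:
        return math.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = ((1.0 - lam) / lam) * (np.float64(i2) / np.float64(i1))
    return float(odds)


def posterior_given_y(model: MixtureModel, y: int, z: int) -> Tuple[float, float]:
    """Source posterior (p1, p2) marginalizing the RSF out by quadrature."""
    return _posterior_from_odds(_marginal_odds(model, y, z), model.lam)


def score_log_odds(model: MixtureModel, y: int, z: int, cap: float = 700.0) -> float:
    """log(p(Theta=2|Y) / p(Theta=1|Y)), with infinities capped at +-cap."""
    odds = _marginal_odds(model, y, z)
    if math.isnan(odds):
        lam = model.lam
        return float(np.clip(math.log((1.0 - lam) / lam), -cap, cap))
    if odds <= 0.0:
        return -cap
    if math.isinf(odds):
        return cap
    return float(np.clip(math.log(odds), -cap, cap))


def posterior2_on_grid(model: MixtureModel) -> np.ndarray:
    """p(Theta=2 | x) at every grid point; NaN where both densities vanish."""
    lam = model.lam
    w1 = lam * model.f1
    w2 = (1.0 - lam) * model.f2
    tot = w1 + w2
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = np.where(tot > 0, w2 / tot, np.nan)
    return p2


def rsf_support(model: MixtureModel, posterior_cutoff: float) -> Tuple[float, float]:
    """Smallest RSF interval [a, b] containing every grid point whose
    x-conditional posterior for the experimental component reaches the cutoff."""
    if not (0.5 < posterior_cutoff < 1.0):
        raise ModelError("posterior cutoff must lie in (0.5, 1)")
    p2 = posterior2_on_grid(model)
    hit = np.flatnonzero(np.nan_to_num(p2, nan=-1.0) >= posterior_cutoff)
    if hit.size == 0:
        raise ModelError("cutoff too strict for fitted model: empty RSF support")
    return float(model.grid[hit[0]]), float(model.grid[hit[-1]])


def classify_hct(
    model: MixtureModel,
    sites: Sequence[TransitionSite],
    posterior_cutoff: float = 0.9,
    min_cov: int = 20,
) -> Tuple[List[TransitionSite], Tuple[float, float]]:
    """Select high-confidence transitions and score them.

    Classification uses the x-conditional posterior (sites whose RSF falls in
    the cutoff-derived support [a, b]); each retained site is scored with the
    Y-marginalized posterior and log-odds used downstream for ranking.
    """
    a, b = rsf_support(model, posterior_cutoff)
    model.delta = posterior_cutoff
    model.support = (a, b)
    hcts: List[TransitionSite] = []
    cache: Dict[Tuple[int, int], Tuple[float, float]] = {}
    for s in sites:
        if s.z < min_cov or not (a <= s.x <= b):
            continue
        key = (s.y, s.z)
        if key not in cache:
            p2 = posterior_given_y(model, s.y, s.z)[1]
            lo = score_log_odds(model, s.y, s.z)
            cache[key] = (p2, lo)
        s.posterior2, s.log_odds = cache[key]
        hcts.append(s)
    return hcts, (a, b)


def write_hct_bed(hcts: Sequence[TransitionSite], path: str) -> None:
    """BED6 export of scored hcTs; score = min(1000, round(posterior2*1000))."""
    with open(path, "w") as fh:
        for s in sorted(hcts, key=lambda t: (t.chrom, t.pos, t.strand)):
            score = 0 if s.posterior2 is None else min(1000, round(s.posterior2 * 1000))
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.y}/{s.z}\t{score}\t{s.strand}\n"
            )
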