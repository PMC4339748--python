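import numpy as np
import pytest

from parclipper import default_truth, run_pipeline, simulate_parclip, simulate_rnaseq
from parclipper.model import MixtureModel, make_grid
from parclipper.mrn import MrnConfig

#: seed of the reference simulation shared across the suite
SIM_SEED = 1


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Default synthetic experiment (200 sites) plus BAM paths."""
    out = tmp_path_factory.mktemp("sim")
    truth = default_truth(seed=SIM_SEED)
    parclip = simulate_parclip(truth, str(out / "parclip.bam"), str(out / "truth.tsv"))
    rnaseq = simulate_rnaseq(truth, str(out / "rnaseq.bam"))
    return {"truth": truth, "parclip": parclip, "rnaseq": rnaseq, "dir": out}


@pytest.fixture(scope="session")
def pipeline(sim):
    """Full pipeline result on the reference simulation (cutoff 0.9)."""
    return run_pipeline(
        sim["parclip"],
        sim["truth"].genome,
        rnaseq_bam=sim["rnaseq"],
        posterior_cutoff=0.9,
        mrn_config=MrnConfig(seed=SIM_SEED),
        top_n_list=(25, 75, 125),
    )


def toy_model(lam=0.25, grid_step=0.001):
    """Analytic toy mixture: f1 decreasing triangle on (0, 0.2],
    f2 symmetric triangle on [0.25, 0.65]; both normalized on the grid."""
    grid = make_grid(grid_step)
    f1 = np.clip(0.2 - grid, 0.0, None)
    f1 /= np.trapezoid(f1, grid)
    f2 = np.clip(0.2 - np.abs(grid - 0.45), 0.0, None)
    f2 /= np.trapezoid(f2, grid)
    return MixtureModel(
        grid=grid, f1=f1, f2=f2, lam=lam, grid_step=grid_step, bandwidth=0.0
    )


def equal_density_model(lam=0.25, grid_step=0.001):
    """f1 == f2 pointwise: the likelihood is uninformative by construction."""
    grid = make_grid(grid_step)
    f = np.clip(0.3 - np.abs(grid - 0.3), 0.0, None)
    f /= np.trapezoid(f, grid)
    return MixtureModel(
        grid=grid, f1=f, f2=f.copy(), lam=lam, grid_step=grid_step, bandwidth=0.0
    )


def smooth_model(lam=0.25, grid_step=0.001):
    """Analytic smooth mixture: Gaussian bumps with negligible mass at the
    grid edges (suitable for quadrature-accuracy checks)."""
    grid = make_grid(grid_step)
    f1 = np.exp(-0.5 * ((grid - 0.12) / 0.025) ** 2)
    f1 /= np.trapezoid(f1, grid)
    f2 = np.exp(-0.5 * ((grid - 0.45) / 0.08) ** 2)
    f2 /= np.trapezoid(f2, grid)
    return MixtureModel(
        grid=grid, f1=f1, f2=f2, lam=lam, grid_step=grid_step, bandwidth=0.0
    )


@pytest.fixture
def analytic_model():
    return toy_model()


@pytest.fixture
def uninformative_model():
    return equal_density_model()
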