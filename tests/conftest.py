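import numpy as np
import pytest

import densefit as df


@pytest.fixture(scope="session")
def noiseless_spec() -> df.PhantomSpec:
    """Default annular phantom with the phase noise switched off."""
    return df.PhantomSpec(phase_noise_sd=0.0)


@pytest.fixture(scope="session")
def truth(noiseless_spec) -> df.GroundTruth:
    return df.generate_ground_truth(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_data(noiseless_spec, truth):
    """(series, masks, nodes) for the noiseless default phantom."""
    series, masks = df.generate_eulerian_series(noiseless_spec, truth)
    nodes = df.NodeSet.from_mask(masks[0], noiseless_spec.spacing)
    return series, masks, nodes


@pytest.fixture(scope="session")
def calibrated_weights(noiseless_data, truth):
    """(lambda, mu) selected by the ground-truth grid search on the phantom."""
    series, _, nodes = noiseless_data
    from densefit.evaluate import calibrate_weights

    return calibrate_weights(series, nodes, truth)


@pytest.fixture(scope="session")
def rstls_solution(noiseless_data, calibrated_weights):
    """Calibrated RSTLS trajectories on the noiseless phantom."""
    series, _, nodes = noiseless_data
    lam, mu = calibrated_weights
    return df.solve_sequence(series, nodes, df.SolverConfig(lam=lam, mu=mu))


@pytest.fixture(scope="session")
def truth_trajectories(noiseless_spec, truth) -> df.LagrangianTrajectories:
    """Exact phantom trajectories wrapped in the solver's output container."""
    return df.LagrangianTrajectories(
        disp=truth.disp,
        ref_positions=truth.positions,
        times_ms=noiseless_spec.encoding.frame_times_ms,
    )


@pytest.fixture(scope="session")
def interior_nodes(noiseless_data) -> np.ndarray:
    """Boolean mask of nodes whose full 8-neighborhood lies on the mask."""
    _, _, nodes = noiseless_data
    out = np.zeros(nodes.n, dtype=bool)
    for k in range(nodes.n):
        r, c = nodes.ij[k]
        out[k] = all(
            nodes.ordinal[r + dr, c + dc] >= 0
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
        )
    return out


@pytest.fixture
def toy_nodes() -> df.NodeSet:
    """Small full rectangular node lattice for dense-oracle comparisons."""
    return df.NodeSet.from_mask(np.ones((5, 5), dtype=bool), 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
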