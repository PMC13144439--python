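"""Shared fixtures: simulated circuit datasets reused across test modules.

The heavier snapshot ensembles (2,000 random-kinetics models) are built
once per session; individual tests treat them as read-only.
"""

import numpy as np
import pytest

import sticcc as st


@pytest.fixture(scope="session")
def rep_topology():
    return st.builtin_circuit("REP")


@pytest.fixture(scope="session")
def cts_topology():
    return st.builtin_circuit("CTS")


def _snapshot_dataset(topology, seed, n_models=2000):
    cfg = st.SimulationConfig(n_models=n_models, seed=seed)
    raw = st.simulate_steady_states(topology, cfg)
    log = st.normalize_log(raw)
    space, model = st.embedding_from_pca(log, 2)
    return {"raw": raw, "log": log, "space": space, "pca": model}


@pytest.fixture(scope="session")
def rep_dataset(rep_topology):
    """Snapshot ensemble of the repressilator (oscillatory regime)."""
    return _snapshot_dataset(rep_topology, seed=11)


@pytest.fixture(scope="session")
def cts_dataset(cts_topology):
    """Snapshot ensemble of the coupled toggle switch (multistable regime)."""
    return _snapshot_dataset(cts_topology, seed=11)


@pytest.fixture(scope="session")
def rep_vectors(rep_topology, rep_dataset):
    return st.run_sticc(
        rep_topology, rep_dataset["log"], rep_dataset["space"], radius_fraction=0.15
    )


@pytest.fixture(scope="session")
def cts_vectors(cts_topology, cts_dataset):
    return st.run_sticc(
        cts_topology, cts_dataset["log"], cts_dataset["space"], radius_fraction=0.15
    )


def find_oscillatory_model(topology, seed=11, n_scan=40):
    """Most oscillatory sampled model: largest relative late-time swing."""
    params = st.sample_parameters(topology, seed=seed, n_models=n_scan)
    best, best_amp = 0, -1.0
    for i in range(n_scan):
        cfg = st.SimulationConfig(
            n_models=1, noise_level=0.0, total_time=200.0, print_interval=0.5, seed=1
        )
        tr = st.simulate_trajectory_sde(topology, params.model(i), cfg)
        late = tr.states[300:]
        amp = float(((late.max(0) - late.min(0)) / (late.mean(0) + 1e-9)).min())
        if amp > best_amp:
            best, best_amp = i, amp
    return params.model(best), best_amp


@pytest.fixture(scope="session")
def rep_limit_cycle(rep_topology):
    """A single oscillatory repressilator model plus its noisy trajectory
    and the standard analysis pipeline (z-score + PCA + vector inference).

    Single-model trajectory data is z-scored per gene: with only three
    edges, static inter-gene offsets would otherwise dominate the
    cross-cell correlation.
    """
    params, amp = find_oscillatory_model(rep_topology)
    assert amp > 0.5, "no sustained oscillator found in the scanned ensemble"
    cfg = st.SimulationConfig(
        n_models=1, noise_level=0.1, total_time=2000.0, print_interval=0.5, seed=2
    )
    traj = st.simulate_trajectory_sde(rep_topology, params, cfg)
    log = st.normalize_log(traj.to_expression())
    rng = np.random.default_rng(3)
    idx = np.sort(rng.choice(log.n_cells, 2000, replace=False))
    sub_log = st.ExpressionMatrix(log.data.iloc[idx], scale="log")
    sub = st.zscore(sub_log)
    space, model = st.embedding_from_pca(sub, 2)
    tv = st.run_sticc(rep_topology, sub, space, radius_fraction=0.15)
    mu = sub_log.values().mean(0)
    sd = sub_log.values().std(0, ddof=1)
    full2d = model.transform((log.values() - mu) / sd)
    return {
        "params": params,
        "trajectory": traj,
        "expression": sub,
        "space": space,
        "pca": model,
        "vectors": tv,
        "full_coords2d": full2d,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
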