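import warnings

import numpy as np
import pytest

import sctipping as st


@pytest.fixture(scope="session")
def small_run():
    """One small synthetic run (50 cells/day, seed 1) shared across tests."""
    table, truth = st.generate(
        st.GeneratorConfig(n_cells_per_day=(50, 50, 50, 50), seed=1)
    )
    return table, truth


@pytest.fixture(scope="session")
def small_log_table(small_run):
    table, _ = small_run
    return st.log_transform(table)


@pytest.fixture(scope="session")
def fitted(small_log_table):
    return st.decompose(small_log_table, n_modules=2)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def ward_path_study(seed, n_per_day=50):
    """Cluster one synthetic run with the package pipeline pieces and return
    (log table, truth, assignment, cluster->path map, planted tipping cluster
    per path).  Paths come from ground-truth majority so the study isolates
    the criticality question."""
    table, truth = st.generate(
        st.GeneratorConfig(n_cells_per_day=(n_per_day,) * 4, seed=seed)
    )
    lt = st.log_transform(table)
    assignment = st.cluster_by_day(lt)
    paths = {}
    for cid in assignment.cluster_ids():
        members = assignment.members(cid)
        n_high = int((truth.path[members] == "high").sum())
        paths[cid] = "upper" if 2 * n_high > members.size else "lower"
    planted = {}
    for path in ("upper", "lower"):
        best, best_n = None, -1
        for cid in assignment.cluster_ids():
            if paths[cid] != path:
                continue
            n_tip = int(truth.tipping[assignment.members(cid)].sum())
            if n_tip > best_n:
                best, best_n = cid, n_tip
        planted[path] = best
    return lt, truth, assignment, paths, planted
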