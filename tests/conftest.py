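"""Shared fixtures.

The 20-seed global-fit recovery study is expensive (a bounded nonlinear
least-squares fit of six datasets per seed), so it is computed once per
session and shared by the recovery property test and the acceptance test.
"""

from __future__ import annotations

import numpy as np
import pytest

import tmfret as tm


def run_recovery_study(n_seeds: int = 20, base_seed: int = 0, n_starts: int = 2):
    """Simulate the six-dataset study at the default truth and refit, per seed.

    Returns a dict of per-seed recovered parameter arrays keyed by name.
    """
    pairs = {a: tm.get_pair(a) for a in ("Fe(phenM)3", "Ru(bpy)2phenM")}
    names = ("rbar1", "sigma1", "rbar2", "sigma2", "A2_apo", "A2_cAMP", "A2_cGMP")
    out = {k: [] for k in names}
    out["converged"] = []
    for i in range(n_seeds):
        design = tm.StudyDesign(seed=base_seed + i)
        datasets, _ = tm.generate_fd_study(design)
        res = tm.fit_global_two_gaussian(datasets, pairs, n_starts=n_starts, seed=0)
        for k in names:
            out[k].append(res.parameters[k])
        out["converged"].append(res.converged)
    return {k: np.asarray(v) for k, v in out.items()}


@pytest.fixture(scope="session")
def recovery_study():
    return run_recovery_study()


@pytest.fixture(scope="session")
def fe_pair():
    return tm.get_pair("Fe(phenM)3")


@pytest.fixture(scope="session")
def ru_pair():
    return tm.get_pair("Ru(bpy)2phenM")


@pytest.fixture(scope="session")
def default_truth():
    return tm.TwoGaussianTruth()
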