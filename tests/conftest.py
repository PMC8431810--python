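import numpy as np
import pytest

from gelscan import build_template


@pytest.fixture(scope="session")
def f34():
    return build_template("f34")


@pytest.fixture(scope="session")
def f35():
    return build_template("f35")


@pytest.fixture(scope="session")
def phe():
    return build_template("phe")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def brute_force_partition(frame, template, cutoff=4.0):
    """Independent transitive-closure oracle for cluster detection:
    O(n²) pair scan plus explicit closure, no graph library."""
    n = frame.n_monomers
    h = template.heavy_indices
    box = frame.box
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = frame.coords[i, h][:, None, :] - frame.coords[j, h][None, :, :]
            d = d - box * np.round(d / box)
            if np.sqrt((d * d).sum(axis=2)).min() <= cutoff:
                adj[i][j] = adj[j][i] = True
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if adj[i][j] and labels[j] != labels[i]:
                    lo = min(labels[i], labels[j])
                    labels[i] = labels[j] = lo
                    changed = True
    groups = {}
    for m, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(m)
    clusters = {frozenset(g) for g in groups.values() if len(g) >= 2}
    singletons = {next(iter(g)) for g in groups.values() if len(g) == 1}
    return clusters, singletons
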