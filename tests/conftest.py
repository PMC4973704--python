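"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import netmoments as nm
from netmoments.network import pcd_matrix


def ab_study(sid: str, y: float, v: float, design: str = "AB") -> nm.Study:
    d = nm.canonicalize_design(tuple(design))
    return nm.Study(sid, d, [y], [[v]])


def two_arm_network(ys, vs, design: str = "AB") -> nm.Network:
    return nm.Network(
        [ab_study(f"s{i}", y, v, design) for i, (y, v) in enumerate(zip(ys, vs))]
    )


@pytest.fixture
def two_ab_network() -> nm.Network:
    """Two AB studies, y = (0, 2), v = (1, 1): hand-checkable throughout."""
    return two_arm_network([0.0, 2.0], [1.0, 1.0])


def random_network(rng: np.random.Generator) -> nm.Network:
    """A small random connected network with random PD covariances."""
    n_treat = int(rng.integers(2, 5))
    treatments = list("ABCD")[:n_treat]
    # star of 2-arm designs guarantees connectivity
    design_sets = [{treatments[0], t} for t in treatments[1:]]
    for _ in range(int(rng.integers(0, 3))):
        size = int(rng.integers(2, n_treat + 1))
        design_sets.append(set(rng.choice(treatments, size=size, replace=False)))
    studies = []
    k = 0
    for ds in design_sets:
        d = nm.canonicalize_design(ds)
        for _ in range(int(rng.integers(1, 4))):
            sigma2 = float(rng.uniform(0.05, 0.5))
            studies.append(
                nm.Study(
                    id=f"s{k}",
                    design=d,
                    y=rng.normal(0.0, 1.0, d.c_d),
                    S=sigma2 * pcd_matrix(d.c_d),
                )
            )
            k += 1
    return nm.Network(studies)


def dl_tau_squared(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Independent classical DerSimonian-Laird oracle for 2-arm studies.

    Returns (untruncated, truncated) between-study variance: Q computed with
    fixed-effect weights w = 1/v about the inverse-variance mean, matched to
    its expectation k - 1 + tau^2 (sum w - sum w^2 / sum w).
    """
    y = np.asarray(y, float)
    w = 1.0 / np.asarray(v, float)
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    untrunc = (q - (len(y) - 1)) / denom
    return untrunc, max(untrunc, 0.0)
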