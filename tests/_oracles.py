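"""Shared independent oracles for the test suite."""

import numpy as np
from scipy.spatial.transform import Rotation


def sampled_min_rmsd(a, b, rng, n_global=200_000, n_local=200_000):
    """Minimum superposition RMSD found by pure rotation sampling.

    Centroids are aligned analytically (optimal for any rotation); rotations
    are sampled uniformly, then progressively finer perturbations of the best
    rotation found so far are sampled. No gradient or closed-form rotation
    solution is used, so this is independent of the Kabsch implementation.
    """
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def batch_rmsd(mats):
        moved = np.einsum("nij,kj->nki", mats, bc)
        return np.sqrt(np.mean(np.sum((moved - ac) ** 2, axis=2), axis=1))

    mats = Rotation.random(n_global, rng=rng).as_matrix()
    rmsds = batch_rmsd(mats)
    best_idx = int(np.argmin(rmsds))
    best_rmsd = float(rmsds[best_idx])
    best_rot = Rotation.from_matrix(mats[best_idx])

    for scale in (0.1, 0.01, 0.001):
        tweaks = Rotation.from_rotvec(rng.normal(0.0, scale, size=(n_local, 3)))
        mats = (tweaks * best_rot).as_matrix()
        rmsds = batch_rmsd(mats)
        idx = int(np.argmin(rmsds))
        if rmsds[idx] < best_rmsd:
            best_rmsd = float(rmsds[idx])
            best_rot = Rotation.from_matrix(mats[idx])
    return best_rmsd
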