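"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def classic_pac_bruteforce(R: np.ndarray) -> np.ndarray:
    """Unweighted apparent-competition matrix computed with explicit loops.

    d_ij = sum over ligands k of (i's portfolio share of k) times (j's share
    of k's total uptake); independent of the package implementation.
    """
    n_lig, n_cell = R.shape
    P = np.zeros((n_cell, n_cell))
    for i in range(n_cell):
        for j in range(n_cell):
            for k in range(n_lig):
                tot_i = R[:, i].sum()
                tot_k = R[k, :].sum()
                if tot_i and tot_k:
                    P[i, j] += (R[k, i] / tot_i) * (R[k, j] / tot_k)
    return P
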