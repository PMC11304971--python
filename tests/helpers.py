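"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: exhaustive path scoring
instead of Viterbi, all-pairs difference counting instead of the pooled
heterozygosity formula, sort-and-accumulate instead of the N50 routine.
"""

from __future__ import annotations

import numpy as np


def exhaustive_best_path(log_emissions: np.ndarray, persistence: float):
    """Best state path by scoring every one of the 4^T paths explicitly."""
    n_states, T = log_emissions.shape
    assert T <= 10, "exhaustive enumeration is for short tracks only"
    grids = np.meshgrid(*([np.arange(n_states)] * T), indexing="ij")
    paths = np.stack([g.ravel() for g in grids], axis=1)  # (4^T, T)
    log_stay = np.log(persistence)
    log_move = np.log((1 - persistence) / (n_states - 1))
    score = np.log(1.0 / n_states) + log_emissions[paths[:, 0], 0]
    for t in range(1, T):
        score = score + np.where(paths[:, t] == paths[:, t - 1], log_stay, log_move)
        score = score + log_emissions[paths[:, t], t]
    best = int(np.argmax(score))
    return paths[best], float(score[best])


def brute_force_site_pi(alleles: np.ndarray) -> float:
    """Mean pairwise difference over all distinct pairs of allele copies."""
    alleles = np.asarray(alleles)
    n = alleles.size
    diffs = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            diffs += int(alleles[i] != alleles[j])
    return diffs / pairs if pairs else 0.0


def brute_force_n50(lengths) -> int:
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    acc = 0
    for ln in lengths:
        acc += ln
        if acc * 2 >= total:
            return ln
    raise AssertionError("unreachable")
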