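"""Multiplicative-update NMF baseline with simplex renormalization.

Classical Frobenius-loss multiplicative updates (element-wise multiply by a
ratio of non-negative factors) with an extra step after each loop that
renormalizes every column of F to sum to 1.  Plain MU never increases the
objective, but the injected renormalization can; the iteration therefore
stops the first time the objective rises, returning the pre-increase iterate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deconv import DeconvResult

__all__ = ["MUConfig", "mu_nmf_fit"]


@dataclass
class MUConfig:
    k: int = 5
    max_iters: int = 5_000
    seed: int = 0
    floor_eps: float = 1e-12

    def __post_init__(self):
        if self.floor_eps <= 0:
            raise ValueError("floor_eps must be positive")
        if self.k < 1:
            raise ValueError("k must be a positive integer")


def mu_nmf_fit(B, config: MUConfig, renormalize: bool = True) -> DeconvResult:
    """MU-NMF on a non-negative matrix; F column-stochastic on return.

    With ``renormalize=False`` this is plain Lee–Seung MU whose objective is
    non-increasing over all iterations (no early stop fires).
    """
    B = np.asarray(getattr(B, "values", B), dtype=float)
    if np.any(B < 0):
        raise ValueError("MU-NMF requires a non-negative matrix")
    m, n = B.shape
    k = config.k
    eps = config.floor_eps
    rng = np.random.default_rng(config.seed)
    C = rng.uniform(0.1, 1.0, size=(m, k))
    F = rng.uniform(0.1, 1.0, size=(k, n))
    if renormalize:
        F = F / F.sum(axis=0)

    def objective(C, F):
        R = B - C @ F
        return float(np.sum(R * R))

    prev_obj = objective(C, F)
    trace = [(0, prev_obj)]
    converged = False
    for t in range(1, config.max_iters + 1):
        C_new = C * (B @ F.T) / (C @ F @ F.T + eps)
        F_new = F * (C_new.T @ B) / (C_new.T @ C_new @ F + eps)
        if renormalize:
            F_new = F_new / (F_new.sum(axis=0) + eps)
        obj = objective(C_new, F_new)
        if renormalize and obj > prev_obj:
            converged = True  # stop on objective increase, keep previous iterate
            break
        C, F = C_new, F_new
        trace.append((t, obj))
        prev_obj = obj
    if renormalize:
        F = F / F.sum(axis=0)  # exact unit sums (floor_eps slightly deflates them)
    return DeconvResult(C=C, F=F, F_par=F, loss_trace=trace, converged=converged)
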