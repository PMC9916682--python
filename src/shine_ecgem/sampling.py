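"""Seeded hit-and-run sampling of the steady-state flux polytope.

Every steady-state flux vector satisfies S·v = 0, so v = N·x for a null-space
basis N of S; the sampler walks uniformly inside the polytope
{x : lb ≤ N·x ≤ ub} and maps points back to flux space. Defaults: warm-up of
100·n_reactions steps and thinning of 10 (one kept sample every 10 steps),
both configurable. Identical seeds give bit-identical sample matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .network import MetabolicNetwork, TOL_FEAS


class SamplingError(RuntimeError):
    """Sampling could not start (infeasible network or empty interior)."""


@dataclass
class FluxSampleSet:
    """n_samples × n_reactions flux samples from one network."""

    samples: pd.DataFrame  # columns = reaction ids
    sampler: str
    seed: int
    thinning: int
    warmup: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column(self, rid: str) -> np.ndarray:
        return self.samples[rid].to_numpy()


def _interior_point(N: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                    tol: float) -> np.ndarray:
    """Point x with lb + t ≤ N·x ≤ ub − t and t as large as possible.

    Rows with ub − lb ≤ 2·tol are treated as (near-)fixed and only required
    to hold as two-sided inequalities without clearance.
    """
    n_rows, dim = N.shape
    wide = (ub - lb) > 2 * tol
    # variables: x (dim), t (1); maximize t
    rows_ub = []
    rhs_ub = []
    for i in range(n_rows):
        t_coef = 1.0 if wide[i] else 0.0
        rows_ub.append(np.concatenate([N[i], [t_coef]]))
        rhs_ub.append(ub[i])
        rows_ub.append(np.concatenate([-N[i], [t_coef]]))
        rhs_ub.append(-lb[i])
    A_ub = np.array(rows_ub)
    b_ub = np.array(rhs_ub)
    c = np.zeros(dim + 1)
    c[-1] = -1.0
    span = np.max(ub[wide] - lb[wide]) if wide.any() else 1.0
    bounds = [(None, None)] * dim + [(0.0, span)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status != 0:
        raise SamplingError("no feasible starting point: network infeasible")
    if wide.any() and res.x[-1] <= tol:
        raise SamplingError("feasible set has empty interior")
    return res.x[:dim]


def sample_fluxes(
    network: MetabolicNetwork,
    n_samples: int,
    seed: int,
    warmup: int | None = None,
    thinning: int = 10,
    tol: float = TOL_FEAS,
) -> FluxSampleSet:
    """Draw ``n_samples`` steady-state flux vectors by hit-and-run.

    Raises :class:`SamplingError` when the network is infeasible or the
    polytope has no interior point to start from.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if network.bound_violations():
        raise SamplingError(
            f"bounds violated (lb > ub): {network.bound_violations()}")
    rids = network.reaction_ids
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    N = null_space(S)
    if warmup is None:
        warmup = 100 * len(rids)
    if N.shape[1] == 0:
        # only v = 0 is steady-state; valid iff within bounds
        if np.all(lb <= tol) and np.all(ub >= -tol):
            zeros = np.zeros((n_samples, len(rids)))
            return FluxSampleSet(pd.DataFrame(zeros, columns=rids),
                                 "hit-and-run", seed, thinning, warmup)
        raise SamplingError("null space is trivial and v = 0 violates bounds")

    x = _interior_point(N, lb, ub, tol)
    rng = np.random.default_rng(seed)
    dim = N.shape[1]
    v = N @ x
    shrink = 1.0 - 1e-12
    samples = np.empty((n_samples, len(rids)))
    kept = 0
    step = 0
    attempts = 0
    total_steps = warmup + n_samples * thinning
    while kept < n_samples:
        attempts += 1
        if attempts > 20 * total_steps + 1000:
            raise SamplingError("sampler failed to advance")
        d = rng.standard_normal(dim)
        u = N @ d
        # admissible step interval [alpha_lo, alpha_hi]
        alpha_lo, alpha_hi = -np.inf, np.inf
        pos = u > 1e-12
        neg = u < -1e-12
        if pos.any():
            alpha_hi = min(alpha_hi, np.min((ub[pos] - v[pos]) / u[pos]))
            alpha_lo = max(alpha_lo, np.max((lb[pos] - v[pos]) / u[pos]))
        if neg.any():
            alpha_hi = min(alpha_hi, np.min((lb[neg] - v[neg]) / u[neg]))
            alpha_lo = max(alpha_lo, np.max((ub[neg] - v[neg]) / u[neg]))
        if not np.isfinite(alpha_lo) or not np.isfinite(alpha_hi):
            # direction escapes the polytope to infinity: resample direction
            continue
        if alpha_hi < alpha_lo:
            # interval collapsed by numerical noise (degenerate direction):
            # stay put but let the chain advance
            alpha = 0.0
        else:
            alpha = rng.uniform(alpha_lo * shrink, alpha_hi * shrink)
        x = x + alpha * d
        v = N @ x
        step += 1
        if step > warmup and (step - warmup) % thinning == 0:
            samples[kept] = v
            kept += 1
    frame = pd.DataFrame(samples, columns=rids)
    return FluxSampleSet(frame, "hit-and-run", seed, thinning, warmup)
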