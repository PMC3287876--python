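"""Metropolis-Hastings over the fixed-size model space.

The proposal swaps one random active factor for one random inactive factor,
so q(gamma*|gamma) = q(gamma|gamma*) = 1/(m (p-m)) and the acceptance ratio
reduces to the posterior ratio.  Marginal inclusion probabilities are visit
counts: every post-burn-in iteration contributes its current model, repeats
included.
"""

from __future__ import annotations

import gzip
from collections import OrderedDict
from dataclasses import dataclass, field
from math import exp, isfinite
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chain",
    "InclusionSummary",
    "propose_swap",
    "mh_step",
    "run_chain",
    "marginal_inclusion",
    "convergence_check",
    "replay_audit",
]


@dataclass
class Chain:
    """Post-burn-in model visits of one sampler run.

    ``visits[j]`` holds the sorted active-factor indices at post-burn-in
    iteration j (shape n_iter x m).
    """

    visits: np.ndarray
    n_accept: int
    seed: int
    burn_in: int
    p: int
    log_posts: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_iter(self) -> int:
        return self.visits.shape[0]

    @property
    def m(self) -> int:
        return self.visits.shape[1]

    @property
    def acceptance_rate(self) -> float:
        return self.n_accept / self.n_iter


@dataclass
class InclusionSummary:
    """Per-factor marginal posterior inclusion probabilities."""

    probabilities: np.ndarray
    factor_ids: list[str]
    m: int
    p: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape[0] != self.p:
            raise ValueError("probabilities length differs from p")
        if len(self.factor_ids) != self.p:
            raise ValueError("factor_ids length differs from p")

    def ranking(self) -> list[int]:
        """Factor indices by descending posterior; ties broken by factor id."""
        order = sorted(
            range(self.p), key=lambda i: (-self.probabilities[i], self.factor_ids[i])
        )
        return order

    def top(self, k: int) -> list[int]:
        if k > self.p:
            raise ValueError(f"k={k} exceeds number of factors p={self.p}")
        return self.ranking()[:k]

    def as_dataframe(self) -> pd.DataFrame:
        ranks = np.empty(self.p, dtype=int)
        for r, i in enumerate(self.ranking(), start=1):
            ranks[i] = r
        return pd.DataFrame(
            {
                "factor_id": self.factor_ids,
                "marginal_posterior": self.probabilities,
                "rank": ranks,
            }
        )


def propose_swap(
    state: tuple[int, ...], p: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Swap a random active factor for a random inactive one.

    Returns a sorted tuple differing from ``state`` in exactly two positions.
    The proposal is symmetric: both directions have probability 1/(m (p-m)).
    """
    m = len(state)
    if not 0 < m < p:
        raise ValueError(f"need 0 < m < p (m={m}, p={p})")
    drop_pos = int(rng.integers(m))
    r = int(rng.integers(p - m))
    # map r to the r-th currently-inactive index (state is sorted ascending)
    for a in state:
        if a <= r:
            r += 1
        else:
            break
    new = list(state)
    new[drop_pos] = r
    new.sort()
    return tuple(new)


def mh_step(
    state: tuple[int, ...],
    proposal: tuple[int, ...],
    log_posterior_fn: Callable[[tuple[int, ...]], float],
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], bool]:
    """One Metropolis accept/reject decision.

    Accepts with probability min{exp(delta log posterior), 1}; a non-finite
    proposal log posterior is treated as -inf (auto-reject).
    """
    lp_cur = log_posterior_fn(state)
    lp_prop = log_posterior_fn(proposal)
    accepted = _accept(lp_cur, lp_prop, rng)
    return (proposal, True) if accepted else (state, False)


def _accept(lp_cur: float, lp_prop: float, rng: np.random.Generator) -> bool:
    if not isfinite(lp_prop):
        return False
    delta = lp_prop - lp_cur
    if delta >= 0:
        return True
    return rng.random() < exp(delta)


class _LRUCache:
    """Bounded evidence cache keyed by the sorted active set."""

    def __init__(self, fn: Callable[[tuple[int, ...]], float], maxsize: int) -> None:
        self.fn = fn
        self.maxsize = maxsize
        self._data: OrderedDict[tuple[int, ...], float] = OrderedDict()

    def __call__(self, key: tuple[int, ...]) -> float:
        data = self._data
        if key in data:
            data.move_to_end(key)
            return data[key]
        val = self.fn(key)
        data[key] = val
        if len(data) > self.maxsize:
            data.popitem(last=False)
        return val


def run_chain(
    log_posterior_fn: Callable[[tuple[int, ...]], float],
    p: int,
    m: int,
    n_iter: int = 100_000,
    burn_in: int = 1_000,
    seed: int = 0,
    init: Sequence[int] | None = None,
    cache_size: int = 500_000,
    audit_path: str | Path | None = None,
) -> Chain:
    """Run one Metropolis-Hastings chain and record post-burn-in visits.

    The initial state is a uniformly random m-subset from the seeded
    generator (unless ``init`` is given); ``burn_in`` iterations are then
    discarded and ``n_iter`` visits recorded, repeats included.  Evidence
    values are cached per model, so revisits cost a dictionary lookup.

    With ``audit_path`` set, one gzipped TSV line per recorded iteration logs
    the proposal, the log-posterior difference, the decision and the
    resulting state.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if not 0 < m < p:
        raise ValueError(f"need 0 < m < p (m={m}, p={p})")
    rng = np.random.default_rng(seed)
    if init is None:
        state = tuple(sorted(int(i) for i in rng.choice(p, size=m, replace=False)))
    else:
        state = tuple(sorted(int(i) for i in init))
        if len(state) != m:
            raise ValueError("init must contain exactly m distinct factors")
    cached = _LRUCache(log_posterior_fn, cache_size)
    lp = cached(state)
    if not isfinite(lp):
        raise ValueError("initial state has non-finite log posterior")

    visits = np.empty((n_iter, m), dtype=np.int64)
    log_posts = np.empty(n_iter)
    n_accept = 0
    audit = gzip.open(audit_path, "wt") if audit_path is not None else None
    if audit is not None:
        audit.write("iteration\tproposed\tdelta_log_post\taccepted\tstate\n")
    try:
        for j in range(burn_in + n_iter):
            proposal = propose_swap(state, p, rng)
            lp_prop = cached(proposal)
            delta = lp_prop - lp
            accepted = _accept(lp, lp_prop, rng)
            if accepted:
                state, lp = proposal, lp_prop
            if j >= burn_in:
                i = j - burn_in
                visits[i] = state
                log_posts[i] = lp
                n_accept += accepted
                if audit is not None:
                    audit.write(
                        f"{i}\t{','.join(map(str, proposal))}\t"
                        f"{delta:.10g}\t{int(accepted)}\t"
                        f"{','.join(map(str, state))}\n"
                    )
    finally:
        if audit is not None:
            audit.close()
    return Chain(
        visits=visits,
        n_accept=n_accept,
        seed=seed,
        burn_in=burn_in,
        p=p,
        log_posts=log_posts,
    )


def marginal_inclusion(
    chain: Chain, p: int | None = None, factor_ids: Sequence[str] | None = None
) -> InclusionSummary:
    """Visit-count marginal inclusion probabilities from a chain."""
    if chain.n_iter == 0:
        raise ValueError("chain is empty")
    p = chain.p if p is None else p
    counts = np.bincount(chain.visits.ravel(), minlength=p)
    probs = counts / chain.n_iter
    if factor_ids is None:
        width = len(str(p - 1))
        factor_ids = [f"f{i:0{width}d}" for i in range(p)]
    return InclusionSummary(
        probabilities=probs, factor_ids=list(factor_ids), m=chain.m, p=p
    )


def convergence_check(
    summary_a: InclusionSummary,
    summary_b: InclusionSummary,
    method: str = "pearson",
) -> float:
    """Correlation of inclusion probabilities between two independent chains.

    Reported as a diagnostic, never used as a gate; high correlation between
    chains started from different seeds suggests convergence.
    """
    if summary_a.p != summary_b.p or summary_a.factor_ids != summary_b.factor_ids:
        raise ValueError("summaries are over different factor sets")
    a, b = summary_a.probabilities, summary_b.probabilities
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance inclusion vector: degenerate run")
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        from scipy.stats import spearmanr

        return float(spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def replay_audit(path: str | Path, p: int) -> InclusionSummary:
    """Recompute the inclusion summary from a saved chain audit log."""
    states: list[list[int]] = []
    with gzip.open(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("iteration"):
            raise ValueError(f"{path} is not a chain audit log")
        for line in fh:
            states.append([int(x) for x in line.rstrip("\n").split("\t")[4].split(",")])
    if not states:
        raise ValueError(f"audit log {path} holds no iterations")
    visits = np.asarray(states, dtype=np.int64)
    chain = Chain(visits=visits, n_accept=0, seed=-1, burn_in=0, p=p)
    return marginal_inclusion(chain, p)
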