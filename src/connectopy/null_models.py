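"""Degree- and strength-preserving randomised reference networks.

Global efficiency and clustering grow with overall connectivity strength,
so raw group comparisons confound topology with weight scale.  Dividing a
subject's measure by its expected value in an ensemble of randomised
reference networks of the same size, degree sequence and weight
distribution removes that confound.  Modularity is invariant under a
global shift in connectivity strength and is never normalised.

The randomisation is two-stage:

1. topology: repeated Maslov-Sneppen double-edge swaps (default 10 per
   edge), which preserve the degree sequence exactly;
2. weights: the original weight multiset is re-assigned to the randomised
   edges greedily — the largest weight goes to the free edge whose
   endpoints currently have the largest remaining strength deficit — so
   per-node strengths are approximately preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import graph_measures
from .connectome import Connectome

__all__ = ["NullEnsemble", "randomize_network", "null_ensemble", "normalize_measure"]

_MEASURES = {
    "efficiency": graph_measures.global_efficiency,
    "clustering": lambda w: graph_measures.weighted_clustering(w)[0],
}


def _as_weights(c) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)


@dataclass
class NullEnsemble:
    """A set of randomised realisations of one source network."""

    realizations: list[np.ndarray]
    measure_means: dict[str, float] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.realizations)


def randomize_network(
    c,
    rewires_per_edge: int = 10,
    seed=None,
) -> np.ndarray:
    """One size-, degree- and strength-preserving randomised realisation.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.  With a
    fixed seed the output is bit-reproducible.
    """
    w = _as_weights(c)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    present = w[iu, ju] > 0
    edges = np.stack([iu[present], ju[present]], axis=1)
    m = edges.shape[0]
    if m < 2:
        raise ValueError("need at least two edges to rewire")
    weights_desc = np.sort(w[iu[present], ju[present]])[::-1]

    adj = w > 0
    n_pairs = n * (n - 1) // 2
    target_swaps = rewires_per_edge * m if m < n_pairs else 0  # complete: fixed
    max_attempts = 40 * target_swaps
    swaps = attempts = 0
    chunk = 1024
    pick = flip = None
    while swaps < target_swaps and attempts < max_attempts:
        if attempts % chunk == 0:
            pick = rng.integers(0, m, size=(chunk, 2))
            flip = rng.integers(0, 2, size=chunk)
        e1, e2 = pick[attempts % chunk]
        do_flip = flip[attempts % chunk]
        attempts += 1
        if e1 == e2:
            continue
        a, b = edges[e1]
        cc, d = edges[e2]
        if do_flip:
            cc, d = d, cc
        # proposed rewiring: (a,b),(c,d) -> (a,d),(c,b)
        if a == cc or a == d or b == cc or b == d:
            continue
        if adj[a, d] or adj[cc, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[cc, d] = adj[d, cc] = False
        adj[a, d] = adj[d, a] = True
        adj[cc, b] = adj[b, cc] = True
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(cc, b), max(cc, b))
        swaps += 1

    # greedy strength-rank weight reassignment
    strengths = w.sum(axis=1)
    residual = strengths.copy()
    u, v = edges[:, 0], edges[:, 1]
    unassigned = np.ones(m, dtype=bool)
    out = np.zeros_like(w)
    for wt in weights_desc:
        deficit = residual[u] + residual[v]
        deficit[~unassigned] = -np.inf
        e = int(np.argmax(deficit))
        unassigned[e] = False
        out[u[e], v[e]] = out[v[e], u[e]] = wt
        residual[u[e]] -= wt
        residual[v[e]] -= wt
    return out


def null_ensemble(
    c,
    measures=("efficiency", "clustering"),
    ensemble_size: int = 150,
    rewires_per_edge: int = 10,
    seed=None,
) -> NullEnsemble:
    """Ensemble of randomised realisations with mean measure values."""
    w = _as_weights(c)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    realizations = [
        randomize_network(
            w, rewires_per_edge=rewires_per_edge, seed=np.random.default_rng(child)
        )
        for child in ss.spawn(ensemble_size)
    ]
    means = {
        name: float(np.mean([_MEASURES[name](r) for r in realizations]))
        for name in measures
    }
    return NullEnsemble(realizations=realizations, measure_means=means)


def normalize_measure(
    c,
    measure: str = "efficiency",
    ensemble_size: int = 150,
    rewires_per_edge: int = 10,
    seed=None,
) -> float:
    """Measure of the network divided by its null-ensemble expectation.

    Returns NaN when the ensemble mean is zero (degenerate graph).
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; use 'efficiency' or 'clustering'")
    w = _as_weights(c)
    ens = null_ensemble(
        w,
        measures=(measure,),
        ensemble_size=ensemble_size,
        rewires_per_edge=rewires_per_edge,
        seed=seed,
    )
    expected = ens.measure_means[measure]
    if expected == 0:
        return float("nan")
    return _MEASURES[measure](w) / expected
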