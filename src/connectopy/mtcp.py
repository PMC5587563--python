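"""Multi-threshold cluster permutation (MTCP) inference.

Choosing a single edge density for thresholding a connectome is
arbitrary, and testing every density separately inflates the type-I
error.  MTCP tests the whole measure-versus-density curve at once:

1. an independent-samples t statistic (control mean minus patient mean)
   is computed at every density kappa of the grid;
2. the group labels are randomly reassigned ``n_perm`` times (the same
   relabelling is evaluated at every kappa) and the maximum |t| across
   the grid is recorded for each relabelling;
3. the 95th percentile of these maxima is the critical value ``t_crit``;
   a group difference is declared significant at the 5% level when the
   observed maximal |t| exceeds ``t_crit``;
4. as an effect size combining strength and persistence, the
   supercritical area-under-the-curve (scAUC) ``A`` is the trapezoidal
   area of ``|t_obs| - t_crit`` over the maximal contiguous supercritical
   run containing the peak, compared with ``A_crit``, the average scAUC
   of the supercritical permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from . import graph_measures, null_models
from .connectome import (
    Connectome,
    apply_mask,
    density_threshold,
    extract_hemisphere,
    median_summary,
)
from .group_stats import hedges_g

__all__ = [
    "GLOBAL_KAPPA_GRID",
    "NODAL_KAPPA_GRID",
    "MeasureCurve",
    "MTCPResult",
    "measure_curve",
    "mtcp_test",
    "nodal_mtcp_screen",
]

# measure-versus-density grids: coarse for global measures, finer for
# nodal ones
GLOBAL_KAPPA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)
NODAL_KAPPA_GRID = np.round(np.arange(0.10, 0.901, 0.02), 2)

_GLOBAL_MEASURES = ("efficiency", "clustering", "modularity")
_NODAL_MEASURES = ("strength", "local_efficiency", "local_clustering")


@dataclass
class MeasureCurve:
    """Per-subject values of one measure over the kappa grid."""

    kappas: np.ndarray
    values: np.ndarray  # (n_subjects, n_kappas)
    subject_ids: list[str]
    measure: str
    scope: str = "whole"
    node: str | None = None

    def __post_init__(self) -> None:
        self.kappas = np.asarray(self.kappas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.kappas) <= 0):
            raise ValueError("kappa grid must be strictly increasing")
        if self.values.shape != (len(self.subject_ids), len(self.kappas)):
            raise ValueError("values must be (n_subjects, n_kappas)")


@dataclass
class MTCPResult:
    """Observed t-curve, permutation calibration, supercritical cluster."""

    kappas: np.ndarray
    t_obs: np.ndarray
    t_crit: float
    t_max: float               # max |t| across the grid
    kappa_mtcp: float          # kappa of the peak group effect
    t_mtcp: float              # signed t at the peak
    significant: bool          # t_max > t_crit
    cluster: np.ndarray        # boolean supercritical run containing the peak
    A: float                   # supercritical AUC (0 when not significant)
    A_crit: float              # mean scAUC of supercritical permutations
    A_crit_with_zeros: float   # same average but counting subcritical perms as 0
    p: float
    n_perm: int
    dropped_kappas: np.ndarray = field(default_factory=lambda: np.array([]))


def _scope_cohort(cohort: list[Connectome], scope: str) -> list[Connectome]:
    if scope == "whole":
        return list(cohort)
    if scope in ("left", "right"):
        return [extract_hemisphere(c, scope) for c in cohort]
    raise ValueError(f"unknown scope {scope!r}")


def measure_curve(
    cohort: list[Connectome],
    scope: str = "whole",
    measure: str = "efficiency",
    normalize: bool = False,
    node: str | None = None,
    kappas: np.ndarray | None = None,
    ensemble_size: int = 150,
    modularity_repeats: int = 10,
    clustering_denominator: str = "degree",
    seed: int | None = None,
) -> MeasureCurve:
    """Per-subject measure values over the kappa grid.

    Masks are derived per kappa from the pooled median summary matrix of
    the (scoped) cohort and applied to every subject.  ``normalize=True``
    divides efficiency or clustering by its expectation under an
    independent null ensemble per subject and kappa (modularity and nodal
    measures are never normalised).  ``node`` selects a nodal measure for
    one region (by label).
    """
    nets = _scope_cohort(cohort, scope)
    if kappas is None:
        kappas = NODAL_KAPPA_GRID if node is not None else GLOBAL_KAPPA_GRID
    kappas = np.asarray(kappas, dtype=float)
    if node is None and measure not in _GLOBAL_MEASURES:
        if measure != "strength":
            raise ValueError(f"unknown global measure {measure!r}")
    if node is not None and measure not in _NODAL_MEASURES:
        raise ValueError(f"unknown nodal measure {measure!r}")
    if normalize and measure not in ("efficiency", "clustering"):
        raise ValueError("only efficiency and clustering are normalised")

    summary = median_summary(nets)
    masks = [density_threshold(summary, k) for k in kappas]
    node_idx = None
    if node is not None:
        node_idx = nets[0].parcellation.labels.index(node)

    ss = np.random.SeedSequence(seed)
    values = np.empty((len(nets), len(kappas)))
    for i, c in enumerate(nets):
        for j, m in enumerate(masks):
            w = apply_mask(c, m).weights
            values[i, j] = _evaluate(
                w, measure, node_idx, normalize, ensemble_size,
                modularity_repeats, clustering_denominator, ss,
            )
    return MeasureCurve(
        kappas=kappas, values=values,
        subject_ids=[c.subject_id for c in nets],
        measure=measure, scope=scope, node=node,
    )


def _evaluate(w, measure, node_idx, normalize, ensemble_size,
              modularity_repeats, clustering_denominator, seedseq):
    if node_idx is not None:
        if measure == "strength":
            return w[node_idx].sum()
        if measure == "local_efficiency":
            return graph_measures.local_efficiency(w)[node_idx]
        return graph_measures.weighted_clustering(
            w, denominator=clustering_denominator)[1][node_idx]
    if measure == "strength":
        return w.sum() / 2
    if measure == "modularity":
        child = seedseq.spawn(1)[0]
        return graph_measures.modularity(
            w, repeats=modularity_repeats,
            seed=int(child.generate_state(1)[0]) % (2**31),
        )
    if normalize:
        child = seedseq.spawn(1)[0]
        return null_models.normalize_measure(
            w, measure=measure, ensemble_size=ensemble_size, seed=child)
    if measure == "efficiency":
        return graph_measures.global_efficiency(w)
    return graph_measures.weighted_clustering(
        w, denominator=clustering_denominator)[0]


def _curve_t(values: np.ndarray, assign: np.ndarray, n1: int) -> np.ndarray:
    """Pooled t per kappa for many relabellings; values (n_subj, n_k)."""
    n = values.shape[0]
    n2 = n - n1
    a = assign.astype(float)
    s1 = a @ values
    s1sq = a @ values**2
    tot = values.sum(axis=0)
    totsq = (values**2).sum(axis=0)
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    ss1 = s1sq - n1 * m1**2
    ss2 = (totsq - s1sq) - n2 * m2**2
    sp2 = (ss1 + ss2) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def _cluster_area(abs_t: np.ndarray, t_crit: float, kappas: np.ndarray) -> tuple[np.ndarray, float]:
    """Supercritical run containing the peak, and its trapezoidal scAUC.

    The clipped excess ``max(|t| - t_crit, 0)`` is integrated over the
    run extended one grid step to each side (where the clipped value is
    zero), so that even a single supercritical density contributes a
    positive area: A > 0 exactly when t_max > t_crit.
    """
    above = abs_t > t_crit
    peak = int(np.argmax(abs_t))
    if not above[peak]:
        return np.zeros_like(above), 0.0
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(above) - 1 and above[hi + 1]:
        hi += 1
    cluster = np.zeros_like(above)
    cluster[lo : hi + 1] = True
    a, b = max(lo - 1, 0), min(hi + 1, len(above) - 1)
    excess = np.clip(abs_t[a : b + 1] - t_crit, 0.0, None)
    area = float(np.trapezoid(excess, kappas[a : b + 1]))
    return cluster, area


def mtcp_test(
    curve: MeasureCurve,
    groups: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    control: str = "control",
    exact: bool = False,
) -> MTCPResult:
    """Multi-threshold cluster permutation test of a measure curve.

    The t numerator is control mean minus patient mean, so positive
    values indicate a deficit in patients.  The same random relabelling
    is evaluated at every kappa.  Densities where the pooled variance is
    degenerate in the observed data are dropped with a warning.
    ``exact=True`` enumerates all distinct group assignments.
    """
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if control not in levels:
        raise ValueError(f"control label {control!r} not among groups {levels}")
    is_ctrl = groups == control
    n, n1 = len(groups), int(is_ctrl.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need at least two subjects per group")

    values = curve.values
    kappas = curve.kappas
    t_obs_full = _curve_t(values, is_ctrl[None, :], n1)[0]
    bad = ~np.isfinite(t_obs_full)
    if bad.any():
        warnings.warn(
            f"dropping {bad.sum()} kappa(s) with degenerate variance: "
            f"{kappas[bad]}"
        )
    dropped = kappas[bad]
    values = values[:, ~bad]
    kappas = kappas[~bad]
    t_obs = t_obs_full[~bad]
    if kappas.size == 0:
        raise ValueError("no usable densities remain")

    if exact:
        assign = np.zeros((comb(n, n1), n), dtype=bool)
        for r, idx in enumerate(combinations(range(n), n1)):
            assign[r, list(idx)] = True
    else:
        rng = np.random.default_rng(seed)
        assign = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            assign[r, rng.permutation(n)[:n1]] = True

    t_perm = np.abs(_curve_t(values, assign, n1))
    t_perm[~np.isfinite(t_perm)] = 0.0
    max_perm = t_perm.max(axis=1)
    t_crit = float(np.quantile(max_perm, 1 - alpha))

    abs_obs = np.abs(t_obs)
    peak = int(np.argmax(abs_obs))
    t_max = float(abs_obs[peak])
    significant = t_max > t_crit
    cluster, area = _cluster_area(abs_obs, t_crit, kappas)

    perm_areas = np.array(
        [_cluster_area(row, t_crit, kappas)[1] for row in t_perm[max_perm > t_crit]]
    )
    nonzero = perm_areas[perm_areas > 0]
    a_crit = float(nonzero.mean()) if nonzero.size else 0.0
    a_crit_zeros = float(perm_areas.sum() / len(max_perm)) if len(max_perm) else 0.0

    n_eff = assign.shape[0]
    exceed = int((max_perm >= t_max - 1e-12).sum())
    p = exceed / n_eff if exact else (exceed + 1) / (n_eff + 1)
    return MTCPResult(
        kappas=kappas, t_obs=t_obs, t_crit=t_crit, t_max=t_max,
        kappa_mtcp=float(kappas[peak]), t_mtcp=float(t_obs[peak]),
        significant=significant, cluster=cluster,
        A=area if significant else 0.0,
        A_crit=a_crit, A_crit_with_zeros=a_crit_zeros,
        p=float(min(p, 1.0)), n_perm=n_eff, dropped_kappas=dropped,
    )


def nodal_mtcp_screen(
    cohort: list[Connectome],
    groups: np.ndarray,
    scope: str = "right",
    measure: str = "strength",
    kappas: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    control: str = "control",
    clustering_denominator: str = "degree",
) -> pd.DataFrame:
    """Per-region MTCP screen of one nodal measure.

    Produces one row per region with the peak density kappa_mtcp, the
    group means of the measure at the peak, Hedges' g, t_max, t_crit, the
    scAUC A and A_crit, and significance flags.  The same set of random
    relabellings is shared across regions.  All-zero (constant) regions
    are dropped with a warning.
    """
    nets = _scope_cohort(cohort, scope)
    if kappas is None:
        kappas = NODAL_KAPPA_GRID
    kappas = np.asarray(kappas, dtype=float)
    if measure not in _NODAL_MEASURES:
        raise ValueError(f"unknown nodal measure {measure!r}")

    summary = median_summary(nets)
    masks = [density_threshold(summary, k) for k in kappas]
    labels = nets[0].parcellation.labels
    n_nodes = len(labels)
    # curves: (n_subjects, n_kappas, n_nodes)
    curves = np.empty((len(nets), len(kappas), n_nodes))
    for i, c in enumerate(nets):
        for j, m in enumerate(masks):
            w = apply_mask(c, m).weights
            if measure == "strength":
                curves[i, j] = w.sum(axis=1)
            elif measure == "local_efficiency":
                curves[i, j] = graph_measures.local_efficiency(w)
            else:
                curves[i, j] = graph_measures.weighted_clustering(
                    w, denominator=clustering_denominator)[1]

    groups = np.asarray(groups)
    is_ctrl = groups == control
    rng = np.random.default_rng(seed)
    n, n1 = len(groups), int(is_ctrl.sum())
    assign = np.zeros((n_perm, n), dtype=bool)
    for r in range(n_perm):
        assign[r, rng.permutation(n)[:n1]] = True

    rows = []
    for v, label in enumerate(labels):
        vals = curves[:, :, v]
        if np.allclose(vals, vals[0, 0]):
            warnings.warn(f"region {label!r} is constant across the grid; dropped")
            continue
        curve = MeasureCurve(
            kappas=kappas, values=vals,
            subject_ids=[c.subject_id for c in nets],
            measure=measure, scope=scope, node=label,
        )
        res = _mtcp_with_assignments(curve, is_ctrl, assign, alpha)
        jpeak = int(np.argmin(np.abs(curve.kappas - res.kappa_mtcp)))
        ctrl_vals = vals[is_ctrl, jpeak]
        pat_vals = vals[~is_ctrl, jpeak]
        g = hedges_g(ctrl_vals, pat_vals) if ctrl_vals.std() + pat_vals.std() > 0 else np.nan
        rows.append(
            {
                "measure": measure, "region": label,
                "kappa_mtcp": res.kappa_mtcp,
                "control_value": float(ctrl_vals.mean()),
                "patient_value": float(pat_vals.mean()),
                "hedges_g": g,
                "t_max": res.t_max, "t_crit": res.t_crit,
                "t_ratio": res.t_max / res.t_crit if res.t_crit > 0 else np.inf,
                "A": res.A, "A_crit": res.A_crit,
                "A_ratio": res.A / res.A_crit if res.A_crit > 0 else np.nan,
                "significant": res.significant,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def _mtcp_with_assignments(
    curve: MeasureCurve, is_ctrl: np.ndarray, assign: np.ndarray, alpha: float
) -> MTCPResult:
    """MTCP with a pre-drawn relabelling matrix (shared across regions)."""
    n1 = int(is_ctrl.sum())
    values, kappas = curve.values, curve.kappas
    t_obs = _curve_t(values, is_ctrl[None, :], n1)[0]
    ok = np.isfinite(t_obs)
    dropped = kappas[~ok]
    values, kappas, t_obs = values[:, ok], kappas[ok], t_obs[ok]
    t_perm = np.abs(_curve_t(values, assign, n1))
    t_perm[~np.isfinite(t_perm)] = 0.0
    max_perm = t_perm.max(axis=1)
    t_crit = float(np.quantile(max_perm, 1 - alpha))
    abs_obs = np.abs(t_obs)
    peak = int(np.argmax(abs_obs))
    t_max = float(abs_obs[peak])
    cluster, area = _cluster_area(abs_obs, t_crit, kappas)
    perm_areas = np.array(
        [_cluster_area(row, t_crit, kappas)[1] for row in t_perm[max_perm > t_crit]]
    )
    nonzero = perm_areas[perm_areas > 0]
    significant = t_max > t_crit
    exceed = int((max_perm >= t_max - 1e-12).sum())
    return MTCPResult(
        kappas=kappas, t_obs=t_obs, t_crit=t_crit, t_max=t_max,
        kappa_mtcp=float(kappas[peak]), t_mtcp=float(t_obs[peak]),
        significant=significant, cluster=cluster,
        A=area if significant else 0.0,
        A_crit=float(nonzero.mean()) if nonzero.size else 0.0,
        A_crit_with_zeros=float(perm_areas.sum() / len(max_perm)),
        p=float(min((exceed + 1) / (len(max_perm) + 1), 1.0)),
        n_perm=len(max_perm), dropped_kappas=dropped,
    )
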