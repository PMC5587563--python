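"""Synthetic cohorts of weighted connectomes with known ground truth.

The generator emulates the statistical structure the analysis assumes,
not the biophysics that produced it:

* a population template of symmetric lognormal weights with a block
  structure (intra-left, intra-right, interhemispheric), the
  interhemispheric block weaker by a fixed mean ratio, mirroring the
  modular organisation of the brain;
* per-subject matrices: template times per-edge lognormal noise times a
  per-subject global lognormal scale factor;
* a group-specific multiplicative deficit: patients' right-hemisphere
  intra-block weights are scaled by (1 - delta), delta = 0 being the
  exchangeable null;
* ROI volumes drawn lognormally and used to back-construct raw
  "streamline counts" so that volume normalisation round-trips through
  the construction pipeline;
* clinical severity scores for patients generated from each patient's
  right-hemisphere global efficiency (standardised within patients)
  through a linear or exponential link plus Gaussian noise, clipped to
  the 0-100 YGTSS scale.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .connectome import Connectome, build_connectome
from .graph_measures import global_efficiency
from .connectome import extract_hemisphere
from .parcellation import RegionParcellation, default_parcellation

__all__ = ["SimulationConfig", "simulate_cohort", "fixture_suite"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the study design being emulated: 36 regions per
    hemisphere, 13 controls and 13 patients, interhemispheric weights
    three times weaker on average than intra-hemispheric ones, and
    0-100 YGTSS-scale severity scores linked exponentially to
    right-hemisphere efficiency.
    """

    n_nodes_per_hemisphere: int = 36
    n_controls: int = 13
    n_patients: int = 13
    base_log_weight_mean: float = 0.0
    base_log_weight_sd: float = 1.0
    intra_inter_ratio: float = 3.0      # mean intra / mean inter weight
    delta: float = 0.0                  # right-hemisphere deficit in patients
    subject_noise_sd: float = 0.2       # per-subject global lognormal scale, log units
    edge_noise_sd: float = 0.4          # per-edge lognormal noise, log units
    volume_log_mean: float = 7.6        # ~2000 mm^3
    volume_log_sd: float = 0.3
    score_link: str = "exponential"     # none | linear | exponential
    score_intercept: float | None = None  # YGTSS at average efficiency
    score_coef: float | None = None     # per SD of efficiency; link-dependent default
    score_noise_sd: float = 5.0         # YGTSS points
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.delta < 1:
            raise ValueError("delta must lie in [0, 1)")
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least two subjects per group")
        for name in ("base_log_weight_sd", "subject_noise_sd", "edge_noise_sd",
                     "volume_log_sd", "score_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.intra_inter_ratio <= 0:
            raise ValueError("intra_inter_ratio must be positive")
        if self.score_link not in ("none", "linear", "exponential"):
            raise ValueError(f"unknown score link {self.score_link!r}")
        # link-dependent defaults chosen so scores stay on the 0-100 YGTSS
        # scale without saturating at the ceiling
        if self.score_coef is None:
            self.score_coef = 15.0 if self.score_link == "linear" else 0.7
        if self.score_intercept is None:
            self.score_intercept = 40.0 if self.score_link == "linear" else 25.0


def _parcellation_for(cfg: SimulationConfig, volumes: np.ndarray) -> RegionParcellation:
    m = cfg.n_nodes_per_hemisphere
    if m == 36:
        return default_parcellation(volumes=volumes)
    labels = tuple(f"lh_r{i:02d}" for i in range(m)) + tuple(
        f"rh_r{i:02d}" for i in range(m)
    )
    return RegionParcellation(
        labels=labels,
        hemisphere=("left",) * m + ("right",) * m,
        volume=tuple(volumes),
    )


def _symmetric_lognormal(rng, n, mu, sigma):
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    w[iu, ju] = rng.lognormal(mean=mu, sigma=sigma, size=iu.size)
    return w + w.T


def simulate_cohort(cfg: SimulationConfig):
    """Generate (connectomes, cohort table, ground-truth record).

    The cohort table has columns subject_id, group, age and score (NaN
    for controls).  The ground-truth record stores every parameter of
    the generating process plus the noiseless quantities (template, raw
    per-subject efficiencies) needed for parameter-recovery checks.
    """
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_nodes_per_hemisphere
    m = cfg.n_nodes_per_hemisphere
    left = slice(0, m)
    right = slice(m, n)

    mu = cfg.base_log_weight_mean
    template = _symmetric_lognormal(rng, n, mu, cfg.base_log_weight_sd)
    # weaken the interhemispheric block by the configured mean ratio
    template[left, right] /= cfg.intra_inter_ratio
    template[right, left] /= cfg.intra_inter_ratio

    volumes = rng.lognormal(cfg.volume_log_mean, cfg.volume_log_sd, size=n)
    parcellation = _parcellation_for(cfg, volumes)

    n_total = cfg.n_controls + cfg.n_patients
    groups = ["control"] * cfg.n_controls + ["patient"] * cfg.n_patients
    ages = np.round(rng.normal(34.5, 9.0, size=n_total), 1)

    connectomes: list[Connectome] = []
    iu, ju = np.triu_indices(n, k=1)
    for i, group in enumerate(groups):
        noise = np.zeros((n, n))
        noise[iu, ju] = rng.lognormal(0.0, cfg.edge_noise_sd, size=iu.size)
        noise += noise.T
        scale = rng.lognormal(0.0, cfg.subject_noise_sd)
        w = template * noise * scale
        if group == "patient" and cfg.delta > 0:
            w[right, right] *= 1 - cfg.delta
        np.fill_diagonal(w, 0.0)
        # raw directed streamline counts that volume-normalise back to w
        raw = w * np.outer(volumes, volumes)
        sid = f"{'ctrl' if group == 'control' else 'pat'}{i:02d}"
        connectomes.append(build_connectome(raw, parcellation, subject_id=sid))

    # clinical scores from right-hemisphere global efficiency (patients only)
    scores = np.full(n_total, np.nan)
    efficiencies = np.array(
        [global_efficiency(extract_hemisphere(c, "right")) for c in connectomes]
    )
    if cfg.score_link != "none":
        pat = np.array([g == "patient" for g in groups])
        e = efficiencies[pat]
        z = (e - e.mean()) / e.std() if e.std() > 0 else np.zeros_like(e)
        if cfg.score_link == "linear":
            clean = cfg.score_intercept + cfg.score_coef * z
        else:
            clean = cfg.score_intercept * np.exp(cfg.score_coef * z)
        noisy = clean + rng.normal(0.0, cfg.score_noise_sd, size=clean.size)
        scores[pat] = np.clip(noisy, 1.0, 100.0)

    cohort_table = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in connectomes],
            "group": groups,
            "age": ages,
            "score": scores,
        }
    )
    ground_truth = {
        "config": asdict(cfg),
        "template_median_intra_right": float(
            np.median(template[right, right][np.triu_indices(m, k=1)])
        ),
        "right_hemisphere_efficiency": efficiencies.tolist(),
        "volumes": volumes.tolist(),
    }
    return connectomes, cohort_table, ground_truth


def fixture_suite() -> dict[str, np.ndarray]:
    """Deterministic library of small weighted graphs for oracle tests.

    Keys: triangle, path3, star4, two_cliques (two disjoint unit-weight
    triangles), planted (12-node two-block partition), ring_lattice_36,
    random8/random10_* (seeded Erdos-Renyi-like weighted graphs).
    """
    out: dict[str, np.ndarray] = {}

    tri = np.zeros((3, 3))
    tri[[0, 1, 0], [1, 2, 2]] = 1.0
    out["triangle"] = tri + tri.T

    path = np.zeros((3, 3))
    path[[0, 1], [1, 2]] = 1.0
    out["path3"] = path + path.T

    star = np.zeros((4, 4))
    star[0, 1:] = 1.0
    out["star4"] = star + star.T

    two = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        two[a, b] = two[b, a] = 1.0
    out["two_cliques"] = two

    rng = np.random.default_rng(20170906)
    planted = np.zeros((12, 12))
    for i in range(12):
        for j in range(i + 1, 12):
            same = (i < 6) == (j < 6)
            p, lo, hi = (0.9, 0.5, 1.5) if same else (0.15, 0.1, 0.4)
            if rng.random() < p:
                planted[i, j] = planted[j, i] = rng.uniform(lo, hi)
    out["planted"] = planted

    ring = np.zeros((36, 36))
    for i in range(36):
        for k in (1, 2, 3):
            j = (i + k) % 36
            ring[i, j] = ring[j, i] = 1.0 / k
    out["ring_lattice_36"] = ring

    for name, n_nodes, seed in [("random8", 8, 8), ("random10_a", 10, 10),
                                ("random10_b", 10, 11)]:
        r = np.random.default_rng(seed)
        w = np.zeros((n_nodes, n_nodes))
        iu, ju = np.triu_indices(n_nodes, k=1)
        present = r.random(iu.size) < 0.5
        w[iu[present], ju[present]] = r.uniform(0.2, 2.0, size=present.sum())
        out[name] = w + w.T
    return out
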