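"""Synthetic lesioned-connectome cohorts with a planted mediation structure.

The generator emulates the study design the pipeline is built for: ~93
participants with chronic left-hemisphere strokes, each contributing a
100-node weighted connectome and a covariate/outcome row (chronological age,
predicted brain age, aphasia-severity score, lesion volume, months post
stroke, education, sex).

The causal structure is planted and recoverable:

* a path — the brain-age gap attenuates the edges incident to a designated
  mediator region by ``exp(-kappa * max(gap, 0))``, with ``kappa`` calibrated
  so the mediator's *computed* average controllability falls by about
  ``a_path`` units per year of gap.  The mediator is therefore a genuine
  network property, not a simulated scalar.
* b path / direct path — the severity score is a linear outcome in the
  computed mediator controllability (``b_path`` per unit), the gap
  (``c_prime`` per year), lesion volume (``beta_lesion`` per ml) and the
  demographic covariates, plus Gaussian noise, clipped to the 0-100 range of
  the severity scale.

A variable-level generator draws the mediator directly from the linear
equations instead of from a network, for exact parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import atlas
from .control import average_controllability, normalize_adjacency
from .prep import prep_connectome
from .types import Connectome

_SEED_CAP = 2**31 - 1


@dataclass
class SyntheticTruth:
    """Generator parameters; kept with the cohort to enable recovery tests."""

    n_participants: int = 93
    n_nodes: int = 100
    baseline_density: float = 0.3
    #: raw streamline-count scale; after size correction 2w/(v_i+v_j) with
    #: volumes of a few thousand mm^3 this leaves link weights O(1), a largest
    #: singular value of a few tens, and per-node average controllability in
    #: the 1-20 range seen on real stroke connectomes
    weight_scale: float = 1.0e5
    #: multiplicative strengthening of the mediator region's links (applied
    #: symmetrically to its homotopic partner): the posterior STG is a
    #: language-network hub, and hub regions carry high average controllability
    mediator_hub_boost: float = 2.0
    #: ("beta", alpha, beta) for per-participant lesion extent in (0, 1)
    lesion_severity_dist: tuple = ("beta", 2.0, 5.0)
    a_path: float = -0.05       # mediator-controllability units per year of gap
    b_path: float = -2.0        # severity points per controllability unit
    c_prime: float = -0.71      # direct severity points per year of gap
    beta_lesion: float = -0.125  # severity points per ml lesion volume
    noise_sd_m: float = 0.3     # variable-level mediator noise only
    noise_sd_y: float = 8.0
    mediator_node: str = "L_posterior_STG"
    seed: int = 0
    # demographic model (study ranges)
    gap_mean: float = 1.95
    gap_sd: float = 7.46
    age_range: tuple[float, float] = (29.0, 80.0)
    intercept: float = 98.5
    covariate_coefs: dict = field(
        default_factory=lambda: {
            "chronological_age": -0.45,
            "months_post_stroke": 0.01,
            "education": 0.5,
            "sex": -1.0,
        }
    )
    lesion_decay: float = 1.0   # e-folding of lesion damage in graph hops
    lesion_volume_scale: float = 465.0  # ml at severity 1 (plus 2.4 ml floor)

    def __post_init__(self) -> None:
        if not 0 < self.baseline_density <= 1:
            raise ValueError("baseline_density must lie in (0, 1]")
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be positive")
        if self.noise_sd_m < 0 or self.noise_sd_y < 0:
            raise ValueError("noise SDs must be nonnegative (0 allowed)")
        if not self.mediator_node.startswith("L_"):
            raise ValueError("mediator_node must be a left-hemisphere label")
        if self.lesion_severity_dist[0] != "beta":
            raise ValueError("lesion_severity_dist must be ('beta', a, b)")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["lesion_severity_dist"] = list(self.lesion_severity_dist)
        d["age_range"] = list(self.age_range)
        return d


@dataclass
class CohortBundle:
    connectomes: list[Connectome]
    table: pd.DataFrame
    truth: SyntheticTruth
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.connectomes) != len(self.table):
            raise ValueError("connectome count must equal table row count")
        if self.table["id"].duplicated().any():
            raise ValueError("participant identifiers must be unique")


# ---------------------------------------------------------------------------
# base connectome
# ---------------------------------------------------------------------------

def generate_base_connectome(
    n_nodes: int, density: float, weight_scale: float, seed: int
) -> Connectome:
    """Random symmetric nonnegative connectome with homotopic hemispheres.

    Intra-hemispheric links are generated for the left block and mirrored to
    the right block (identical before lesioning, so right-hemisphere
    percentile thresholding is meaningful); inter-hemispheric links are drawn
    independently.  Edge presence is Bernoulli(density); weights are uniform
    on ``(0.5, 1.5) * weight_scale``.  Homotopic region pairs share volumes.
    """
    if n_nodes % 2 != 0:
        raise ValueError(f"n_nodes must be even, got {n_nodes}")
    if not 0 < density <= 1:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    if weight_scale <= 0:
        raise ValueError(f"weight_scale must be positive, got {weight_scale}")
    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    labels, hemis = atlas.generic_labels(n_nodes)

    adj = np.zeros((n_nodes, n_nodes))
    # left intra-hemispheric block, mirrored to the right block
    for i in range(half):
        for j in range(i + 1, half):
            if rng.random() < density:
                w = rng.uniform(0.5, 1.5) * weight_scale
                adj[i, j] = adj[j, i] = w
                adj[i + half, j + half] = adj[j + half, i + half] = w
    # inter-hemispheric links
    for i in range(half):
        for j in range(half, n_nodes):
            if rng.random() < density:
                w = rng.uniform(0.5, 1.5) * weight_scale
                adj[i, j] = adj[j, i] = w
    vol_half = rng.uniform(2000.0, 12000.0, half)
    volumes = np.concatenate([vol_half, vol_half])
    return Connectome(
        node_ids=labels,
        hemisphere=np.array(hemis, dtype=object),
        adjacency=adj,
        region_volume=volumes,
        region_lesion_fraction=np.zeros(n_nodes),
    )


# ---------------------------------------------------------------------------
# lesion operator
# ---------------------------------------------------------------------------

def _hop_distances(adjacency: np.ndarray, source: int) -> np.ndarray:
    """Unweighted BFS hop distances; unreachable nodes get +inf."""
    n = adjacency.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    frontier = [source]
    d = 0
    nz = [np.flatnonzero(adjacency[i]) for i in range(n)]
    while frontier:
        d += 1
        nxt = []
        for i in frontier:
            for j in nz[i]:
                if dist[j] == np.inf:
                    dist[j] = d
                    nxt.append(j)
        frontier = nxt
    return dist


def apply_synthetic_lesion(
    base: Connectome,
    severity: float,
    focus_node: str,
    seed: int,
    decay: float = 1.0,
) -> Connectome:
    """Left-lateralized lesion centered on ``focus_node``.

    Each link with at least one left-hemisphere endpoint is deleted with
    probability ``severity * exp(-d / decay)`` — ``d`` the smaller hop
    distance of its endpoints from the focus — and, if kept, attenuated by the
    complementary factor.  Right-hemisphere-internal links are untouched.
    The per-region lesion fraction ``severity * exp(-d_i / decay)`` is
    recorded for left-hemisphere regions.
    """
    if not 0 <= severity < 1:
        raise ValueError(f"severity must lie in [0, 1), got {severity}")
    focus = base.index_of(focus_node)
    if base.hemisphere[focus] != "L":
        raise ValueError("lesion focus must be a left-hemisphere region")
    if severity == 0:
        return base.with_adjacency(base.adjacency.copy())
    rng = np.random.default_rng(seed)
    dist = _hop_distances(base.adjacency, focus)
    left = base.left_mask()
    damage = np.where(
        left & np.isfinite(dist), severity * np.exp(-dist / decay), 0.0
    )
    adj = base.adjacency.copy()
    n = base.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    touch = (left[iu] | left[ju]) & (adj[iu, ju] > 0)
    d_edge = np.minimum(
        np.where(np.isfinite(dist[iu]), dist[iu], np.inf),
        np.where(np.isfinite(dist[ju]), dist[ju], np.inf),
    )
    p_del = np.where(
        touch & np.isfinite(d_edge), severity * np.exp(-d_edge / decay), 0.0
    )
    u = rng.random(iu.size)
    for k in np.flatnonzero(touch):
        i, j = iu[k], ju[k]
        if u[k] < p_del[k]:
            adj[i, j] = adj[j, i] = 0.0
        elif p_del[k] > 0:
            adj[i, j] = adj[j, i] = adj[i, j] * (1.0 - p_del[k])
    out = base.with_adjacency(adj)
    out.region_lesion_fraction = damage
    return out


# ---------------------------------------------------------------------------
# gap -> mediator-controllability coupling
# ---------------------------------------------------------------------------

def _mediator_avg_controllability(conn: Connectome, mediator: str) -> float:
    normalized, _ = normalize_adjacency(conn.adjacency)
    return average_controllability(normalized, conn.index_of(mediator))


def _attenuate_mediator(conn: Connectome, mediator: str, factor: float) -> Connectome:
    adj = conn.adjacency.copy()
    k = conn.index_of(mediator)
    adj[k, :] *= factor
    adj[:, k] *= factor
    np.fill_diagonal(adj, 0.0)
    return conn.with_adjacency(adj)


def calibrate_gap_coupling(
    base: Connectome, truth: SyntheticTruth, percentile: float = 20.0
) -> float:
    """Find ``kappa`` so one SD of gap shifts mediator controllability by
    ``a_path * gap_sd`` units (slope ~ ``a_path`` per year of gap).

    Solved on the preprocessed lesion-free base connectome by bisection.
    Raises when the requested drop exceeds the mediator's headroom above the
    controllability floor of 1.
    """
    if truth.a_path == 0:
        return 0.0
    if truth.a_path > 0:
        raise ValueError(
            "a_path must be <= 0 at network level: the gap attenuates, never "
            "strengthens, mediator connectivity"
        )
    prepped, _ = prep_connectome(base, percentile=percentile)
    if truth.mediator_node not in prepped.node_ids:
        raise ValueError("mediator removed from the base connectome during prep")
    m0 = _mediator_avg_controllability(prepped, truth.mediator_node)
    target_drop = -truth.a_path * truth.gap_sd  # positive
    floor_drop = m0 - _mediator_avg_controllability(
        _attenuate_mediator(prepped, truth.mediator_node, 0.0), truth.mediator_node
    )
    if target_drop >= floor_drop:
        raise ValueError(
            f"requested controllability drop {target_drop:.3f} per gap SD exceeds "
            f"the mediator's headroom {floor_drop:.3f}; weaken a_path or densify "
            "the base connectome"
        )

    def objective(kappa: float) -> float:
        g = float(np.exp(-kappa * truth.gap_sd))
        m = _mediator_avg_controllability(
            _attenuate_mediator(prepped, truth.mediator_node, g),
            truth.mediator_node,
        )
        return (m0 - m) - target_drop

    hi = 1.0 / truth.gap_sd
    while objective(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("gap-coupling calibration failed to bracket")
    return float(brentq(objective, 0.0, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _draw_demographics(rng: np.random.Generator, truth: SyntheticTruth, n: int
                       ) -> pd.DataFrame:
    age = rng.uniform(*truth.age_range, n)
    gap = rng.normal(truth.gap_mean, truth.gap_sd, n)
    months = np.clip(rng.lognormal(np.log(40.0), 0.8, n), 10.0, 241.0)
    education = rng.integers(12, 21, n).astype(float)
    sex = (rng.random(n) < 0.602).astype(float)  # 1 = male
    _, a, b = truth.lesion_severity_dist
    severity = rng.beta(a, b, n)
    lesion_volume = 2.4 + severity * truth.lesion_volume_scale
    return pd.DataFrame(
        {
            "id": [f"P{i + 1:03d}" for i in range(n)],
            "chronological_age": age,
            "predicted_brain_age": age + gap,
            "brain_age_gap": gap,
            "lesion_volume": lesion_volume,
            "lesion_severity": severity,
            "months_post_stroke": months,
            "education": education,
            "sex": sex,
        }
    )


def _outcome(
    truth: SyntheticTruth,
    row: pd.Series,
    mediator_value: float,
    mediator_reference: float,
    noise: float,
) -> float:
    # the b path acts on the mediator's deviation from its lesion-free
    # reference value, so the intercept keeps the severity score on scale
    c = truth.covariate_coefs
    y = (
        truth.intercept
        + truth.c_prime * row["brain_age_gap"]
        + truth.b_path * (mediator_value - mediator_reference)
        + truth.beta_lesion * row["lesion_volume"]
        + c.get("chronological_age", 0.0) * row["chronological_age"]
        + c.get("months_post_stroke", 0.0) * row["months_post_stroke"]
        + c.get("education", 0.0) * row["education"]
        + c.get("sex", 0.0) * row["sex"]
        + noise
    )
    return y


def generate_cohort(truth: SyntheticTruth, percentile: float = 20.0) -> CohortBundle:
    """Full network-level cohort: connectomes plus covariate/outcome table.

    The mediator value entering the severity score is the mediator region's
    average controllability *computed* from each participant's preprocessed
    connectome, so the a path exists only through the network.  Severity is
    clipped to [0, 100]; the clipping count is recorded in the diagnostics.
    """
    rng = np.random.default_rng(truth.seed)
    base = generate_base_connectome(
        truth.n_nodes,
        truth.baseline_density,
        truth.weight_scale,
        int(rng.integers(_SEED_CAP)),
    )
    if truth.mediator_hub_boost != 1.0:
        # hub-like mediator: strengthen its links and, to preserve homotopic
        # mirror symmetry, those of its right-hemisphere partner
        adj = base.adjacency.copy()
        half = truth.n_nodes // 2
        k = base.index_of(truth.mediator_node)
        for idx in (k, k + half):
            adj[idx, :] *= truth.mediator_hub_boost
            adj[:, idx] *= truth.mediator_hub_boost
        np.fill_diagonal(adj, 0.0)
        base = base.with_adjacency(adj)
    kappa = calibrate_gap_coupling(base, truth, percentile=percentile)
    base_prepped, _ = prep_connectome(base, percentile=percentile)
    m_ref = _mediator_avg_controllability(base_prepped, truth.mediator_node)
    table = _draw_demographics(rng, truth, truth.n_participants)

    left_labels = [
        lbl
        for lbl, h in zip(base.node_ids, base.hemisphere)
        if h == "L" and lbl != truth.mediator_node
    ]
    connectomes: list[Connectome] = []
    mediator_ctrl = np.empty(truth.n_participants)
    n_clipped = 0
    wab = np.empty(truth.n_participants)
    for i in range(truth.n_participants):
        row = table.iloc[i]
        focus = left_labels[int(rng.integers(len(left_labels)))]
        lesioned = apply_synthetic_lesion(
            base,
            float(row["lesion_severity"]),
            focus,
            int(rng.integers(_SEED_CAP)),
            decay=truth.lesion_decay,
        )
        g = float(np.exp(-kappa * max(float(row["brain_age_gap"]), 0.0)))
        conn = _attenuate_mediator(lesioned, truth.mediator_node, g)
        connectomes.append(conn)
        try:
            prepped, _ = prep_connectome(conn, percentile=percentile)
        except ValueError:
            mediator_ctrl[i] = np.nan
        else:
            if truth.mediator_node in prepped.node_ids:
                mediator_ctrl[i] = _mediator_avg_controllability(
                    prepped, truth.mediator_node
                )
            else:
                mediator_ctrl[i] = np.nan
        noise = rng.normal(0.0, truth.noise_sd_y) if truth.noise_sd_y > 0 else 0.0
        m_for_outcome = mediator_ctrl[i] if np.isfinite(mediator_ctrl[i]) else m_ref
        raw = _outcome(truth, row, m_for_outcome, m_ref, noise)
        clipped = min(max(raw, 0.0), 100.0)
        if clipped != raw:
            n_clipped += 1
        wab[i] = clipped
    table = table.assign(wab_aq=wab, mediator_controllability=mediator_ctrl)
    diagnostics = {
        "kappa": kappa,
        "mediator_reference": m_ref,
        "n_clipped": n_clipped,
        "clipping_rate": n_clipped / truth.n_participants,
        "n_mediator_missing": int(np.sum(~np.isfinite(mediator_ctrl))),
    }
    return CohortBundle(
        connectomes=connectomes, table=table, truth=truth, diagnostics=diagnostics
    )


def generate_variable_level_cohort(
    truth: SyntheticTruth, mediator_baseline: float = 1.5
) -> pd.DataFrame:
    """Cohort table with the mediator drawn from the linear equations.

    ``m = m0 + a x + eps_m`` and ``y = y0 + c' x + b m + beta_l * lesion +
    covariate terms + eps_y`` with no clipping — for exact mediation
    parameter-recovery tests where the planted coefficients must come back to
    solver precision at zero noise.
    """
    rng = np.random.default_rng(truth.seed)
    table = _draw_demographics(rng, truth, truth.n_participants)
    eps_m = (
        rng.normal(0.0, truth.noise_sd_m, truth.n_participants)
        if truth.noise_sd_m > 0
        else np.zeros(truth.n_participants)
    )
    m = mediator_baseline + truth.a_path * table["brain_age_gap"].to_numpy() + eps_m
    eps_y = (
        rng.normal(0.0, truth.noise_sd_y, truth.n_participants)
        if truth.noise_sd_y > 0
        else np.zeros(truth.n_participants)
    )
    y = np.array(
        [
            _outcome(truth, table.iloc[i], m[i], mediator_baseline, eps_y[i])
            for i in range(truth.n_participants)
        ]
    )
    return table.assign(mediator_controllability=m, wab_aq=y)


#: covariate columns entering every adjusted model, in the study's order
COVARIATE_COLUMNS = [
    "chronological_age",
    "lesion_volume",
    "months_post_stroke",
    "education",
    "sex",
]
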