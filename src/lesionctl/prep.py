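"""Stroke-adapted connectome preprocessing.

The pipeline order is fixed: average directed streamline counts into an
undirected link, correct links for region size, zero out spurious links below
the 20th percentile of the (lesion-free) right hemisphere's link weights, then
drop zero-degree nodes one at a time until none remain.  Every stage preserves
symmetry, nonnegativity and the zero diagonal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Connectome, PrepReport, link_count


def symmetrize_streamlines(directed_counts: np.ndarray) -> np.ndarray:
    """Average streamline counts in both directions into an undirected weight.

    ``out[i, j] = (in[i, j] + in[j, i]) / 2`` with the diagonal forced to zero.
    """
    a = np.asarray(directed_counts, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"streamline-count matrix must be square, got {a.shape}")
    if np.any(a < 0):
        raise ValueError("streamline counts must be nonnegative")
    out = (a + a.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def correct_links(adjacency: np.ndarray, region_volume: np.ndarray) -> np.ndarray:
    """Correct link weights for the sizes of the two endpoint regions.

    ``w'(i, j) = 2 w(i, j) / (vol_i + vol_j)``.  Streamline-distance correction
    is assumed to have been applied by the tracking stage and is not reapplied.
    """
    vol = np.asarray(region_volume, dtype=float)
    if np.any(vol <= 0):
        bad = np.flatnonzero(vol <= 0)
        raise ValueError(f"region volumes must be positive (indices {bad.tolist()})")
    a = np.asarray(adjacency, dtype=float)
    denom = vol[:, None] + vol[None, :]
    out = 2.0 * a / denom
    np.fill_diagonal(out, 0.0)
    return out


def threshold_spurious(
    conn: Connectome, percentile: float = 20.0
) -> tuple[Connectome, PrepReport]:
    """Zero out links weaker than a right-hemisphere percentile.

    The threshold is the given percentile (linear interpolation between order
    statistics) of the *nonzero* links whose two endpoints both lie in the
    right hemisphere — the hemisphere untouched by the lesion — and every link
    in the whole matrix strictly below it is removed.
    """
    right = conn.hemisphere == "R"
    a = conn.adjacency
    iu, ju = np.triu_indices(conn.n_nodes, k=1)
    rr = right[iu] & right[ju]
    rr_weights = a[iu[rr], ju[rr]]
    rr_weights = rr_weights[rr_weights > 0]
    if rr_weights.size == 0:
        raise ValueError(
            "no nonzero right-hemisphere-internal links: percentile threshold undefined"
        )
    threshold = float(np.percentile(rr_weights, percentile))
    before = link_count(a)
    out = a.copy()
    out[(out < threshold) & (out > 0)] = 0.0
    new = conn.with_adjacency(out)
    report = PrepReport(
        removed_nodes=[],
        n_links_before=before,
        n_links_after=link_count(out),
        threshold_value=threshold,
        right_hemisphere_link_count=int(rr_weights.size),
    )
    return new, report


def remove_zero_degree(conn: Connectome) -> tuple[Connectome, PrepReport]:
    """Drop zero-degree nodes one by one, re-evaluating after each removal.

    Ties are broken by node order (lowest index first).  Raises if the
    procedure would empty the network.
    """
    current = conn
    removed: list[tuple[str, int]] = []
    rnd = 0
    before = link_count(conn.adjacency)
    while True:
        deg = current.degrees()
        zeros = np.flatnonzero(deg == 0)
        if zeros.size == 0:
            break
        if zeros.size == current.n_nodes:
            raise ValueError("all nodes are zero-degree: empty network after removal")
        rnd += 1
        idx = int(zeros[0])
        removed.append((current.node_ids[idx], rnd))
        current = current.subset([i for i in range(current.n_nodes) if i != idx])
    report = PrepReport(
        removed_nodes=removed,
        n_links_before=before,
        n_links_after=link_count(current.adjacency),
    )
    return current, report


def prep_connectome(
    conn: Connectome, percentile: float = 20.0, correct: bool = True
) -> tuple[Connectome, PrepReport]:
    """Full preprocessing: symmetrize -> size-correct -> threshold -> prune.

    Input adjacency may be a raw (possibly directed) count matrix; the output
    connectome has no zero-degree nodes.  The returned report merges the
    thresholding and removal ledgers.
    """
    adj = symmetrize_streamlines(conn.adjacency)
    if correct:
        adj = correct_links(adj, conn.region_volume)
    staged = conn.with_adjacency(adj)
    thresholded, t_report = threshold_spurious(staged, percentile)
    pruned, r_report = remove_zero_degree(thresholded)
    report = PrepReport(
        removed_nodes=r_report.removed_nodes,
        n_links_before=t_report.n_links_before,
        n_links_after=r_report.n_links_after,
        threshold_value=t_report.threshold_value,
        right_hemisphere_link_count=t_report.right_hemisphere_link_count,
    )
    return pruned, report


def regional_lesion_summary(cohort: list[Connectome]) -> pd.DataFrame:
    """Per-region means of lesion fraction, degree and strength over a cohort.

    Regions removed from a participant's connectome are skipped for that
    participant; the mean is over participants possessing the region.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rows: dict[str, dict[str, list[float]]] = {}
    for conn in cohort:
        deg = conn.degrees()
        stren = conn.strengths()
        for i, label in enumerate(conn.node_ids):
            acc = rows.setdefault(
                label, {"lesion_fraction": [], "degree": [], "strength": []}
            )
            acc["lesion_fraction"].append(float(conn.region_lesion_fraction[i]))
            acc["degree"].append(float(deg[i]))
            acc["strength"].append(float(stren[i]))
    records = []
    for label, acc in rows.items():
        records.append(
            {
                "region": label,
                "mean_lesion_fraction": float(np.mean(acc["lesion_fraction"])),
                "mean_degree": float(np.mean(acc["degree"])),
                "mean_strength": float(np.mean(acc["strength"])),
                "n_participants": len(acc["degree"]),
            }
        )
    return pd.DataFrame.from_records(records).set_index("region")
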