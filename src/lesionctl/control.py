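"""Linear network controllability on structural connectomes.

The connectome adjacency ``A`` defines discrete-time linear dynamics
``x(t+1) = A x(t) + B u(t)``.  With the adjacency scaled by ``1 / (1 + sigma_max)``
the system is stable and the infinite-horizon controllability Gramian of a
single driver node exists, as the solution of the discrete Lyapunov equation

    A W A^T - W + B B^T = 0,       B = indicator column of the driver.

Average controllability of a node is ``trace(W)`` for that driver — the node's
capacity to spread input energy through the network; it is bounded below by 1
(the t=0 term) and equals 1 exactly when the driver is disconnected.  The
global-controllability check asks that the smallest Gramian eigenvalue be
strictly positive for every driver: every region can steer the whole network.

Single-driver Gramians are notoriously ill-conditioned: already at ten nodes
the genuine smallest eigenvalue can sit below 1e-80, far beneath any floating
tolerance, so thresholding the computed eigenvalue cannot decide
controllability.  The verdict therefore uses the PBH test, which for symmetric
dynamics is *exactly* equivalent to a positive smallest Gramian eigenvalue:
the system is controllable from a driver node iff every eigenvalue of ``A`` is
simple and no eigenvector vanishes at that node.  The raw double-precision
smallest eigenvalues are still computed and reported alongside the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .types import Connectome

DEFAULT_TOLERANCE = 1e-12

#: relative gap below which two eigenvalues of A count as degenerate (PBH)
EIGENVALUE_GAP_RTOL = 1e-9


@dataclass
class ControlResult:
    """Per-node controllability metrics for one connectome."""

    node_avg_controllability: dict[str, float]
    min_gramian_eigenvalue: dict[str, float]
    globally_controllable: bool  # PBH verdict: controllable from every node
    normalization_factor: float
    tolerance: float
    horizon: str = "infinite"
    absent_regions: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "node_avg_controllability": self.node_avg_controllability,
            "min_gramian_eigenvalue": self.min_gramian_eigenvalue,
            "globally_controllable": self.globally_controllable,
            "normalization_factor": self.normalization_factor,
            "tolerance": self.tolerance,
            "horizon": self.horizon,
            "absent_regions": self.absent_regions or [],
        }


def normalize_adjacency(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale the adjacency by ``1 + sigma_max`` so the dynamics are stable.

    Returns the normalized matrix and the factor.  The zero matrix passes
    through unchanged (factor 1).  Self-loops are forced to zero first.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got {a.shape}")
    if np.max(np.abs(a - a.T), initial=0.0) > 1e-9:
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    if not np.any(a):
        return a, 1.0
    sigma_max = float(np.linalg.norm(a, 2))
    factor = 1.0 + sigma_max
    return a / factor, factor


def _check_stable(a: np.ndarray) -> None:
    rho = float(np.max(np.abs(np.linalg.eigvalsh((a + a.T) / 2))))
    if rho >= 1.0:
        raise ValueError(
            f"spectral radius {rho:.6f} >= 1: normalize the adjacency first"
        )


def _driver_column(n: int, driver: int) -> np.ndarray:
    if not 0 <= driver < n:
        raise ValueError(f"driver index {driver} out of range for n={n}")
    b = np.zeros((n, 1))
    b[driver, 0] = 1.0
    return b


def controllability_gramian(normalized: np.ndarray, driver: int) -> np.ndarray:
    """Infinite-horizon single-driver Gramian via the discrete Lyapunov equation."""
    a = np.asarray(normalized, dtype=float)
    _check_stable(a)
    b = _driver_column(a.shape[0], driver)
    w = solve_discrete_lyapunov(a, b @ b.T)
    return (w + w.T) / 2.0  # enforce exact symmetry


def average_controllability(normalized: np.ndarray, driver: int) -> float:
    """Trace of the driver node's controllability Gramian."""
    return float(np.trace(controllability_gramian(normalized, driver)))


def pbh_controllable_nodes(a: np.ndarray, tolerance: float = DEFAULT_TOLERANCE
                           ) -> np.ndarray:
    """Per-node exact controllability verdict via the PBH eigenvector test.

    For symmetric ``A`` the smallest eigenvalue of node ``k``'s Gramian is
    strictly positive iff all eigenvalues of ``A`` are simple and no
    eigenvector has a zero component at ``k``.  Returns a boolean array; if
    any eigenvalue is (numerically) repeated, no single node is controllable.
    """
    eigvals, eigvecs = np.linalg.eigh(a)
    n = a.shape[0]
    scale = max(float(np.max(np.abs(eigvals))), 1.0)
    gaps = np.diff(np.sort(eigvals))
    if np.any(gaps < EIGENVALUE_GAP_RTOL * scale):
        return np.zeros(n, dtype=bool)
    component_floor = np.abs(eigvecs).min(axis=1)  # per node, over eigenvectors
    return component_floor > tolerance


def global_controllability(
    normalized: np.ndarray,
    tolerance: float = DEFAULT_TOLERANCE,
    check_zero_degree: bool = True,
) -> tuple[bool, np.ndarray]:
    """All-drivers controllability verdict and per-driver smallest Gramian
    eigenvalue.

    The verdict (``True`` iff the network can be steered from *every* single
    node) comes from the PBH test, the exact equivalent of a positive smallest
    Gramian eigenvalue; the reported eigenvalues are the double-precision
    values from the Lyapunov solutions, which hit the floating-point floor on
    all but the smallest networks.

    By default the presence of a zero-degree node is an error: the caller is
    expected to have pruned the connectome first.
    """
    a = np.asarray(normalized, dtype=float)
    _check_stable(a)
    n = a.shape[0]
    if check_zero_degree:
        deg = np.count_nonzero(a - np.diag(np.diag(a)), axis=1)
        if np.any(deg == 0):
            bad = np.flatnonzero(deg == 0).tolist()
            raise ValueError(
                f"zero-degree nodes present at indices {bad}: "
                "run zero-degree removal before the controllability check"
            )
    lam_min = np.empty(n)
    for k in range(n):
        w = controllability_gramian(a, k)
        lam_min[k] = float(np.linalg.eigvalsh(w)[0])
    controllable = bool(np.all(pbh_controllable_nodes(a, tolerance)))
    return controllable, lam_min


def batch_controllability(
    conn: Connectome,
    tolerance: float = DEFAULT_TOLERANCE,
    all_node_ids: list[str] | None = None,
) -> ControlResult:
    """Normalize, run every single-driver Gramian, and assemble a ControlResult.

    ``all_node_ids`` may list the full atlas node space; regions missing from
    ``conn`` (removed upstream as zero-degree) are reported as absent.
    """
    normalized, factor = normalize_adjacency(conn.adjacency)
    if np.any(conn.degrees() == 0):
        raise ValueError(
            "zero-degree nodes present: run zero-degree removal before "
            "batch controllability"
        )
    n = conn.n_nodes
    avg: dict[str, float] = {}
    lam_min = np.empty(n)
    for k, label in enumerate(conn.node_ids):
        w = controllability_gramian(normalized, k)
        avg[label] = float(np.trace(w))
        lam_min[k] = float(np.linalg.eigvalsh(w)[0])
    controllable = bool(np.all(pbh_controllable_nodes(normalized, tolerance)))
    absent = []
    if all_node_ids is not None:
        present = set(conn.node_ids)
        absent = [lbl for lbl in all_node_ids if lbl not in present]
    return ControlResult(
        node_avg_controllability=avg,
        min_gramian_eigenvalue={
            label: float(lam_min[k]) for k, label in enumerate(conn.node_ids)
        },
        globally_controllable=controllable,
        normalization_factor=factor,
        tolerance=tolerance,
        absent_regions=absent,
    )
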