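"""Formats and configuration.

Adjacency matrices travel as dense TSV (region labels as header row and index
column) or MatrixMarket (``.mtx``, node order supplied by the metadata table);
node metadata as TSV; covariate tables as CSV; reports as JSON; pipeline
configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .types import Connectome

logger = logging.getLogger("lesionctl")

ASYMMETRY_WARN_TOL = 1e-6


# ---------------------------------------------------------------------------
# connectome I/O
# ---------------------------------------------------------------------------

def write_connectome(conn: Connectome, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    matrix_path = Path(matrix_path)
    meta = pd.DataFrame(
        {
            "node_id": conn.node_ids,
            "hemisphere": list(conn.hemisphere),
            "volume_mm3": conn.region_volume,
            "lesion_fraction": conn.region_lesion_fraction,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)
    if matrix_path.suffix == ".mtx":
        scipy.io.mmwrite(
            str(matrix_path),
            scipy.sparse.coo_matrix(conn.adjacency),
            symmetry="symmetric",
        )
    else:
        pd.DataFrame(
            conn.adjacency, index=conn.node_ids, columns=conn.node_ids
        ).to_csv(matrix_path, sep="\t")


def read_connectome(matrix_path: str | Path, metadata_path: str | Path) -> Connectome:
    """Load and validate a connectome from disk.

    NaNs and negative weights are rejected with the offending cell named;
    asymmetry up to 1e-6 is silently symmetrized with a logged warning,
    anything larger is rejected.
    """
    matrix_path = Path(matrix_path)
    meta = pd.read_csv(metadata_path, sep="\t")
    labels = meta["node_id"].astype(str).tolist()
    if matrix_path.suffix == ".mtx":
        adj = np.asarray(scipy.io.mmread(str(matrix_path)).todense(), dtype=float)
        if adj.shape[0] != len(labels):
            raise ValueError(
                f"matrix size {adj.shape[0]} does not match {len(labels)} "
                "metadata rows"
            )
    else:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if list(frame.index.astype(str)) != labels or list(
            frame.columns.astype(str)
        ) != labels:
            raise ValueError(
                "matrix header/index labels do not match the metadata node_id "
                "column"
            )
        adj = frame.to_numpy(dtype=float)
    if np.any(np.isnan(adj)):
        i, j = np.argwhere(np.isnan(adj))[0]
        raise ValueError(f"NaN adjacency entry at ({labels[i]}, {labels[j]})")
    if np.any(adj < 0):
        i, j = np.argwhere(adj < 0)[0]
        raise ValueError(f"negative weight at ({labels[i]}, {labels[j]})")
    asym = float(np.max(np.abs(adj - adj.T), initial=0.0))
    if asym > ASYMMETRY_WARN_TOL:
        raise ValueError(f"adjacency asymmetry {asym:.3g} exceeds {ASYMMETRY_WARN_TOL}")
    if asym > 0:
        logger.warning(
            "adjacency asymmetry %.3g within tolerance: symmetrizing", asym
        )
        adj = (adj + adj.T) / 2.0
    np.fill_diagonal(adj, 0.0)
    return Connectome(
        node_ids=labels,
        hemisphere=meta["hemisphere"].astype(str).to_numpy(dtype=object),
        adjacency=adj,
        region_volume=meta["volume_mm3"].to_numpy(dtype=float),
        region_lesion_fraction=meta["lesion_fraction"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything run_pipeline needs; exactly one input source.

    Either ``connectome_dir``/``covariate_table`` point at real data on disk,
    or ``synthetic`` holds a SyntheticTruth field block.
    """

    output_dir: str = "results"
    connectome_dir: str | None = None
    covariate_table: str | None = None
    synthetic: dict | None = None
    # prep
    percentile: float = 20.0
    correct_links: bool = True
    # control
    tolerance: float = 1e-12
    global_check: bool = False
    regions: list[str] = field(default_factory=list)  # empty = default ROI set
    # stats
    n_boot: int = 5000
    ci: float = 0.95
    seed: int = 0
    mediators: list[str] = field(default_factory=list)  # empty = default set
    run_graph_metrics: bool = True

    def __post_init__(self) -> None:
        real = self.connectome_dir is not None or self.covariate_table is not None
        if real and self.synthetic is not None:
            raise ValueError("config must give real-input paths OR a synthetic block")
        if not real and self.synthetic is None:
            raise ValueError("config gives neither input paths nor a synthetic block")
        if real and (self.connectome_dir is None or self.covariate_table is None):
            raise ValueError(
                "real input needs both connectome_dir and covariate_table"
            )

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def write_json(obj: dict, path: str | Path, config_hash: str | None = None) -> None:
    if config_hash is not None:
        obj = {"config_hash": config_hash, **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def write_table(frame: pd.DataFrame, path: str | Path,
                config_hash: str | None = None, **to_csv_kwargs) -> None:
    """CSV/TSV with a leading ``# config_hash`` comment line."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash: {config_hash}\n")
        frame.to_csv(fh, sep=sep, **to_csv_kwargs)
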