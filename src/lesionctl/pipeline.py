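"""End-to-end orchestration: ingest -> prep -> control -> metrics -> stats.

The summary JSON gathers, per the study design: the brain-age descriptives
and paired t-test, the three severity regressions (chronological age, brain
age, brain-age gap), the varimax PCA over the language-region controllability
table, one mediation model per candidate mediator, and the LMG decomposition
of the final severity model.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas, metrics, stats
from .cohort import COVARIATE_COLUMNS, SyntheticTruth, generate_cohort
from .control import average_controllability, normalize_adjacency
from .io import PipelineConfig, read_connectome, write_json, write_table
from .prep import prep_connectome, regional_lesion_summary
from .types import Connectome

logger = logging.getLogger("lesionctl")


def _load_real_cohort(config: PipelineConfig
                      ) -> tuple[list[Connectome], pd.DataFrame]:
    table = pd.read_csv(config.covariate_table, comment="#")
    conns = []
    cdir = Path(config.connectome_dir)
    for pid in table["id"].astype(str):
        matrix = cdir / f"{pid}.tsv"
        if not matrix.exists():
            matrix = cdir / f"{pid}.mtx"
        conns.append(read_connectome(matrix, cdir / f"{pid}_nodes.tsv"))
    return conns, table


def _roi_controllability(
    prepped: Connectome, regions: list[str], tolerance: float
) -> dict[str, float]:
    normalized, _ = normalize_adjacency(prepped.adjacency)
    out = {}
    for label in regions:
        if label in prepped.node_ids:
            out[label] = average_controllability(
                normalized, prepped.index_of(label)
            )
        else:
            out[label] = float("nan")
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write per-stage artifacts.

    Returns the summary dictionary that is also written to
    ``<output_dir>/summary.json``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash

    # ---- ingest ----------------------------------------------------------
    if config.synthetic is not None:
        truth = SyntheticTruth(**config.synthetic)
        logger.info("simulating cohort: n=%d seed=%d", truth.n_participants, truth.seed)
        bundle = generate_cohort(truth, percentile=config.percentile)
        connectomes, table = bundle.connectomes, bundle.table
        synth_diag = bundle.diagnostics
    else:
        connectomes, table = _load_real_cohort(config)
        synth_diag = None
    ids = table["id"].astype(str).tolist()

    # ---- prep ------------------------------------------------------------
    prepped_list, prep_reports = [], []
    for pid, conn in zip(ids, connectomes):
        try:
            prepped, report = prep_connectome(
                conn, percentile=config.percentile, correct=config.correct_links
            )
        except ValueError as err:
            raise RuntimeError(f"prep failed for participant {pid}: {err}") from err
        prepped_list.append(prepped)
        prep_reports.append(report.to_dict())
    write_json({"reports": dict(zip(ids, prep_reports))},
               out_dir / "prep_reports.json", chash)
    write_table(regional_lesion_summary(prepped_list),
                out_dir / "regional_summary.csv", chash)

    # ---- control ---------------------------------------------------------
    regions = config.regions or sorted(
        set(atlas.LANGUAGE_ROIS) | set(config.mediators or atlas.CANDIDATE_MEDIATORS)
    )
    ctrl_rows = []
    for pid, prepped in zip(ids, prepped_list):
        vals = _roi_controllability(prepped, regions, config.tolerance)
        for label, v in vals.items():
            ctrl_rows.append({"participant": pid, "region": label,
                              "avg_controllability": v})
    ctrl_long = pd.DataFrame(ctrl_rows)
    write_table(ctrl_long, out_dir / "controllability.csv", chash, index=False)
    ctrl_wide = ctrl_long.pivot(index="participant", columns="region",
                                values="avg_controllability")
    ctrl_wide = ctrl_wide.loc[ids]

    if config.global_check:
        from .control import batch_controllability

        verdicts = {}
        for pid, prepped in zip(ids, prepped_list):
            res = batch_controllability(prepped, tolerance=config.tolerance)
            verdicts[pid] = res.globally_controllable
        write_json({"globally_controllable": verdicts},
                   out_dir / "global_controllability.json", chash)

    # ---- graph metrics ---------------------------------------------------
    if config.run_graph_metrics:
        long = metrics.cohort_metrics_long(prepped_list, ids)
        long = long[long["region"].isin(regions)]
        write_table(long, out_dir / "graph_metrics.csv", chash, index=False)

    # ---- stats -----------------------------------------------------------
    summary: dict = {"seed": config.seed, "n_participants": len(ids)}
    if synth_diag is not None:
        summary["synthetic_diagnostics"] = synth_diag
        summary["truth"] = SyntheticTruth(**config.synthetic).to_dict()

    t, df, p = stats.paired_t_test(
        table["chronological_age"].to_numpy(),
        table["predicted_brain_age"].to_numpy(),
    )
    summary["brain_age"] = {
        "mean_chronological_age": float(table["chronological_age"].mean()),
        "mean_predicted_brain_age": float(table["predicted_brain_age"].mean()),
        "mean_gap": float(table["brain_age_gap"].mean()),
        "paired_t": {"t": t, "df": df, "p": p},
    }

    cov = table[COVARIATE_COLUMNS]
    y = table["wab_aq"]
    base_controls = ["lesion_volume", "months_post_stroke", "education", "sex"]
    regressions = {}
    for name, cols in (
        ("chronological_age_model", ["chronological_age"] + base_controls),
        ("brain_age_model", ["predicted_brain_age"] + base_controls),
        ("gap_model", ["brain_age_gap", "chronological_age"] + base_controls),
    ):
        regressions[name] = stats.fit_ols(y, table[cols]).to_dict()
    summary["regressions"] = regressions

    pca_table = ctrl_wide.dropna(axis=0)
    if pca_table.shape[1] >= 3 and pca_table.shape[0] >= pca_table.shape[1] + 1:
        pca = stats.pca_varimax(pca_table)
        summary["pca"] = pca.to_dict()
    else:
        summary["pca"] = None

    mediators = config.mediators or [
        m for m in atlas.CANDIDATE_MEDIATORS if m in ctrl_wide.columns
    ]
    mediation = {}
    for mediator in mediators:
        res = stats.mediate(
            table["brain_age_gap"].to_numpy(),
            ctrl_wide[mediator].to_numpy(),
            y.to_numpy(),
            covariates=cov,
            n_boot=config.n_boot,
            ci=config.ci,
            seed=config.seed,
        )
        mediation[mediator] = res.to_dict()
    summary["mediation"] = mediation

    primary = mediators[0] if mediators else None
    if primary is not None:
        final = pd.DataFrame(
            {
                "lesion_volume": table["lesion_volume"],
                "chronological_age": table["chronological_age"],
                "brain_age_gap": table["brain_age_gap"],
                "mediator_controllability": ctrl_wide[primary].to_numpy(),
            }
        )
        keep = final.notna().all(axis=1)
        summary["lmg"] = stats.lmg(y[keep], final[keep]).to_dict()
        summary["lmg"]["mediator"] = primary

    write_json(summary, out_dir / "summary.json", chash)
    return summary
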