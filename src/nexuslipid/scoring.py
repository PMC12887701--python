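"""Gene-scoring cascade turning model metrics and importances into ranked
gene lists.

Scores:
    CMPS  composite model performance = mean of six 0-1 metrics
          (kappa mapped via (kappa+1)/2)
    PWIS  performance-weighted importance = raw importance x CMPS
    GPS   per-dataset sum of a gene's PWIS over (pathway, model) records
    DSS   per-dataset GPS x ln(1 + appearance frequency)
    HGS   all-dataset PWIS sum x ln(1 + total hits)

The logarithmic robustness factor uses ln(1 + hits) so a single-hit gene
keeps a non-zero factor (ln 2) and can still top a ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ml import METRICS, ModelMetrics

RECORD_COLUMNS = ["gene", "dataset", "pathway", "model",
                  "raw_importance", "cmps", "pwis"]


def composite_model_performance(metrics: ModelMetrics | dict,
                                kappa_minmax: bool = False,
                                kappa_bounds: tuple[float, float] | None = None
                                ) -> float:
    """Mean of the six metrics on a 0-1 scale.

    auc/accuracy/f1/precision/recall are used as-is; kappa is mapped by
    (kappa+1)/2 by default, or min-max rescaled over ``kappa_bounds`` when
    ``kappa_minmax`` is set.
    """
    d = metrics.as_dict() if isinstance(metrics, ModelMetrics) else dict(metrics)
    missing = [m for m in METRICS if m not in d or d[m] is None]
    if missing:
        raise ValueError(f"composite_model_performance: missing metric(s) {missing}")
    kappa = d["kappa"]
    if kappa_minmax:
        lo, hi = kappa_bounds if kappa_bounds else (-1.0, 1.0)
        kappa01 = 0.0 if hi == lo else (kappa - lo) / (hi - lo)
    else:
        kappa01 = (kappa + 1.0) / 2.0
    values = [d["auc"], d["accuracy"], d["f1"], d["precision"], d["recall"], kappa01]
    return float(np.mean(values))


def performance_weighted_importance(raw_importance: float, cmps: float) -> float:
    if raw_importance < 0 or cmps < 0:
        raise ValueError("raw importance and CMPS must be non-negative")
    return raw_importance * cmps


def build_score_records(evaluations) -> pd.DataFrame:
    """Flatten PathwayEvaluation objects into one PWIS record per
    (gene, dataset, pathway, model)."""
    rows = []
    for ev in evaluations:
        cmps_by_model = {m.model: composite_model_performance(m) for m in ev.metrics}
        for model_name, vector in ev.importances.items():
            cmps = cmps_by_model[model_name]
            for gene, raw in vector.importances.items():
                rows.append({
                    "gene": gene, "dataset": ev.dataset, "pathway": ev.pathway,
                    "model": model_name, "raw_importance": float(raw),
                    "cmps": cmps,
                    "pwis": performance_weighted_importance(float(raw), cmps),
                })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def gene_prioritization(records: pd.DataFrame,
                        top_frac: float = 0.01) -> pd.DataFrame:
    """Per-dataset GPS ranking with top-fraction retention.

    GPS(g) = sum of PWIS over all (pathway, model) records of g in the
    dataset.  ceil(top_frac * n_genes) genes (minimum 1) are retained per
    dataset; ties broken by hit count, then symbol.
    """
    out = []
    for dataset, sub in records.groupby("dataset"):
        agg = sub.groupby("gene").agg(
            gps=("pwis", "sum"), total_hits=("pwis", "size"))
        agg = agg.sort_values(["gps", "total_hits", "gene"],
                              ascending=[False, False, True],
                              kind="mergesort").reset_index()
        n_keep = max(1, math.ceil(top_frac * len(agg)))
        agg["rank"] = np.arange(1, len(agg) + 1)
        agg["retained"] = agg["rank"] <= n_keep
        agg.insert(0, "dataset", dataset)
        out.append(agg)
    if not out:
        return pd.DataFrame(columns=["dataset", "gene", "gps", "total_hits",
                                     "rank", "retained"])
    return pd.concat(out, ignore_index=True)


def retained_genes(prioritized: pd.DataFrame) -> dict[str, list[str]]:
    return {d: sub.loc[sub["retained"], "gene"].tolist()
            for d, sub in prioritized.groupby("dataset")}


def dataset_specific_score(records: pd.DataFrame) -> pd.DataFrame:
    """DSS(g) = (sum PWIS in the dataset) * ln(1 + appearance frequency)."""
    out = []
    for dataset, sub in records.groupby("dataset"):
        agg = sub.groupby("gene").agg(
            pwis_sum=("pwis", "sum"), freq=("pwis", "size")).reset_index()
        agg["dss"] = agg["pwis_sum"] * np.log1p(agg["freq"])
        agg = agg.sort_values(["dss", "freq", "gene"],
                              ascending=[False, False, True],
                              kind="mergesort").reset_index(drop=True)
        agg["rank"] = np.arange(1, len(agg) + 1)
        agg.insert(0, "dataset", dataset)
        out.append(agg)
    if not out:
        return pd.DataFrame(columns=["dataset", "gene", "pwis_sum", "freq",
                                     "dss", "rank"])
    return pd.concat(out, ignore_index=True)


def holistic_score(records: pd.DataFrame) -> pd.DataFrame:
    """HGS(g) = (sum PWIS across every dataset/pathway/model record)
    * ln(1 + Total_Hits)."""
    agg = records.groupby("gene").agg(
        pwis_sum=("pwis", "sum"), total_hits=("pwis", "size")).reset_index()
    agg["hgs"] = agg["pwis_sum"] * np.log1p(agg["total_hits"])
    agg = agg.sort_values(["hgs", "total_hits", "gene"],
                          ascending=[False, False, True],
                          kind="mergesort").reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg


def shared_pathway_score(per_dataset_scores: dict[str, float]) -> float:
    """Overall score of a pathway shared across datasets: the mean of its
    per-dataset composite gene-set scores (interpretation; no closed form
    is published for this quantity)."""
    if not per_dataset_scores:
        raise ValueError("shared_pathway_score: no per-dataset scores")
    return float(np.mean(list(per_dataset_scores.values())))
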