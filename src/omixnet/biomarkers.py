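"""Saliency-based biomarker ranking and marker-to-gene mapping.

Significant markers are found by backpropagating the model output to its
inputs: the gradient of the positive-class logit (pre-softmax) with respect
to every input entry, aggregated per feature as the mean over samples of the
channel-wise maximum absolute gradient. One-hot layers therefore collapse to
one score per feature, never per channel. Scores are converted to dense
ranks — rank 1 is the highest saliency, ties share a rank, ranks have no
gaps — and markers that are not genes (CpG islands, SNPs) can be mapped to
their annotated neighboring gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MultiOmicsDataset
from .io import MarkerAnnotation, ValidationError
from .multicnn import TrainedModel, input_gradients


@dataclass
class MarkerReport:
    """Per-feature saliency with dense ranks and optional gene mapping.

    ``table`` columns: feature, layer, saliency, dense_rank, gene.
    """

    table: pd.DataFrame
    model_ref: str
    n_samples_used: int
    aggregation: str = "mean_abs_channel_max"

    def __post_init__(self) -> None:
        required = {"feature", "layer", "saliency", "dense_rank"}
        if not required <= set(self.table.columns):
            raise ValidationError(f"marker table needs columns {sorted(required)}")

    def to_csv(self, path) -> None:
        cols = ["feature", "layer", "saliency", "dense_rank"]
        if "gene" in self.table.columns:
            cols.append("gene")
        self.table[cols].to_csv(path, index=False)


def saliency_map(model: TrainedModel, d: MultiOmicsDataset,
                 target: int | None = None) -> list[np.ndarray]:
    """Per-sample, per-feature, per-channel input gradients, one array per layer."""
    return input_gradients(model, d, target=target)


def aggregate_saliency(gradients: list[np.ndarray]) -> list[np.ndarray]:
    """Collapse gradients to one non-negative scalar per feature per layer.

    mean over samples of max over channels of |gradient|; invariant to
    sample order.
    """
    return [np.abs(g).max(axis=2).mean(axis=0) for g in gradients]


def dense_rank(saliency: dict[str, float] | pd.Series) -> dict[str, int]:
    """Dense ranks, descending by saliency: highest value gets rank 1,
    ties share a rank, no gaps."""
    s = pd.Series(saliency, dtype=float)
    if s.empty:
        raise ValidationError("cannot rank an empty saliency map")
    ranks = s.rank(method="dense", ascending=False).astype(int)
    return ranks.to_dict()


def marker_report(model: TrainedModel, d: MultiOmicsDataset,
                  target: int | None = None,
                  aggregation: str = "mean",
                  layer_scale: str = "median") -> MarkerReport:
    """Full saliency report over all layers of a dataset.

    ``aggregation`` selects how per-sample channel-max |gradients| collapse
    across samples: "mean" (default) or "max". ``layer_scale`` controls
    cross-layer calibration: raw gradient magnitudes are not comparable
    between branches with different encodings (a one-hot genotype branch
    systematically carries larger input gradients than a z-scored expression
    branch), so each layer's saliencies are divided by that layer's median
    ("median", default) before global ranking; "none" keeps raw magnitudes.
    A layer whose median is 0 is left unscaled.
    """
    if aggregation not in ("mean", "max"):
        raise ValidationError("aggregation must be 'mean' or 'max'")
    if layer_scale not in ("median", "none"):
        raise ValidationError("layer_scale must be 'median' or 'none'")
    grads = saliency_map(model, d, target=target)
    rows = []
    for lay, g in zip(d.layers, grads):
        per_sample = np.abs(g).max(axis=2)  # channel collapse
        sal = per_sample.mean(axis=0) if aggregation == "mean" else per_sample.max(axis=0)
        if layer_scale == "median":
            med = float(np.median(sal))
            if med > 0:
                sal = sal / med
        for feat, v in zip(lay.feature_ids, sal):
            rows.append({"feature": feat, "layer": lay.omics_type, "saliency": float(v)})
    table = pd.DataFrame(rows)
    rank_lut = pd.Series(table["saliency"].to_numpy()).rank(
        method="dense", ascending=False).astype(int)
    table["dense_rank"] = rank_lut.to_numpy()
    table = table.sort_values(["saliency", "feature"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    agg_name = f"{aggregation}_abs_channel_max/layer_{layer_scale}"
    return MarkerReport(table, model_ref=f"multicnn(seed={model.seed})",
                        n_samples_used=d.n_samples, aggregation=agg_name)


def report_from_importance(feature_scores: pd.DataFrame, model_ref: str,
                           n_samples: int) -> MarkerReport:
    """Build a MarkerReport from baseline (layer, feature, score) importances."""
    table = feature_scores.rename(columns={"score": "saliency"}).copy()
    table["dense_rank"] = pd.Series(table["saliency"].to_numpy()).rank(
        method="dense", ascending=False).astype(int).to_numpy()
    table = table.sort_values(["saliency", "feature"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    return MarkerReport(table[["feature", "layer", "saliency", "dense_rank"]],
                        model_ref=model_ref, n_samples_used=n_samples,
                        aggregation="model_importance")


def top_markers(report: MarkerReport, k: int | None = None,
                threshold: float | None = None) -> pd.DataFrame:
    """Top markers by saliency: either the top-k (boundary ties all included)
    or everything at or above a saliency threshold, sorted descending."""
    t = report.table
    if (k is None) == (threshold is None):
        raise ValidationError("give exactly one of k or threshold")
    if threshold is not None:
        return t[t["saliency"] >= threshold].reset_index(drop=True)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= len(t):
        if k > len(t):
            warnings.warn(f"k={k} exceeds the {len(t)} available features; "
                          "returning all", stacklevel=2)
        return t.reset_index(drop=True)
    cutoff = t["saliency"].iloc[k - 1]
    return t[t["saliency"] >= cutoff].reset_index(drop=True)


#: layers whose feature IDs are already gene identifiers
GENE_TYPED_LAYERS = frozenset({"gene_expression", "protein_expression"})


def map_markers_to_genes(markers: pd.DataFrame,
                         ann: MarkerAnnotation) -> tuple[pd.DataFrame, list[str]]:
    """Replace non-gene markers (CpGs, SNPs, CNV segments) by their annotated
    neighboring gene.

    Gene-typed markers pass through unchanged. When several markers map to
    one gene, the gene keeps the best (lowest) dense rank. Returns the mapped
    table plus the list of markers with no annotation.
    """
    mapped_rows, unmapped = [], []
    for _, row in markers.iterrows():
        if row["layer"] in GENE_TYPED_LAYERS:
            gene = row["feature"]
        else:
            gene = ann.gene_for(row["feature"])
            if gene is None:
                unmapped.append(row["feature"])
                continue
        mapped_rows.append({**row.to_dict(), "gene": gene})
    if not mapped_rows:
        return pd.DataFrame(columns=[*markers.columns, "gene"]), unmapped
    df = pd.DataFrame(mapped_rows)
    df = (df.sort_values(["dense_rank", "saliency"], ascending=[True, False],
                         kind="mergesort")
            .drop_duplicates(subset="gene", keep="first")
            .reset_index(drop=True))
    return df, unmapped
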