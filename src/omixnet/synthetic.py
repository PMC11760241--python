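"""Synthetic multi-omics cohorts with planted, ground-truth-known signal.

The generator emulates the statistical skeleton the predictive models
assume: a shared sample cohort measured on up to three layers, where most
features carry no class information and a small planted subset differs
between classes. Continuous (expression-like) features are i.i.d. standard
normal, with planted features mean-shifted by ``effect`` standard deviations
in the positive class. Categorical SNP/CNV features draw per-feature
category frequencies once from a Dirichlet; planted features mix a fraction
``0.15 * effect`` of the positive-class distribution onto a single randomly
chosen category. Missingness is applied uniformly at a configurable rate.
A JSON manifest records the planted feature IDs per layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MultiOmicsDataset, align_samples
from .encoding import encode_layer
from .io import CNV_STATES, OMICS_TYPES, LabelTable, OmicsMatrix, ValidationError

_PREFIX = {"gene_expression": "ge", "mirna_expression": "mir",
           "dna_methylation": "cg", "protein_expression": "pr",
           "snp": "snp", "cnv": "cnv"}


@dataclass
class LayerSpec:
    layer_type: str
    n_features: int
    n_planted: int = 0
    effect: float = 2.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.layer_type not in OMICS_TYPES:
            raise ValidationError(f"unknown layer type {self.layer_type!r}")
        if not 0 <= self.n_planted <= self.n_features:
            raise ValidationError("need 0 <= n_planted <= n_features")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing rate must be in [0, 1)")


@dataclass
class SyntheticSpec:
    n_samples: int
    layers: list[LayerSpec]
    class_balance: float = 0.5
    task: str = "categorical"
    seed: int = 0
    noise_sd: float = 1.0  # residual sd of quantitative labels

    def __post_init__(self) -> None:
        if not 1 <= len(self.layers) <= 3:
            raise ValidationError("need 1-3 layers")
        if not 0.0 < self.class_balance < 1.0:
            raise ValidationError("class balance must be in (0, 1)")
        if self.task not in ("categorical", "quantitative"):
            raise ValidationError(f"unknown task {self.task!r}")


@dataclass
class Manifest:
    spec: dict
    planted: dict[str, list[str]] = field(default_factory=dict)  # layer name -> IDs

    def all_planted(self) -> set[str]:
        return set().union(*self.planted.values()) if self.planted else set()

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"spec": self.spec, "planted": self.planted}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Manifest":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["spec"], d["planted"])


def _layer_name(i: int, lt: str) -> str:
    return f"layer{i}_{lt}"


def generate_tables(spec: SyntheticSpec
                    ) -> tuple[dict[str, OmicsMatrix], LabelTable, Manifest]:
    """Generate raw omics matrices, labels, and the planted-marker manifest."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"s{i:04d}" for i in range(n)]
    n_pos = int(round(n * spec.class_balance))
    is_pos = np.zeros(n, dtype=bool)
    is_pos[rng.choice(n, size=n_pos, replace=False)] = True

    manifest = Manifest(spec=asdict(spec))
    matrices: dict[str, OmicsMatrix] = {}
    planted_signal = np.zeros(n)  # accumulates continuous planted values for y_quant

    for li, lspec in enumerate(spec.layers):
        prefix = _PREFIX[lspec.layer_type]
        feats = [f"{prefix}{li}_f{j:04d}" for j in range(lspec.n_features)]
        planted_idx = np.sort(rng.choice(lspec.n_features, size=lspec.n_planted,
                                         replace=False))
        planted_ids = [feats[j] for j in planted_idx]

        if lspec.layer_type in ("snp", "cnv"):
            vocab = ("A", "T", "C", "G") if lspec.layer_type == "snp" else CNV_STATES
            w = 0.15 * lspec.effect
            if w > 0.95:
                raise ValidationError(
                    f"effect {lspec.effect} implies frequency shift {w:.2f} > 0.95")
            data = np.empty((n, lspec.n_features), dtype=object)
            planted_set = set(planted_idx.tolist())
            for j in range(lspec.n_features):
                base = rng.dirichlet(np.full(len(vocab), 5.0))
                if j in planted_set:
                    c = int(rng.integers(len(vocab)))
                    shifted = (1 - w) * base + w * np.eye(len(vocab))[c]
                else:
                    shifted = base
                neg_draw = rng.choice(len(vocab), size=n, p=base)
                pos_draw = rng.choice(len(vocab), size=n, p=shifted)
                col = np.where(is_pos, pos_draw, neg_draw)
                data[:, j] = np.asarray(vocab, dtype=object)[col]
            if lspec.missing_rate > 0:
                mask = rng.random((n, lspec.n_features)) < lspec.missing_rate
                if lspec.layer_type == "snp":
                    data[mask] = "missing"
                else:
                    # CNV layers carry no missing token; drop the mask instead
                    pass
            df = pd.DataFrame(data, index=sample_ids, columns=feats)
        else:
            x = rng.standard_normal((n, lspec.n_features))
            if lspec.n_planted:
                if spec.task == "categorical":
                    x[np.ix_(is_pos, planted_idx)] += lspec.effect
                else:
                    planted_signal += lspec.effect * x[:, planted_idx].mean(axis=1)
            if lspec.missing_rate > 0:
                mask = rng.random((n, lspec.n_features)) < lspec.missing_rate
                x[mask] = np.nan
            df = pd.DataFrame(x, index=sample_ids, columns=feats)

        name = _layer_name(li, lspec.layer_type)
        matrices[name] = OmicsMatrix(lspec.layer_type, df, source_tag="synthetic")
        manifest.planted[name] = planted_ids

    if spec.task == "categorical":
        labels = LabelTable(sample_ids, "categorical",
                            np.where(is_pos, "pos", "neg").astype(object))
    else:
        y = planted_signal + spec.noise_sd * rng.standard_normal(n)
        labels = LabelTable(sample_ids, "quantitative", y)
    return matrices, labels, manifest


def generate(spec: SyntheticSpec, outdir) -> dict[str, Path]:
    """Write per-layer CSVs, a labels CSV, and the manifest JSON to ``outdir``.

    Output is byte-identical for identical specs (same seed included).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, labels, manifest = generate_tables(spec)
    paths: dict[str, Path] = {}
    for name, m in matrices.items():
        p = outdir / f"{name}.csv"
        m.values.to_csv(p, index_label="sample_id", lineterminator="\n")
        paths[name] = p
    lp = outdir / "labels.csv"
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.values}
                 ).to_csv(lp, index=False, lineterminator="\n")
    paths["labels"] = lp
    mp = outdir / "manifest.json"
    manifest.to_json(mp)
    paths["manifest"] = mp
    return paths


def build_dataset(matrices: dict[str, OmicsMatrix], labels: LabelTable,
                  seed: int = 0) -> MultiOmicsDataset:
    """Encode every layer and align with the labels — the standard entry
    from raw tables into the modelling stages."""
    encoded = [encode_layer(m) for m in matrices.values()]
    return align_samples(encoded, labels, seed=seed)


def manifest_check(report, manifest: Manifest, k: int) -> dict[str, float]:
    """Recovery metrics of a marker report against the planted ground truth.

    precision@k = fraction of the top-k markers that are planted;
    recall@k = fraction of planted markers found in the top-k.
    """
    from .biomarkers import top_markers

    if k < 1:
        raise ValidationError("k must be >= 1")
    planted = manifest.all_planted()
    reported = set(report.table["feature"])
    if not planted & reported and planted:
        raise ValidationError("manifest and report share no feature IDs")
    top = top_markers(report, k=k)
    top_feats = set(top["feature"].head(k))  # ties beyond k do not inflate precision
    hits = len(top_feats & planted)
    return {"k": float(k), "precision_at_k": hits / min(k, len(top_feats)) if top_feats else 0.0,
            "recall_at_k": hits / len(planted) if planted else 0.0}
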