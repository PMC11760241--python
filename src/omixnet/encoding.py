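"""Per-omics encodings that turn raw layers into model-ready tensors.

Expression-like layers (gene/miRNA/protein expression, DNA methylation) are
z-scored within each sample (row) using the population standard deviation,
after which missing entries become 0 — i.e. the per-sample mean on the
normalized scale. SNP and CNV layers are one-hot encoded over fixed channel
orders and receive no imputation: a missing genotype is itself a channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    CNV_STATES,
    SNP_TOKENS,
    MarkerAnnotation,
    OmicsMatrix,
    ValidationError,
)


@dataclass
class EncodedLayer:
    """A numeric (samples x features x channels) tensor ready for a model branch."""

    omics_type: str
    sample_ids: list[str]
    feature_ids: list[str]
    tensor: np.ndarray
    channels: list[str]
    encoding_kind: str  # "zscored_continuous" | "onehot"

    def __post_init__(self) -> None:
        n, f, c = self.tensor.shape
        if n != len(self.sample_ids) or f != len(self.feature_ids) or c != len(self.channels):
            raise ValueError("tensor shape does not match ID/channel lists")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("encoded tensor contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_features(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[2]

    def subset(self, ids: list[str]) -> "EncodedLayer":
        lut = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lut[s] for s in ids]
        return EncodedLayer(self.omics_type, list(ids), self.feature_ids,
                            self.tensor[idx], self.channels, self.encoding_kind)


def zscore_per_sample(m: OmicsMatrix, axis: str = "sample") -> EncodedLayer:
    """Z-score an expression-like layer and zero-fill missing entries.

    Each row (sample) is transformed to ``(x - mean) / sd`` with mean and
    population sd (divisor n) computed over that row's *observed* entries;
    missing entries are then set to 0. Zero-variance rows map to all zeros.
    ``axis="feature"`` applies the same transform column-wise instead.

    Parameters
    ----------
    m : OmicsMatrix
        Expression-like layer (floats, NaN = missing).
    axis : {"sample", "feature"}
        Normalization axis; per-sample is the default behaviour.
    """
    if not m.is_expression_like():
        raise ValidationError(f"z-scoring applies to expression-like layers, not {m.omics_type}")
    if axis not in ("sample", "feature"):
        raise ValueError("axis must be 'sample' or 'feature'")
    x = m.values.to_numpy(dtype=float)
    ax = 1 if axis == "sample" else 0
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(x, axis=ax, keepdims=True)
        sd = np.nanstd(x, axis=ax, keepdims=True)  # population sd (ddof=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    z = np.where(np.isnan(x), 0.0, z)  # imputation after normalization
    return EncodedLayer(m.omics_type, m.sample_ids, m.feature_ids,
                        z[:, :, None], ["value"], "zscored_continuous")


def impute_expression_missing(m: OmicsMatrix) -> OmicsMatrix:
    """Replace missing entries of an expression-like layer by 0 (raw scale).

    The modelling path normally zero-fills *after* z-scoring (see
    :func:`zscore_per_sample`); this operation exposes the raw-scale variant
    for pipelines that skip normalization.
    """
    if not m.is_expression_like():
        raise ValidationError(f"imputation applies to expression-like layers, not {m.omics_type}")
    return OmicsMatrix(m.omics_type, m.values.fillna(0.0), source_tag=m.source_tag)


def _onehot(m: OmicsMatrix, vocab: tuple[str, ...]) -> EncodedLayer:
    tokens = m.values.to_numpy(dtype=object)
    n, f = tokens.shape
    tensor = np.zeros((n, f, len(vocab)), dtype=float)
    for c, tok in enumerate(vocab):
        tensor[:, :, c] = tokens == tok
    bad = tensor.sum(axis=2) != 1.0
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"token {tokens[i, j]!r} at sample {m.sample_ids[i]!r}, feature "
            f"{m.feature_ids[j]!r} outside vocabulary {list(vocab)}"
        )
    return EncodedLayer(m.omics_type, m.sample_ids, m.feature_ids,
                        tensor, list(vocab), "onehot")


def encode_snp(m: OmicsMatrix) -> EncodedLayer:
    """One-hot encode genotypes over channels (A, T, C, G, missing)."""
    if m.omics_type != "snp":
        raise ValidationError(f"encode_snp expects a snp layer, got {m.omics_type}")
    return _onehot(m, SNP_TOKENS)


def encode_cnv(m: OmicsMatrix) -> EncodedLayer:
    """One-hot encode copy-number states, channels ordered from homozygous
    deletion through high-level amplification."""
    if m.omics_type != "cnv":
        raise ValidationError(f"encode_cnv expects a cnv layer, got {m.omics_type}")
    return _onehot(m, CNV_STATES)


def filter_methylation(m: OmicsMatrix, ann: MarkerAnnotation) -> tuple[OmicsMatrix, int]:
    """Keep only CpG features present in the annotation (promoter/gene CpGs).

    Returns the filtered matrix and the number of dropped features.
    """
    if m.omics_type != "dna_methylation":
        raise ValidationError(f"CpG filtering applies to dna_methylation, not {m.omics_type}")
    keep = [f for f in m.feature_ids if f in ann.marker_ids()]
    dropped = m.n_features - len(keep)
    if not keep:
        raise ValidationError(
            "no methylation feature matches the annotation; check that marker IDs "
            "in the annotation file use the same CpG naming as the methylation table"
        )
    return OmicsMatrix(m.omics_type, m.values[keep], source_tag=m.source_tag), dropped


def encode_layer(m: OmicsMatrix, axis: str = "sample") -> EncodedLayer:
    """Dispatch to the type-appropriate encoding."""
    if m.is_expression_like():
        return zscore_per_sample(m, axis=axis)
    if m.omics_type == "snp":
        return encode_snp(m)
    return encode_cnv(m)
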