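"""Reading and validation of omics tables, label tables, gene sets, and marker annotations.

All tabular inputs are plain CSV/TSV. Omics CSVs are oriented samples-in-rows,
features-in-columns, with the first column holding sample IDs (a ``transpose``
flag tolerates the other orientation). Sample-ID matching throughout the
package is exact string equality — no case folding or whitespace stripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXPRESSION_TYPES = frozenset(
    {"gene_expression", "mirna_expression", "dna_methylation", "protein_expression"}
)
CATEGORICAL_TYPES = frozenset({"snp", "cnv"})
OMICS_TYPES = EXPRESSION_TYPES | CATEGORICAL_TYPES

#: Genotype vocabulary: the four nucleotides plus an explicit missing token.
SNP_TOKENS = ("A", "T", "C", "G", "missing")
#: Copy-number states, ordered from homozygous deletion to high-level amplification.
CNV_STATES = (
    "homozygous_deletion",
    "single_copy_deletion",
    "diploid_normal",
    "low_level_amplification",
    "high_level_amplification",
)
#: GISTIC-style integer aliases for the five copy-number states.
CNV_ALIASES = {"-2": CNV_STATES[0], "-1": CNV_STATES[1], "0": CNV_STATES[2],
               "1": CNV_STATES[3], "2": CNV_STATES[4]}

_MISSING_STRINGS = {"", "na", "nan"}
_SNP_MISSING = {"missing", "-"}


class ValidationError(ValueError):
    """Raised when an input file violates a structural or vocabulary constraint."""


@dataclass
class OmicsMatrix:
    """One omics layer: samples x features with a type tag.

    Expression-like layers store floats with NaN marking missing entries;
    snp/cnv layers store canonical string tokens (``SNP_TOKENS`` /
    ``CNV_STATES``).
    """

    omics_type: str
    values: pd.DataFrame
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.omics_type not in OMICS_TYPES:
            raise ValidationError(
                f"unknown omics type {self.omics_type!r}; expected one of {sorted(OMICS_TYPES)}"
            )
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "feature")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_expression_like(self) -> bool:
        return self.omics_type in EXPRESSION_TYPES

    def to_csv(self, path) -> None:
        """Write back in the same dialect :func:`read_omics_csv` reads."""
        self.values.to_csv(path, index_label="sample_id")


@dataclass
class LabelTable:
    """Phenotype labels for a sample cohort, categorical or quantitative."""

    sample_ids: list[str]
    task: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.task not in ("categorical", "quantitative"):
            raise ValidationError(f"task must be categorical or quantitative, got {self.task!r}")
        _check_unique(pd.Index(self.sample_ids), "sample")
        if len(self.sample_ids) != len(self.values):
            raise ValidationError("label count does not match sample count")
        # >=2 distinct classes is enforced at read time (read_labels); subsets
        # taken for prediction may legitimately hold a single class

    @property
    def classes(self) -> list[str]:
        if self.task != "categorical":
            raise ValueError("classes only defined for categorical labels")
        return sorted(set(map(str, self.values)))

    def subset(self, ids: list[str]) -> "LabelTable":
        lut = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lut[s] for s in ids]
        return LabelTable(list(ids), self.task, np.asarray(self.values)[idx])


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, member gene IDs)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class MarkerAnnotation:
    """Marker -> genomic interval and linked gene, 0-based half-open coordinates."""

    records: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def gene_for(self, marker: str) -> str | None:
        rec = self.records.get(marker)
        return rec[3] if rec is not None else None

    def marker_ids(self) -> set[str]:
        return set(self.records)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValidationError(f"duplicate {what} ID {dup!r}")


def _canon_token(raw: object, omics_type: str, row: str, col: str) -> str:
    tok = str(raw).strip()
    if omics_type == "snp":
        if tok.lower() in _SNP_MISSING or tok.lower() in _MISSING_STRINGS:
            return "missing"
        up = tok.upper()
        if up in SNP_TOKENS[:4]:
            return up
        raise ValidationError(
            f"invalid SNP token {tok!r} at sample {row!r}, feature {col!r}; "
            f"allowed genotypes are A/T/C/G or missing"
        )
    # cnv
    low = tok.lower().replace(" ", "_").replace("-", "_") if not _is_int_like(tok) else tok
    if tok in CNV_ALIASES:
        return CNV_ALIASES[tok]
    if low in CNV_STATES:
        return low
    if tok.lower() in _MISSING_STRINGS:
        raise ValidationError(
            f"missing CNV state at sample {row!r}, feature {col!r}: copy-number layers "
            "carry no imputation; provide one of the five states"
        )
    raise ValidationError(
        f"invalid CNV state {tok!r} at sample {row!r}, feature {col!r}; "
        f"allowed states are {list(CNV_STATES)} or aliases -2..2"
    )


def _is_int_like(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def read_omics_csv(path, omics_type: str, source_tag: str = "",
                   transpose: bool = False) -> OmicsMatrix:
    """Read one omics layer from CSV.

    First column = sample IDs, header row = feature IDs (swapped when
    ``transpose``). Expression-like layers accept numeric entries with
    empty/"NA" as missing; snp layers accept A/T/C/G plus "missing"/"-";
    cnv layers accept the five named states or integer aliases -2..2.
    """
    if omics_type not in OMICS_TYPES:
        raise ValidationError(f"unknown omics type {omics_type!r}")
    raw = pd.read_csv(path, dtype=str, index_col=0, keep_default_na=False)
    if transpose:
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    _check_unique(raw.index, "sample")
    _check_unique(raw.columns, "feature")
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValidationError(f"{path}: empty omics table")

    if omics_type in EXPRESSION_TYPES:
        def to_num(v: str, row: str, col: str) -> float:
            if v.strip().lower() in _MISSING_STRINGS:
                return np.nan
            try:
                return float(v)
            except ValueError:
                raise ValidationError(
                    f"non-numeric entry {v!r} at sample {row!r}, feature {col!r} "
                    f"in {omics_type} layer"
                ) from None

        data = np.empty(raw.shape, dtype=float)
        for i, row in enumerate(raw.index):
            for j, col in enumerate(raw.columns):
                data[i, j] = to_num(raw.iat[i, j], row, col)
        df = pd.DataFrame(data, index=raw.index, columns=raw.columns)
    else:
        data = np.empty(raw.shape, dtype=object)
        for i, row in enumerate(raw.index):
            for j, col in enumerate(raw.columns):
                data[i, j] = _canon_token(raw.iat[i, j], omics_type, row, col)
        df = pd.DataFrame(data, index=raw.index, columns=raw.columns)
    return OmicsMatrix(omics_type, df, source_tag=source_tag)


def read_labels(path, task: str) -> LabelTable:
    """Read a two-column (sample ID, label) CSV into a :class:`LabelTable`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: label file needs two columns (sample ID, label)")
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: empty label file")
    ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).tolist()
    for i, v in enumerate(raw):
        if v.strip().lower() in _MISSING_STRINGS:
            raise ValidationError(f"{path}: missing label for sample {ids[i]!r} (row {i + 2})")
    if task == "quantitative":
        vals = np.empty(len(raw), dtype=float)
        for i, v in enumerate(raw):
            try:
                vals[i] = float(v)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric quantitative label {v!r} for sample "
                    f"{ids[i]!r} (row {i + 2})"
                ) from None
    else:
        vals = np.asarray(raw, dtype=object)
        if len(set(raw)) < 2:
            raise ValidationError(f"{path}: categorical task needs at least 2 distinct labels")
    return LabelTable(ids, task, vals)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: tab-separated lines of name, description, members..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(parts)} fields, need >=3"
                )
            name, desc, *members = parts
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            uniq = frozenset(m for m in members if m.strip())
            if not uniq:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, uniq)
    if not sets:
        raise ValidationError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def read_marker_annotation(path) -> MarkerAnnotation:
    """Read a BED-like 5-column TSV: marker, chrom, start, end, gene.

    Coordinates are 0-based half-open. An empty file yields an empty
    annotation (mapping later simply reports all markers as unmapped).
    """
    records: dict[str, tuple[str, int, int, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValidationError(
                    f"{path}:{lineno}: annotation line has {len(parts)} fields, need 5 "
                    "(marker, chrom, start, end, gene)"
                )
            marker, chrom, start_s, end_s, gene = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end} (0-based half-open)"
                )
            if marker in records:
                raise ValidationError(f"{path}:{lineno}: duplicate marker ID {marker!r}")
            records[marker] = (chrom, start, end, gene)
    return MarkerAnnotation(records)
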