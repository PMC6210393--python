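"""Omics layers: the genes x samples matrices the whole pipeline consumes.

Every molecular data type (mRNA expression, copy number, DNA methylation,
somatic mutation scores) is carried as one :class:`OmicsLayer` — a dense
numeric matrix with gene rows and sample columns plus a layer tag.  Layers
are z-scored before any statistic is computed, so downstream code only ever
sees continuous, standardized values regardless of the original data type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

#: Canonical layer tags, in fixed priority order (used for tie-breaking).
LAYER_TAGS = ("mRNA", "CNV", "methylation", "SNP")

GOOD = "good"
POOR = "poor"


@dataclass
class OmicsLayer:
    """One genes x samples matrix for a single omics data type.

    Parameters
    ----------
    layer_tag : str
        One of :data:`LAYER_TAGS`.
    matrix : ndarray of shape (n_genes, n_samples)
    gene_ids, sample_ids : list of str
        Row / column identifiers, in matrix order.
    """

    layer_tag: str
    matrix: np.ndarray
    gene_ids: list[str] = field(repr=False)
    sample_ids: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.layer_tag not in LAYER_TAGS:
            raise DataError(f"unknown layer tag {self.layer_tag!r}")
        if self.matrix.ndim != 2:
            raise DataError("omics matrix must be 2-D (genes x samples)")
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError(f"duplicate gene ids in layer {self.layer_tag}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, layer_tag: str) -> "OmicsLayer":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            layer_tag=layer_tag,
            matrix=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
        )


def drop_missing_genes(layer: OmicsLayer, policy: str = "drop") -> OmicsLayer:
    """Handle genes with missing values in a layer.

    ``policy="drop"`` removes any gene row containing a NaN (per-layer gene
    sets may therefore differ, as with real multi-omics cohorts);
    ``policy="mean"`` imputes NaNs with the gene's mean over observed samples.
    """
    m = layer.matrix
    bad = ~np.isfinite(m)
    if not bad.any():
        return layer
    if policy == "drop":
        keep = ~bad.any(axis=1)
        return replace(
            layer,
            matrix=m[keep],
            gene_ids=[g for g, k in zip(layer.gene_ids, keep) if k],
        )
    if policy == "mean":
        filled = m.copy()
        for i in np.where(bad.any(axis=1))[0]:
            row = filled[i]
            obs = np.isfinite(row)
            if not obs.any():
                raise DataError(f"gene {layer.gene_ids[i]} has no observed values")
            row[~obs] = row[obs].mean()
        return replace(layer, matrix=filled)
    raise DataError(f"unknown missing-value policy {policy!r}")


def zscore_normalize(layer: OmicsLayer, axis: str = "gene", ddof: int = 0) -> OmicsLayer:
    """Standardize a layer to mean 0, sd 1.

    The default axis is ``"gene"`` (standardize each gene across samples),
    which puts all genes on a common scale so between-group t statistics are
    comparable across genes; ``axis="sample"`` standardizes each sample
    profile instead.  The default sd uses the population convention
    (``ddof=0``).  Constant rows/columns map to all zeros.
    """
    if layer.matrix.size == 0:
        raise DataError("cannot normalize an empty matrix")
    if axis not in ("gene", "sample"):
        raise DataError(f"normalize axis must be 'gene' or 'sample', got {axis!r}")
    ax = 1 if axis == "gene" else 0
    if layer.matrix.shape[ax] < 2:
        raise DataError("need at least 2 values along the normalization axis")
    m = layer.matrix
    mean = m.mean(axis=ax, keepdims=True)
    sd = m.std(axis=ax, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m - mean) / sd
    z[~np.isfinite(z)] = 0.0  # constant rows/columns -> 0
    return replace(layer, matrix=z)


# ------------------------------------------------------------------ clinical


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (sample_id plus label and/or survival columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError("clinical file must have a 'sample_id' column")
    return df.set_index("sample_id")


def labels_for_samples(clinical: pd.DataFrame, sample_ids: list[str]) -> np.ndarray:
    """Extract good/poor labels aligned to ``sample_ids``."""
    if "label" not in clinical.columns:
        raise DataError("clinical file must contain a 'label' column")
    missing = [s for s in sample_ids if s not in clinical.index]
    if missing:
        raise DataError(f"samples missing from clinical file: {missing[:5]}...")
    labels = clinical.loc[sample_ids, "label"].to_numpy(dtype=object)
    bad = set(labels) - {GOOD, POOR}
    if bad:
        raise DataError(f"labels must be '{GOOD}'/'{POOR}', got {sorted(bad)}")
    return labels.astype(str)
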