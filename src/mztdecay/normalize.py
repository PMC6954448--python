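"""ERCC-anchored normalization of stage-resolved expression matrices.

Bulk/low-input RNA-seq of oocytes and early embryos measures expression as
FPKM, which is *relative* to the sequenced library. Because the maternal
transcriptome shrinks dramatically across the maternal-to-zygotic transition,
relative units distort absolute mRNA dynamics. ERCC spike-ins are added at
constant mass per sample, so the percentage of ERCC reads in a library tracks
the (inverse of the) biological RNA content, and scaling each sample by

    factor_s = ercc_pct(reference) / ercc_pct(s)

restores a common absolute scale anchored at a reference sample (the wild-type
zygote by convention). Downstream, lowly expressed genes are filtered and
floored at FPKM = 1 and expression is log2(x + 1) transformed.

The canonical order is ``ercc_normalize`` (or ``batch_anchor``) →
``filter_and_floor`` → ``log_transform``; each step records a transform tag so
the order actually applied is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("GV", "MII", "zygote", "two-cell", "four-cell")
CONDITIONS = ("WT", "alpha-amanitin", "Yap1-mKO", "siTut4/7", "control")

#: Default prefix identifying ERCC spike-in rows in an expression matrix.
DEFAULT_SPIKEIN_PREFIX = "ERCC-"

STAGE_ORDER = {stage: i for i, stage in enumerate(STAGES)}

REQUIRED_META_COLUMNS = ("stage", "condition", "batch", "replicate")


@dataclass
class ExpressionMatrix:
    """A gene × sample matrix of non-negative expression values (FPKM).

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
        ERCC spike-in rows are identified by ``spikein_prefix``.
    sample_meta
        DataFrame indexed by sample identifier with columns ``stage``,
        ``condition``, ``batch``, ``replicate`` and optionally ``ercc_pct``
        (percentage of ERCC reads in total reads, in (0, 100)).
    spikein_prefix
        Gene-identifier prefix marking spike-in control rows.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        for col in REQUIRED_META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample sheet lacks required column {col!r}")
        # keep metadata aligned to matrix column order
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def spikein_mask(self) -> pd.Series:
        return pd.Series(
            self.values.index.str.startswith(self.spikein_prefix),
            index=self.values.index,
        )

    def ercc_pct(self) -> pd.Series:
        """Per-sample ERCC percentage.

        Uses the ``ercc_pct`` column of the sample sheet when present
        (read-derived in a real experiment). Falls back to computing it from
        the matrix itself as 100 × spike-in mass / total mass — an
        approximation valid only when library distortion has not altered the
        spike-in share.
        """
        if "ercc_pct" in self.sample_meta.columns and self.sample_meta["ercc_pct"].notna().all():
            pct = self.sample_meta["ercc_pct"].astype(float)
        else:
            spike = self.values.loc[self.spikein_mask.to_numpy()]
            total = self.values.sum(axis=0)
            if (total <= 0).any():
                raise ValueError("cannot derive ERCC percentage for an all-zero sample")
            pct = 100.0 * spike.sum(axis=0) / total
        if (pct <= 0).any():
            raise ValueError("ERCC percentages must be positive")
        return pct

    def drop_spikeins(self) -> "ExpressionMatrix":
        keep = ~self.spikein_mask.to_numpy()
        return replace(self, values=self.values.loc[keep])


@dataclass
class NormalizedMatrix(ExpressionMatrix):
    """An :class:`ExpressionMatrix` plus per-sample factors and transform tags."""

    factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    transforms: tuple[str, ...] = ()
    removed_genes: tuple[str, ...] = ()


def _as_normalized(matrix: ExpressionMatrix, values: pd.DataFrame, tag: str,
                   factors: pd.Series | None = None,
                   removed: tuple[str, ...] = ()) -> NormalizedMatrix:
    prev_factors = getattr(matrix, "factors", None)
    prev_transforms = getattr(matrix, "transforms", ())
    prev_removed = getattr(matrix, "removed_genes", ())
    if factors is None:
        factors = prev_factors if prev_factors is not None else pd.Series(
            1.0, index=values.columns)
    return NormalizedMatrix(
        values=values,
        sample_meta=matrix.sample_meta,
        spikein_prefix=matrix.spikein_prefix,
        factors=factors.loc[list(values.columns)],
        transforms=tuple(prev_transforms) + (tag,),
        removed_genes=tuple(prev_removed) + tuple(removed),
    )


def default_reference_sample(matrix: ExpressionMatrix, stage: str = "zygote",
                             condition: str = "WT") -> str:
    """The wild-type zygote sample (first replicate) used as the ERCC anchor."""
    meta = matrix.sample_meta
    hits = meta[(meta["stage"] == stage) & (meta["condition"] == condition)]
    if hits.empty:
        hits = meta[meta["stage"] == stage]
    if hits.empty:
        raise ValueError(f"no sample at reference stage {stage!r}")
    return hits.sort_values("replicate").index[0]


def ercc_normalize(matrix: ExpressionMatrix,
                   reference_sample: str | None = None) -> NormalizedMatrix:
    """Scale every sample by its ERCC factor relative to a reference sample.

    ``factor_s = ercc_pct(reference) / ercc_pct(s)``; the reference sample's
    factor is exactly 1. All rows, spike-ins included, are scaled.
    """
    if reference_sample is None:
        reference_sample = default_reference_sample(matrix)
    if reference_sample not in matrix.values.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    pct = matrix.ercc_pct()
    factors = pct.loc[reference_sample] / pct
    values = matrix.values.mul(factors, axis=1)
    return _as_normalized(matrix, values, "ercc", factors=factors)


def batch_anchor(matrix: ExpressionMatrix,
                 batch_reference_stage: str = "zygote",
                 reference_condition: str = "WT") -> NormalizedMatrix:
    """ERCC-normalize each batch against its own reference-stage sample.

    Samples prepared in different batches are anchored to the zygote sample
    of their batch; the shared reference stage makes batches comparable.
    """
    meta = matrix.sample_meta
    pct = matrix.ercc_pct()
    factors = pd.Series(index=matrix.values.columns, dtype=float)
    for batch, batch_meta in meta.groupby("batch", sort=False):
        hits = batch_meta[(batch_meta["stage"] == batch_reference_stage)
                          & (batch_meta["condition"] == reference_condition)]
        if hits.empty:
            hits = batch_meta[batch_meta["stage"] == batch_reference_stage]
        if hits.empty:
            raise ValueError(
                f"batch {batch!r} lacks a {batch_reference_stage!r} sample")
        ref = hits.sort_values("replicate").index[0]
        batch_samples = batch_meta.index
        factors.loc[batch_samples] = pct.loc[ref] / pct.loc[batch_samples]
    values = matrix.values.mul(factors, axis=1)
    return _as_normalized(matrix, values, "ercc", factors=factors)


def filter_and_floor(matrix: ExpressionMatrix, floor: float = 1.0) -> NormalizedMatrix:
    """Drop genes below ``floor`` in every sample; floor surviving low values.

    Genes whose expression never reaches ``floor`` in any sample are removed;
    for the remaining genes every value below ``floor`` is set to ``floor``.
    Spike-in rows are controls, not maternal transcripts: they are exempt from
    both removal and flooring.
    """
    spike = matrix.spikein_mask.to_numpy()
    gene_max = matrix.values.max(axis=1)
    drop = (gene_max < floor).to_numpy() & ~spike
    removed = tuple(matrix.values.index[drop])
    values = matrix.values.loc[~drop].copy()
    kept_spike = values.index.str.startswith(matrix.spikein_prefix)
    floored = values.where(values >= floor, floor)
    values.loc[~kept_spike] = floored.loc[~kept_spike]
    return _as_normalized(matrix, values, "floor", removed=removed)


def log_transform(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """log2(x + 1) transform onto the expression scale used by the cluster rules."""
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("log transform requires non-negative values")
    values = np.log2(matrix.values + 1.0)
    return _as_normalized(matrix, values, "log2p1")
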