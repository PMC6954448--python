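"""RT-qPCR relative quantification and spike-in-normalized polysome profiles.

Relative expression follows the ΔΔCt model with perfect doubling per cycle:
replicate Ct values are averaged per assay, the level of a target is
2^−(Ct_target − Ct_reference), and fold-changes are expressed against the
mean level of the control group.

3′-oligouridylation is quantified by comparing two reverse-transcription
chemistries on the same sample: oligo(dA)-primed RT selectively templates on
oligo(U)-tailed mRNAs (normalized to an exogenous Gfp control), whereas
random-hexamer RT measures total mRNA (normalized to endogenous Gapdh). The
ratio of the two normalized levels tracks the uridylated fraction of a
transcript.

Polysome-bound expression matrices are made comparable across fractions by an
in-vitro-transcribed mCherry spike-in added equally to each sample: dividing
each sample by its spike-in value cancels per-sample capture efficiency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

CT_COLUMNS = ("sample", "condition", "gene", "primer_mode",
              "reference_gene", "replicate", "ct")

PRIMER_MODES = ("random", "oligo_dA")

#: Default reference gene per primer mode: endogenous Gapdh for total mRNA,
#: exogenous Gfp for the uridylation-enriched (oligo-dA-primed) assay.
MODE_REFERENCES = {"random": "Gapdh", "oligo_dA": "Gfp"}


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Load a replicate Ct table; validates columns, modes and Ct positivity."""
    table = pd.read_csv(path)
    return validate_ct_table(table)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    bad_modes = set(table["primer_mode"]) - set(PRIMER_MODES)
    if bad_modes:
        raise ValueError(f"unknown primer modes: {sorted(bad_modes)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


def _mean_ct(table: pd.DataFrame, sample: str, gene: str,
             primer_mode: str) -> float:
    rows = table[(table["sample"] == sample) & (table["gene"] == gene)
                 & (table["primer_mode"] == primer_mode)]
    if rows.empty:
        raise ValueError(
            f"no Ct for gene {gene!r} in sample {sample!r} ({primer_mode})")
    return float(rows["ct"].mean())


def relative_level(table: pd.DataFrame, gene: str, sample: str,
                   primer_mode: str = "random",
                   reference_gene: str | None = None) -> float:
    """Reference-normalized level 2^−ΔCt for one gene in one sample.

    Replicate Cts are averaged before ΔCt (the default aggregation); the
    reference gene defaults to the mode's paired control.
    """
    if reference_gene is None:
        reference_gene = MODE_REFERENCES[primer_mode]
    ct_target = _mean_ct(table, sample, gene, primer_mode)
    ct_ref = _mean_ct(table, sample, reference_gene, primer_mode)
    return float(2.0 ** -(ct_target - ct_ref))


def relative_levels(table: pd.DataFrame, primer_mode: str = "random",
                    reference_gene: str | None = None,
                    control_condition: str | None = None) -> pd.DataFrame:
    """Per-(gene, sample) relative levels, optionally as fold vs control.

    When ``control_condition`` is given, each gene's levels are divided by
    the mean level of that gene across control-condition samples, so the
    control group's mean fold is exactly 1.
    """
    if reference_gene is None:
        reference_gene = MODE_REFERENCES[primer_mode]
    sub = table[table["primer_mode"] == primer_mode]
    mean_ct = (sub.groupby(["sample", "gene"], sort=False)["ct"]
               .mean().unstack("gene"))
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    levels = 2.0 ** -(mean_ct.sub(mean_ct[reference_gene], axis=0))
    out = levels.stack().rename("level").reset_index()
    meta = sub[["sample", "condition"]].drop_duplicates("sample")
    out = out.merge(meta, on="sample", how="left")
    if control_condition is not None:
        control = (out[out["condition"] == control_condition]
                   .groupby("gene")["level"].mean())
        out["fold_vs_control"] = out["level"] / out["gene"].map(control)
    return out


def uridylation_ratio(table: pd.DataFrame, gene: str, sample: str) -> float:
    """3′-oligouridylation index: oligo(dA)-primed over random-primed level.

    Each primer mode is normalized to its own paired reference (Gfp for
    oligo-dA, Gapdh for random priming) before taking the ratio.
    """
    urid = relative_level(table, gene, sample, "oligo_dA")
    total = relative_level(table, gene, sample, "random")
    return urid / total


def polysome_normalize(values: pd.DataFrame,
                       spikein_gene: str = "mCherry") -> pd.DataFrame:
    """Divide each sample by its spike-in value; the spike-in row becomes 1.

    Idempotent: renormalizing an already-normalized matrix is a no-op.
    """
    if spikein_gene not in values.index:
        raise ValueError(f"spike-in row {spikein_gene!r} absent from matrix")
    spike = values.loc[spikein_gene]
    if (spike <= 0).any():
        raise ValueError("spike-in values must be positive in every sample")
    return values.div(spike, axis=1)
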