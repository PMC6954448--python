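"""Readers, writers and the end-to-end pipeline runner.

Standard plain-text formats throughout: TSV expression matrices (genes as
rows, header row of sample IDs), a sample sheet TSV (sample, stage,
condition, batch, replicate, optionally ercc_pct), FASTA for 3′-UTRs, BED
(6-column, 0-based half-open) for UTR intervals, CSV Ct tables, and
one-identifier-per-line gene lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import classify, quant, setstats, utr as utr_mod
from .normalize import (ExpressionMatrix, batch_anchor, ercc_normalize,
                        filter_and_floor, DEFAULT_SPIKEIN_PREFIX)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_ercc_pct(path: str | Path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")


def read_expression_matrix(matrix_path: str | Path,
                           sheet_path: str | Path,
                           ercc_pct_path: str | Path | None = None,
                           spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
                           ) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from its on-disk pieces."""
    values = read_matrix_tsv(matrix_path)
    meta = read_sample_sheet(sheet_path)
    if ercc_pct_path is not None:
        meta = meta.assign(ercc_pct=read_ercc_pct(ercc_pct_path))
    return ExpressionMatrix(values=values, sample_meta=meta,
                            spikein_prefix=spikein_prefix)


@dataclass
class RunConfig:
    """Configuration of an end-to-end analysis run."""

    matrix: str
    sample_sheet: str
    output_dir: str
    ercc_pct: str | None = None
    utr_fasta: str | None = None
    utr_bed: str | None = None
    ct_table: str | None = None
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX
    reference_stage: str = "zygote"
    reference_condition: str = "WT"
    maternal_fpkm_cutoff: float = 2.0
    seed: int = 0
    thresholds: dict = field(default_factory=lambda: {
        "zdecay_ratio": 0.5,
        "tut47_fold": 2.0,
        "tut47_decay_ratio": 1.0 / 3.0,
        "late_decay_ratio": 0.5,
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        for name in ("matrix", "sample_sheet", "ercc_pct", "utr_fasta",
                     "utr_bed", "ct_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValueError("all thresholds must be positive")
        if self.maternal_fpkm_cutoff <= 0:
            raise ValueError("maternal_fpkm_cutoff must be positive")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute normalize → classify → overlap (→ UTR → qPCR) end to end.

    Writes the per-gene annotation TSV, an overlap report TSV, optional UTR
    and qPCR summaries, and a manifest recording thresholds, transform order
    and the seed. Returns the written paths.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    matrix = _stage("load", lambda: read_expression_matrix(
        config.matrix, config.sample_sheet, config.ercc_pct,
        config.spikein_prefix))
    normalized = _stage("normalize", lambda: filter_and_floor(batch_anchor(
        matrix, config.reference_stage, config.reference_condition)))

    annotation = _stage("classify", lambda: classify.annotate(normalized))
    outputs["annotation"] = outdir / "annotation.tsv"
    annotation.to_csv(outputs["annotation"], sep="\t")

    def _overlaps():
        maternal = frozenset(annotation.index[annotation["maternal"]])
        rows = []
        named = {}
        for flag in ("z_decay", "zga_dependent", "yap1_dependent",
                     "tut47_dependent"):
            col = annotation[flag]
            if col.isna().any():
                continue
            named[flag] = setstats.GeneSet(
                flag, frozenset(annotation.index[col.fillna(False)]),
                universe=maternal)
        for name_a in named:
            for name_b in named:
                if name_a < name_b:
                    res = setstats.venn(named[name_a], named[name_b])
                    rows.append({"set_a": name_a, "set_b": name_b,
                                 **res.as_dict()})
        return pd.DataFrame(rows)

    overlaps = _stage("setstats", _overlaps)
    outputs["overlaps"] = outdir / "overlaps.tsv"
    overlaps.to_csv(outputs["overlaps"], sep="\t", index=False)

    if config.utr_fasta is not None:
        def _utr():
            records = utr_mod.load_utrs(config.utr_fasta, config.utr_bed)
            table = utr_mod.utr_table(records)
            cluster = annotation["cluster"]
            z_genes = [g for g in table.index
                       if cluster.get(g) == "II"]
            m_genes = [g for g in table.index
                       if cluster.get(g) == "I"]
            out = {"table": table}
            if z_genes and m_genes:
                out["compare"] = utr_mod.compare_utr_features(
                    m_genes, z_genes, table, "m_decay", "z_decay")
            return out

        utr_out = _stage("utr", _utr)
        outputs["utr_table"] = outdir / "utr_table.tsv"
        utr_out["table"].to_csv(outputs["utr_table"], sep="\t")
        if "compare" in utr_out:
            outputs["utr_compare"] = outdir / "utr_compare.tsv"
            utr_out["compare"].to_csv(outputs["utr_compare"], sep="\t")

    if config.ct_table is not None:
        def _qpcr():
            ct = quant.read_ct_csv(config.ct_table)
            return quant.relative_levels(ct)

        levels = _stage("qpcr", _qpcr)
        outputs["qpcr_levels"] = outdir / "qpcr_levels.tsv"
        levels.to_csv(outputs["qpcr_levels"], sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "transforms": list(normalized.transforms),
        "n_genes_input": int(len(matrix.genes)),
        "n_genes_removed": len(normalized.removed_genes),
        "n_maternal": int(annotation["maternal"].sum()),
        "cluster_sizes": {k: int(v) for k, v in
                          annotation["cluster"].value_counts().items()},
    }
    outputs["manifest"] = outdir / "manifest.json"
    with open(outputs["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outputs
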