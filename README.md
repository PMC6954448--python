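# mztdecay

Analysis toolkit for maternal mRNA clearance across the mouse
maternal-to-zygotic transition (MZT).

During the MZT, maternally deposited transcripts are removed by two
pathways: **M-decay**, driven entirely by maternal factors during oocyte
maturation, and **Z-decay**, which requires zygotic genome activation (ZGA)
and clears transcripts after fertilization, at the two- to four-cell stage.
`mztdecay` implements the computational side of characterizing these
pathways from stage-resolved expression data:

* **ERCC-anchored normalization** — spike-ins added at constant mass per
  sample anchor FPKM values to an absolute scale:
  `factor_s = ERCC%(reference) / ERCC%(s)`, with the wild-type zygote as
  reference and per-batch anchoring; genes with FPKM < 1 everywhere are
  removed, surviving values < 1 are floored to 1.
* **Decay-cluster classification** — maternal transcripts (FPKM > 2 at the
  germinal-vesicle stage) are assigned by strict inequalities on mean
  E = log2(FPKM + 1), where one unit is a two-fold change:
  cluster I (M-decay): `E_GV > E_zyg + 1` and `E_zyg < E_2C + 1`;
  cluster II (Z-decay): `|E_GV − E_zyg| < 1` and `E_zyg > E_2C + 1`;
  cluster III (continuous): `E_GV > E_zyg + 1` and `E_zyg > E_2C + 1`;
  cluster IV (stable): `|E_GV − E_zyg| < 1` and `|E_zyg − E_2C| < 1`.
  Boundary profiles are reported as unclassified, never force-assigned.
* **Pathway attribution** — FPKM-ratio criteria identify Z-decay
  transcripts (stable through fertilization, > 2-fold drop after ZGA) and
  their dependence on ZGA (stabilized by α-amanitin), maternal YAP1
  (accumulated in embryos from *Yap1*-null oocytes) and zygotic TUT4/7
  (upregulated after *Tut4/7* knockdown).
* **Set statistics** — exact Venn overlaps with the truncation-to-two-decimals
  percentage convention, hypergeometric enrichment in log10 space (deep
  tails like 1e−548 stay representable), Spearman replicate correlation,
  and the two-tailed unpaired Student's t-test.
* **3′-UTR cis-element analysis** — CPE (UUUUAU/UUUUAAU) and PAS
  (AAUAAA/AUUAAA) counting with overlapping matches, UTR-length summaries
  and greedy length-matched control sets.
* **RT-qPCR quantification** — ΔΔCt relative levels, oligo(dA)- vs
  random-primed 3′-oligouridylation ratios, and mCherry-spike-in
  normalization of polysome-bound profiles.
* **Synthetic data** — a seeded generator plants five transcript archetypes
  (M-decay, ZGA-dependent and -independent Z-decay, continuous, stable)
  with known stage profiles, library distortion, ERCC percentages, UTR
  motif counts and Ct tables, so the whole pipeline is testable end to end
  against ground truth.

## Worked example

```python
import mztdecay as m
from mztdecay.classify import cluster_report

config = m.SimConfig(genes_per_archetype=100, replicates=3, seed=42)
matrix, truth = m.generate_expression(config)
normalized = m.filter_and_floor(m.ercc_normalize(matrix))
annotation = m.annotate(normalized)

report = cluster_report(annotation["cluster"])
print("cluster sizes:", report["sizes"])
print("analyzed:", report["analyzed"], "unclassified:", report["unclassified"])

maternal = frozenset(annotation.index[annotation["maternal"]])
z = m.GeneSet("z_decay",
              frozenset(annotation.index[annotation["z_decay"].fillna(False)]),
              universe=maternal)
dep = m.GeneSet("zga_dependent",
                frozenset(annotation.index[annotation["zga_dependent"].fillna(False)]))
result = m.venn(z, dep)
print(f"Z-decay: {result.size_a}, ZGA-dependent: {result.size_b}, "
      f"overlap {result.overlap} ({result.pct_of_a}%), log10 p = {result.log10_p:.1f}")
```

prints

```
cluster sizes: {'I': 100, 'II': 200, 'III': 100, 'IV': 100}
analyzed: 500 unclassified: 0
Z-decay: 200, ZGA-dependent: 100, overlap 100 (50.0%), log10 p = -48.4
```

The 500 simulated maternal transcripts land in their planted clusters (both
Z-decay archetypes form cluster II). Half of the Z-decay set is
ZGA-dependent — exactly the planted α-amanitin-sensitive archetype — and the
overlap is far beyond chance against the maternal universe
(hypergeometric log10 p ≈ −48).

The same stages are available from a shell:

```sh
mztdecay simulate --outdir fixtures --seed 42
mztdecay classify --matrix fixtures/matrix.tsv --sheet fixtures/samples.tsv \
    --ercc-pct fixtures/ercc_pct.tsv --out annotation.tsv
mztdecay run --config run.yaml        # end-to-end with a YAML config
```

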