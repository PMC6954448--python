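"""Seeded synthetic data with known ground truth for the decay pipeline.

The generator emulates the structure of stage-resolved embryo RNA-seq across
the maternal-to-zygotic transition, with five planted transcript archetypes:

* ``M-decay``            — degraded during oocyte maturation (cluster I);
* ``Z-decay-ZGA-dep``    — stable through fertilization, degraded after
  zygotic genome activation, stabilized by the configured perturbations
  (cluster II);
* ``Z-decay-ZGA-indep``  — same wild-type kinetics, insensitive to the
  perturbations (cluster II);
* ``continuous``         — degraded throughout (cluster III);
* ``stable``             — constant through the two-cell stage (cluster IV).

True stage profiles are laid out in log2(FPKM + 1) units so that each planted
transition clears the one-unit (two-fold) cluster decision boundary by
``fold_margin_log2``. Observed values are the true FPKM perturbed by
multiplicative log-normal replicate noise and a per-sample library-distortion
scalar; ERCC spike-ins share one true abundance per control across all
samples, and the emitted per-sample ERCC read percentage is proportional to
the sample's distortion (a constant spike-in mass occupies a larger share of
a smaller library), which is exactly the signal the ERCC normalization factor
inverts. The reference sample (wild-type zygote, first replicate) is pinned
to distortion 1 so the true scale is recoverable, not just relative.

Synthetic 3′-UTRs carry exactly planted CPE/PAS counts on a motif-free
background (rejection-sampled), with Z-decay UTRs longer than M-decay UTRs.
Synthetic Ct tables follow the ΔΔCt measurement model with planted relative
levels and uridylation dynamics (low until the zygote stage, three-fold
increase at the two-cell stage for Z-decay transcripts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import ExpressionMatrix, STAGES, CONDITIONS
from .utr import CPE_MOTIFS, PAS_MOTIFS, UTRRecord, count_motifs

ARCHETYPES = ("M-decay", "Z-decay-ZGA-dep", "Z-decay-ZGA-indep",
              "continuous", "stable")

#: Decay cluster each archetype is constructed to occupy.
EXPECTED_CLUSTER = {
    "M-decay": "I",
    "Z-decay-ZGA-dep": "II",
    "Z-decay-ZGA-indep": "II",
    "continuous": "III",
    "stable": "IV",
}

_ALL_MOTIFS = CPE_MOTIFS + PAS_MOTIFS
_BASES = np.array(list("ACGU"))


def _default_utr_params() -> dict:
    # Z-decay UTRs are longer and carry more cis-elements than M-decay UTRs.
    return {
        "M-decay": {"length": (120, 350), "cpe": (0, 1), "pas": (0, 1)},
        "Z-decay-ZGA-dep": {"length": (600, 1200), "cpe": (2, 5), "pas": (2, 4)},
        "Z-decay-ZGA-indep": {"length": (600, 1200), "cpe": (2, 5), "pas": (2, 4)},
        "continuous": {"length": (250, 700), "cpe": (0, 2), "pas": (0, 2)},
        "stable": {"length": (250, 700), "cpe": (0, 2), "pas": (1, 2)},
    }


def _default_stabilized_by() -> dict:
    return {
        "alpha-amanitin": ("Z-decay-ZGA-dep",),
        "Yap1-mKO": ("Z-decay-ZGA-dep",),
        "siTut4/7": ("Z-decay-ZGA-dep",),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic study; identical config + seed reproduces
    byte-identical outputs."""

    genes_per_archetype: int = 200
    n_spikeins: int = 24
    stages: tuple[str, ...] = STAGES
    conditions: tuple[str, ...] = ("WT", "alpha-amanitin", "Yap1-mKO", "siTut4/7")
    replicates: int = 3
    noise_sd_log2: float = 0.2
    library_distortion_range: tuple[float, float] = (0.5, 2.0)
    fold_margin_log2: float = 1.0
    base_log2_range: tuple[float, float] = (6.0, 10.0)
    n_batches: int = 1
    ercc_base_pct: float = 2.0
    utr_params: dict = field(default_factory=_default_utr_params)
    stabilized_by: dict = field(default_factory=_default_stabilized_by)
    qpcr_genes_per_archetype: int = 2
    ct_reference_offset: float = 20.0
    ct_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.genes_per_archetype <= 0:
            raise ValueError("genes_per_archetype must be positive")
        if self.n_spikeins <= 0:
            raise ValueError("n_spikeins must be positive")
        if self.replicates <= 0:
            raise ValueError("replicates must be positive")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be non-negative")
        if self.fold_margin_log2 < 0:
            raise ValueError("fold_margin_log2 must be non-negative")
        lo, hi = self.library_distortion_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_distortion_range must be a positive interval")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage names: {sorted(unknown)}")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition names: {sorted(unknown)}")
        if not {"GV", "zygote", "two-cell"} <= set(self.stages):
            raise ValueError("stages must include GV, zygote and two-cell")
        if not 1 <= self.n_batches <= self.replicates:
            raise ValueError("n_batches must be between 1 and replicates")


@dataclass
class SimTruth:
    """Ground truth of one simulated study.

    ``expression`` holds the planted stage/condition means in log2(FPKM + 1)
    units; ``archetype`` maps each gene to its planted archetype; spike-in
    abundances are constant across samples before library distortion.
    """

    archetype: pd.Series
    expression: pd.DataFrame          # genes x (condition, stage), log2(FPKM+1)
    spikein_abundance: pd.Series
    distortion: pd.Series             # per sample
    ercc_pct: pd.Series               # per sample
    utr: pd.DataFrame | None = None   # gene x (length, cpe_count, pas_count)
    qpcr_expression: pd.DataFrame | None = None
    qpcr_uridylation: pd.DataFrame | None = None
    polysome_binding: pd.DataFrame | None = None

    @property
    def fpkm(self) -> pd.DataFrame:
        """True FPKM means: the inverse of the log2(x + 1) transform."""
        return 2.0 ** self.expression - 1.0

    @property
    def expected_cluster(self) -> pd.Series:
        return self.archetype.map(EXPECTED_CLUSTER).rename("cluster")


def _slug(name: str) -> str:
    return name.replace("/", "").replace(" ", "-")


def _sample_id(condition: str, stage: str, rep: int) -> str:
    return f"{_slug(condition)}.{stage}.r{rep}"


def _true_profiles(config: SimConfig, base: np.ndarray) -> pd.DataFrame:
    """Planted log2(FPKM+1) stage/condition means per gene.

    Every decaying transition drops by ``1 + fold_margin_log2`` units, i.e.
    ``fold_margin_log2`` beyond the one-unit cluster boundary; flat
    transitions sit a full unit from the boundary.
    """
    step = 1.0 + config.fold_margin_log2
    n = config.genes_per_archetype
    archetypes = np.repeat(ARCHETYPES, n)
    genes = [f"gene_{i:05d}" for i in range(len(archetypes))]

    def wt_profile(arch: str, b: np.ndarray) -> dict[str, np.ndarray]:
        if arch == "M-decay":
            prof = {"GV": b, "MII": b - step / 2, "zygote": b - step,
                    "two-cell": b - step, "four-cell": b - step}
        elif arch in ("Z-decay-ZGA-dep", "Z-decay-ZGA-indep"):
            prof = {"GV": b, "MII": b, "zygote": b,
                    "two-cell": b - step, "four-cell": b - step}
        elif arch == "continuous":
            prof = {"GV": b, "MII": b - step / 2, "zygote": b - step,
                    "two-cell": b - 2 * step, "four-cell": b - 2 * step}
        else:  # stable
            prof = {"GV": b, "MII": b, "zygote": b,
                    "two-cell": b, "four-cell": b}
        return prof

    columns = pd.MultiIndex.from_product(
        [config.conditions, config.stages], names=["condition", "stage"])
    data = np.empty((len(genes), len(columns)))
    for ai, arch in enumerate(ARCHETYPES):
        rows = slice(ai * n, (ai + 1) * n)
        b = base[rows]
        wt = wt_profile(arch, b)
        for ci, cond in enumerate(config.conditions):
            stabilized = arch in config.stabilized_by.get(cond, ())
            for si, stage in enumerate(config.stages):
                val = wt[stage]
                if stabilized and stage in ("two-cell", "four-cell"):
                    # perturbation blocks post-zygotic decay
                    val = wt["zygote"]
                data[rows, ci * len(config.stages) + si] = val
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"),
                        columns=columns)


def generate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate the gene × sample FPKM matrix and its ground truth.

    Observed value = 2^(log2 true FPKM + N(0, noise_sd_log2)) × distortion;
    spike-ins share one true abundance across all samples and receive the
    same noise and distortion. The emitted per-sample ERCC percentage is
    ``ercc_base_pct × distortion``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = config.genes_per_archetype * len(ARCHETYPES)
    base = rng.uniform(*config.base_log2_range, size=n_genes)
    expression = _true_profiles(config, base)
    archetype = pd.Series(np.repeat(ARCHETYPES, config.genes_per_archetype),
                          index=expression.index, name="archetype")

    spike_names = [f"ERCC-{i:05d}" for i in range(config.n_spikeins)]
    spike_abund = pd.Series(
        10.0 ** rng.uniform(0.5, 3.0, size=config.n_spikeins),
        index=pd.Index(spike_names, name="gene"), name="abundance")

    samples, meta_rows = [], []
    for cond in config.conditions:
        for stage in config.stages:
            for rep in range(1, config.replicates + 1):
                sid = _sample_id(cond, stage, rep)
                samples.append(sid)
                meta_rows.append({
                    "sample": sid, "stage": stage, "condition": cond,
                    "batch": (rep - 1) % config.n_batches + 1,
                    "replicate": rep,
                })
    meta = pd.DataFrame(meta_rows).set_index("sample")

    distortion = pd.Series(
        rng.uniform(*config.library_distortion_range, size=len(samples)),
        index=meta.index, name="distortion")
    reference = _sample_id("WT" if "WT" in config.conditions
                           else config.conditions[0], "zygote", 1)
    distortion.loc[reference] = 1.0  # pin the anchor sample
    ercc_pct = (config.ercc_base_pct * distortion).rename("ercc_pct")

    true_fpkm = 2.0 ** expression - 1.0
    log2_fpkm = np.log2(true_fpkm.to_numpy())
    gene_values = np.empty((n_genes, len(samples)))
    spike_values = np.empty((config.n_spikeins, len(samples)))
    log2_spike = np.log2(spike_abund.to_numpy())
    cond_idx = {c: i for i, c in enumerate(config.conditions)}
    stage_idx = {s: i for i, s in enumerate(config.stages)}
    for j, sid in enumerate(samples):
        cond, stage = meta.loc[sid, "condition"], meta.loc[sid, "stage"]
        col = cond_idx[cond] * len(config.stages) + stage_idx[stage]
        noise = (rng.normal(0.0, config.noise_sd_log2, size=n_genes)
                 if config.noise_sd_log2 > 0 else 0.0)
        gene_values[:, j] = 2.0 ** (log2_fpkm[:, col] + noise) * distortion[sid]
        snoise = (rng.normal(0.0, config.noise_sd_log2, size=config.n_spikeins)
                  if config.noise_sd_log2 > 0 else 0.0)
        spike_values[:, j] = 2.0 ** (log2_spike + snoise) * distortion[sid]

    values = pd.DataFrame(
        np.vstack([gene_values, spike_values]),
        index=pd.Index(list(expression.index) + spike_names, name="gene"),
        columns=samples)
    meta = meta.assign(ercc_pct=ercc_pct)
    matrix = ExpressionMatrix(values=values, sample_meta=meta)
    truth = SimTruth(archetype=archetype, expression=expression,
                     spikein_abundance=spike_abund, distortion=distortion,
                     ercc_pct=ercc_pct)
    return matrix, truth


# ---------------------------------------------------------------------------
# 3'-UTR generation

def _motif_free(n: int, rng: np.random.Generator) -> str:
    """A random RNA string of length n containing no CPE or PAS occurrence.

    Occurrences are scrubbed in place by resampling the offending window,
    which converges far faster than whole-sequence rejection for long UTRs.
    """
    seq = list(rng.choice(_BASES, size=n))
    for _ in range(1000):
        s = "".join(seq)
        hit = -1
        for motif in _ALL_MOTIFS:
            pos = s.find(motif)
            if pos != -1:
                hit = pos
                width = len(motif)
                break
        if hit == -1:
            return s
        seq[hit:hit + width] = list(rng.choice(_BASES, size=width))
    raise RuntimeError("failed to scrub motifs from background sequence")


def plant_motifs(length: int, cpe: int, pas: int,
                 rng: np.random.Generator) -> str:
    """Build a sequence of exactly ``length`` nt with exactly the given
    CPE and PAS counts; raises if the counts cannot fit the length."""
    for _ in range(100):
        motifs = ([CPE_MOTIFS[i] for i in rng.integers(0, len(CPE_MOTIFS), cpe)]
                  + [PAS_MOTIFS[i] for i in rng.integers(0, len(PAS_MOTIFS), pas)])
        rng.shuffle(motifs)
        occupied = sum(len(m) for m in motifs)
        free = length - occupied
        if free < 0:
            raise ValueError(
                f"motif counts ({cpe} CPE, {pas} PAS) incompatible with "
                f"length {length}")
        cuts = np.sort(rng.integers(0, free + 1, size=len(motifs)))
        seg_lens = np.diff(np.concatenate([[0], cuts, [free]]))
        parts = []
        for seg_len, motif in zip(seg_lens[:-1], motifs):
            parts.append(_motif_free(int(seg_len), rng))
            parts.append(motif)
        parts.append(_motif_free(int(seg_lens[-1]), rng))
        seq = "".join(parts)
        if count_motifs(seq) == (cpe, pas):  # junctions can create extras
            return seq
    raise RuntimeError("failed to plant exact motif counts")


def generate_utrs(config: SimConfig, truth: SimTruth) -> list[UTRRecord]:
    """Simulate one 3′-UTR per gene with planted length and motif counts.

    Per-archetype length and count ranges come from ``config.utr_params``;
    the defaults give Z-decay transcripts longer UTRs and more CPEs/PASs
    than M-decay transcripts. Updates ``truth.utr`` with the planted values.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    records, rows = [], []
    for gene, arch in truth.archetype.items():
        params = config.utr_params[arch]
        length = int(rng.integers(params["length"][0], params["length"][1] + 1))
        cpe = int(rng.integers(params["cpe"][0], params["cpe"][1] + 1))
        pas = int(rng.integers(params["pas"][0], params["pas"][1] + 1))
        seq = plant_motifs(length, cpe, pas, rng)
        records.append(UTRRecord(gene=gene, sequence=seq,
                                 cpe_count=cpe, pas_count=pas))
        rows.append({"gene": gene, "length": length,
                     "cpe_count": cpe, "pas_count": pas})
    truth.utr = pd.DataFrame(rows).set_index("gene")
    return records


# ---------------------------------------------------------------------------
# qPCR generation

_URID_LOW = 0.2
_URID_HIGH = 0.6   # three-fold increase when uridylation is activated


def _urid_level(arch: str, stage: str, stabilized: bool) -> float:
    """Planted 3′-oligouridylation index for one archetype at one stage."""
    stages_after = {"two-cell", "four-cell"}
    if arch in ("Z-decay-ZGA-dep", "Z-decay-ZGA-indep"):
        if stage in stages_after and not stabilized:
            return _URID_HIGH
        return _URID_LOW
    if arch == "M-decay":
        return _URID_LOW if stage == "GV" else _URID_HIGH
    return _URID_LOW


def generate_qpcr(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Simulate a replicate Ct table from the planted expression levels.

    Ct = ct_reference_offset − log2(true relative level) + N(0, ct_noise_sd),
    in triplicate. Random-primed assays measure expression relative to a
    Gapdh-like reference; oligo(dA)-primed assays measure the uridylated
    fraction times expression, relative to a Gfp-like reference. Updates
    ``truth.qpcr_expression`` and ``truth.qpcr_uridylation``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    n = config.qpcr_genes_per_archetype
    genes = [g for arch in ARCHETYPES
             for g in truth.archetype.index[truth.archetype == arch][:n]]
    fpkm = truth.fpkm
    rows, expr_rows, urid_rows = [], [], []
    for cond in config.conditions:
        for stage in config.stages:
            sample = f"{_slug(cond)}.{stage}"
            levels = {"Gapdh": {"random": 1.0}, "Gfp": {"oligo_dA": 1.0}}
            for gene in genes:
                arch = truth.archetype[gene]
                stabilized = arch in config.stabilized_by.get(cond, ())
                expr = fpkm.loc[gene, (cond, stage)] / 100.0
                urid = _urid_level(arch, stage, stabilized)
                if expr <= 0:
                    raise ValueError(f"non-positive true level for {gene}")
                levels[gene] = {"random": expr, "oligo_dA": urid * expr}
                expr_rows.append({"sample": sample, "condition": cond,
                                  "stage": stage, "gene": gene, "level": expr})
                urid_rows.append({"sample": sample, "condition": cond,
                                  "stage": stage, "gene": gene, "level": urid})
            for gene, by_mode in levels.items():
                for mode, level in by_mode.items():
                    ref = "Gapdh" if mode == "random" else "Gfp"
                    for rep in range(1, 4):  # triplicate assays
                        noise = (rng.normal(0.0, config.ct_noise_sd)
                                 if config.ct_noise_sd > 0 else 0.0)
                        rows.append({
                            "sample": sample, "condition": cond, "gene": gene,
                            "primer_mode": mode, "reference_gene": ref,
                            "replicate": rep,
                            "ct": config.ct_reference_offset
                                  - np.log2(level) + noise,
                        })
    truth.qpcr_expression = pd.DataFrame(expr_rows)
    truth.qpcr_uridylation = pd.DataFrame(urid_rows)
    return pd.DataFrame(rows, columns=["sample", "condition", "gene",
                                       "primer_mode", "reference_gene",
                                       "replicate", "ct"])


# ---------------------------------------------------------------------------
# Polysome profiles

def generate_polysome(config: SimConfig, truth: SimTruth,
                      stages: tuple[str, ...] = ("GV", "MII"),
                      repeats: int = 2,
                      spikein_gene: str = "mCherry") -> pd.DataFrame:
    """Simulate polysome-bound expression with an mCherry spike-in row.

    Planted binding fractions: M-decay transcripts are polysome-bound at GV
    and released by MII; Z-decay transcripts show the reverse; others are
    constant. Each sample carries a capture-efficiency scalar that the
    spike-in row (equal mass added to every sample) exposes, so dividing by
    it recovers the planted signal. Updates ``truth.polysome_binding``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    binding = {"M-decay": {"GV": 0.8, "MII": 0.2},
               "Z-decay-ZGA-dep": {"GV": 0.2, "MII": 0.8},
               "Z-decay-ZGA-indep": {"GV": 0.2, "MII": 0.8},
               "continuous": {"GV": 0.5, "MII": 0.5},
               "stable": {"GV": 0.5, "MII": 0.5}}
    gv_fpkm = truth.fpkm[("WT" if "WT" in config.conditions
                          else config.conditions[0], "GV")]
    samples = [f"polysome.{stage}.r{rep}"
               for stage in stages for rep in range(1, repeats + 1)]
    efficiency = rng.uniform(0.5, 2.0, size=len(samples))
    data, bind_rows = {}, []
    for j, sid in enumerate(samples):
        stage = sid.split(".")[1]
        col = []
        for gene in truth.archetype.index:
            frac = binding[truth.archetype[gene]].get(stage, 0.5)
            noise = (rng.normal(0.0, config.noise_sd_log2)
                     if config.noise_sd_log2 > 0 else 0.0)
            col.append(frac * gv_fpkm[gene] * 2.0 ** noise * efficiency[j])
        data[sid] = col + [50.0 * efficiency[j]]  # spike-in row, no noise
    for gene in truth.archetype.index:
        for stage in stages:
            bind_rows.append({"gene": gene, "stage": stage,
                              "binding": binding[truth.archetype[gene]][stage]})
    truth.polysome_binding = pd.DataFrame(bind_rows)
    return pd.DataFrame(
        data, index=pd.Index(list(truth.archetype.index) + [spikein_gene],
                             name="gene"))


# ---------------------------------------------------------------------------
# Fixture writing

def write_fixtures(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic fixture set to ``outdir``; returns the paths.

    Files: expression matrix TSV, sample sheet TSV, ERCC-percentage TSV,
    UTR FASTA, Ct CSV, and the ground-truth TSVs. Deterministic for a fixed
    config (byte-identical across runs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    utr_records = generate_utrs(config, truth)
    ct = generate_qpcr(config, truth)

    paths = {
        "matrix": outdir / "matrix.tsv",
        "samples": outdir / "samples.tsv",
        "ercc_pct": outdir / "ercc_pct.tsv",
        "utr_fasta": outdir / "utrs.fasta",
        "ct": outdir / "ct.csv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_expression": outdir / "truth_expression.tsv",
    }
    matrix.values.to_csv(paths["matrix"], sep="\t", float_format="%.8g")
    matrix.sample_meta.drop(columns=["ercc_pct"]).to_csv(
        paths["samples"], sep="\t")
    truth.ercc_pct.to_frame().to_csv(paths["ercc_pct"], sep="\t",
                                     float_format="%.8g")
    with open(paths["utr_fasta"], "w") as fh:
        for rec in utr_records:
            fh.write(f">{rec.gene}\n{rec.sequence}\n")
    ct.to_csv(paths["ct"], index=False, float_format="%.8g")
    truth_genes = pd.concat(
        [truth.archetype, truth.expected_cluster, truth.utr], axis=1)
    truth_genes.to_csv(paths["truth_genes"], sep="\t")
    flat = truth.expression.copy()
    flat.columns = [f"{c}|{s}" for c, s in flat.columns]
    flat.to_csv(paths["truth_expression"], sep="\t", float_format="%.8g")
    return paths
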