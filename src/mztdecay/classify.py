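"""Decay-cluster classification and pathway-dependence gene sets.

Maternal transcripts (FPKM > 2 in GV oocytes) are partitioned into four decay
clusters by fixed inequalities on mean log2(FPKM + 1) expression E at the GV,
zygote and two-cell stages (a unit step on this scale is a two-fold change):

* Cluster I  (M-decay):    E(GV) > E(zyg) + 1  and  E(zyg) < E(2C) + 1
* Cluster II (Z-decay):    |E(GV) − E(zyg)| < 1  and  E(zyg) > E(2C) + 1
* Cluster III (continuous): E(GV) > E(zyg) + 1  and  E(zyg) > E(2C) + 1
* Cluster IV (stable):     |E(GV) − E(zyg)| < 1  and  |E(zyg) − E(2C)| < 1

All inequalities are strict; profiles on a boundary fall in none of the four
systems and are reported as ``unclassified`` rather than force-assigned. The
systems are mutually exclusive by construction.

Pathway-dependence sets (ZGA-, YAP1-, TUT4/7-dependent decay) are defined by
fold-ratio thresholds on floored, ERCC-normalized FPKM between perturbation
and control conditions; flooring at FPKM = 1 keeps every denominator ≥ 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .normalize import ExpressionMatrix, log_transform

CLUSTERS = ("I", "II", "III", "IV")
UNCLASSIFIED = "unclassified"

#: FPKM threshold (strict) defining a maternal transcript at the GV stage.
MATERNAL_FPKM_THRESHOLD = 2.0


def stage_means(matrix: ExpressionMatrix, scale: str = "fpkm",
                drop_spikeins: bool = True) -> pd.DataFrame:
    """Per-gene stage/condition means on the requested working scale.

    Returns a DataFrame indexed by gene with MultiIndex columns
    ``(condition, stage)``. ``scale='fpkm'`` averages the (floored) FPKM
    values used by ratio criteria; ``scale='log2'`` averages log2(x + 1)
    values used by the cluster inequalities. Replicates are aggregated by
    arithmetic mean on the working scale.
    """
    if scale == "log2":
        matrix = log_transform(matrix)
    elif scale != "fpkm":
        raise ValueError(f"unknown scale {scale!r}")
    if drop_spikeins:
        matrix = matrix.drop_spikeins()
    meta = matrix.sample_meta
    groups = matrix.values.T.groupby(
        [meta["condition"], meta["stage"]], sort=False).mean().T
    groups.columns = pd.MultiIndex.from_tuples(
        groups.columns, names=["condition", "stage"])
    return groups


def _require_stages(profile: pd.DataFrame, stages: tuple[str, ...]) -> None:
    missing = [s for s in stages if s not in profile.columns]
    if missing:
        raise ValueError(f"profile lacks required stage(s): {missing}")


def classify_cluster(gv: float, zygote: float, two_cell: float) -> str:
    """Classify one expression profile (log2(x+1) stage means) into a cluster."""
    labels = classify_clusters(pd.DataFrame(
        {"GV": [gv], "zygote": [zygote], "two-cell": [two_cell]}))
    return labels.iloc[0]


def classify_clusters(log2_means: pd.DataFrame) -> pd.Series:
    """Vectorized cluster assignment for a genes × stages log2(x+1) frame.

    Requires columns ``GV``, ``zygote`` and ``two-cell``. Returns a Series of
    labels in {"I", "II", "III", "IV", "unclassified"}.
    """
    _require_stages(log2_means, ("GV", "zygote", "two-cell"))
    gv = log2_means["GV"].to_numpy(float)
    zy = log2_means["zygote"].to_numpy(float)
    tc = log2_means["two-cell"].to_numpy(float)

    gv_drop = gv > zy + 1          # two-fold drop GV -> zygote
    gv_flat = (gv < zy + 1) & (gv > zy - 1)
    zy_drop = zy > tc + 1          # two-fold drop zygote -> two-cell
    zy_rise_ok = zy < tc + 1       # no two-fold drop zygote -> two-cell
    zy_flat = zy_rise_ok & (zy > tc - 1)

    labels = np.full(len(log2_means), UNCLASSIFIED, dtype=object)
    labels[gv_drop & zy_rise_ok] = "I"
    labels[gv_flat & zy_drop] = "II"
    labels[gv_drop & zy_drop] = "III"
    labels[gv_flat & zy_flat] = "IV"
    return pd.Series(labels, index=log2_means.index, name="cluster")


def cluster_report(labels: pd.Series) -> dict:
    """Cluster-size accounting for a Series of cluster labels.

    Returns the per-cluster sizes, the number of analyzed (classified)
    transcripts — the sum of the four cluster sizes — and the number left
    unclassified, reported separately rather than folded into a cluster.
    """
    counts = labels.value_counts()
    sizes = {c: int(counts.get(c, 0)) for c in CLUSTERS}
    return {"sizes": sizes,
            "analyzed": int(sum(sizes.values())),
            "unclassified": int(counts.get(UNCLASSIFIED, 0))}


def select_maternal(fpkm_means: pd.DataFrame,
                    threshold: float = MATERNAL_FPKM_THRESHOLD) -> pd.Index:
    """Genes with mean floored FPKM > ``threshold`` at the GV stage (strict)."""
    _require_stages(fpkm_means, ("GV",))
    return fpkm_means.index[fpkm_means["GV"] > threshold]


def degraded_set(fpkm_means: pd.DataFrame, from_stage: str, to_stage: str,
                 ratio_threshold: float) -> pd.Index:
    """Genes whose FPKM(to)/FPKM(from) ratio is strictly below the threshold."""
    if not 0.0 < ratio_threshold < 1.0:
        raise ValueError("ratio_threshold must lie in (0, 1)")
    _require_stages(fpkm_means, (from_stage, to_stage))
    ratio = fpkm_means[to_stage] / fpkm_means[from_stage]
    return fpkm_means.index[ratio < ratio_threshold]


def zdecay_set(fpkm_means: pd.DataFrame,
               maternal_threshold: float = MATERNAL_FPKM_THRESHOLD) -> pd.Index:
    """Z-decay transcripts from wild-type stage means.

    FPKM(GV) > 2; FPKM(zygote)/FPKM(GV) ≥ 1/2; FPKM(two-cell)/FPKM(zygote) < 1/2.
    Stable through fertilization, cleared after zygotic genome activation.
    """
    _require_stages(fpkm_means, ("GV", "zygote", "two-cell"))
    maternal = fpkm_means["GV"] > maternal_threshold
    stable_to_zygote = fpkm_means["zygote"] / fpkm_means["GV"] >= 0.5
    degraded_after = fpkm_means["two-cell"] / fpkm_means["zygote"] < 0.5
    return fpkm_means.index[maternal & stable_to_zygote & degraded_after]


def zga_dependent(fpkm_wt: pd.DataFrame, fpkm_treated: pd.DataFrame,
                  maternal_threshold: float = MATERNAL_FPKM_THRESHOLD) -> pd.Index:
    """Z-decay transcripts stabilized when zygotic transcription is blocked.

    The Z-decay criteria are evaluated on the wild-type means; a transcript is
    ZGA-dependent when its two-cell/zygote ratio under RNA-polymerase-II
    inhibition (alpha-amanitin) is ≥ 1/2, i.e. its degradation is blocked.
    The treated zygote column is used when the treated condition includes one
    (treatment begins at the zygote stage, so it matches the wild-type
    zygote); otherwise the wild-type zygote is the denominator.
    """
    z_genes = zdecay_set(fpkm_wt, maternal_threshold)
    _require_stages(fpkm_treated, ("two-cell",))
    if "zygote" in fpkm_treated.columns:
        denominator = fpkm_treated["zygote"]
    else:
        denominator = fpkm_wt["zygote"]
    common = z_genes.intersection(fpkm_treated.index)
    ratio = fpkm_treated.loc[common, "two-cell"] / denominator.loc[common]
    return common[ratio >= 0.5]


def yap1_dependent(fpkm_wt: pd.DataFrame, fpkm_ko: pd.DataFrame,
                   maternal_threshold: float = MATERNAL_FPKM_THRESHOLD) -> pd.Index:
    """Maternal transcripts stabilized in embryos from Yap1-null oocytes.

    FPKM(GV) > 2; FPKM(four-cell)/FPKM(GV) < 1/2 in wild type;
    FPKM(knockout)/FPKM(wild type) > 1 at the four-cell stage.
    """
    _require_stages(fpkm_wt, ("GV", "four-cell"))
    _require_stages(fpkm_ko, ("four-cell",))
    maternal = fpkm_wt["GV"] > maternal_threshold
    degraded_wt = fpkm_wt["four-cell"] / fpkm_wt["GV"] < 0.5
    candidates = fpkm_wt.index[maternal & degraded_wt]
    common = candidates.intersection(fpkm_ko.index)
    accumulated = (fpkm_ko.loc[common, "four-cell"]
                   / fpkm_wt.loc[common, "four-cell"]) > 1.0
    return common[accumulated]


def tut47_dependent(fpkm_wt: pd.DataFrame, fpkm_kd: pd.DataFrame,
                    fold_threshold: float = 2.0,
                    decay_ratio: float = 1.0 / 3.0) -> pd.Index:
    """Transcripts dependent on zygotic TUT4/7 for clearance.

    Upregulated in Tut4/7-depleted two-cell embryos
    (FPKM(knockdown)/FPKM(wild type) > 2, strict) intersected with transcripts
    degraded from zygote to two-cell in wild type
    (FPKM(two-cell)/FPKM(zygote) < 1/3, strict).
    """
    _require_stages(fpkm_wt, ("zygote", "two-cell"))
    _require_stages(fpkm_kd, ("two-cell",))
    common = fpkm_wt.index.intersection(fpkm_kd.index)
    up_in_kd = (fpkm_kd.loc[common, "two-cell"]
                / fpkm_wt.loc[common, "two-cell"]) > fold_threshold
    degraded = (fpkm_wt.loc[common, "two-cell"]
                / fpkm_wt.loc[common, "zygote"]) < decay_ratio
    return common[up_in_kd & degraded]


def annotate(matrix: ExpressionMatrix,
             wt_condition: str = "WT",
             amanitin_condition: str = "alpha-amanitin",
             yap1_condition: str = "Yap1-mKO",
             tut47_condition: str = "siTut4/7") -> pd.DataFrame:
    """Full per-gene decay annotation of a floored, ERCC-normalized matrix.

    Returns a DataFrame with the cluster label, the maternal flag, and
    pathway-dependence flags as pandas nullable booleans; ``pd.NA`` encodes a
    criterion that was not evaluable (a required stage or condition absent),
    which is deliberately distinct from ``False``.
    """
    fpkm = stage_means(matrix, "fpkm")
    log2 = stage_means(matrix, "log2")
    conditions = fpkm.columns.get_level_values("condition").unique()
    if wt_condition not in conditions:
        raise ValueError(f"no samples in condition {wt_condition!r}")
    fpkm_wt = fpkm[wt_condition]
    log2_wt = log2[wt_condition]

    genes = fpkm.index
    out = pd.DataFrame(index=genes)
    maternal_genes = select_maternal(fpkm_wt)
    out["maternal"] = genes.isin(maternal_genes)

    clusterable = {"GV", "zygote", "two-cell"} <= set(log2_wt.columns)
    if clusterable:
        labels = classify_clusters(log2_wt)
        labels[~out["maternal"]] = UNCLASSIFIED
        out["cluster"] = labels
    else:
        out["cluster"] = pd.NA

    def _flag(name: str, fn) -> None:
        try:
            members = fn()
        except (ValueError, KeyError):
            out[name] = pd.array([pd.NA] * len(genes), dtype="boolean")
            return
        out[name] = pd.array(genes.isin(members), dtype="boolean")

    _flag("m_decay", lambda: genes[(out["cluster"] == "I").to_numpy(bool)])
    _flag("z_decay", lambda: zdecay_set(fpkm_wt))
    _flag("zga_dependent",
          lambda: zga_dependent(fpkm_wt, fpkm[amanitin_condition]))
    _flag("yap1_dependent",
          lambda: yap1_dependent(fpkm_wt, fpkm[yap1_condition]))
    _flag("tut47_dependent",
          lambda: tut47_dependent(fpkm_wt, fpkm[tut47_condition]))
    _flag("degraded_2c_4c",
          lambda: degraded_set(fpkm_wt, "two-cell", "four-cell", 0.5))

    # underlying ratios for transparency
    with np.errstate(divide="ignore", invalid="ignore"):
        for frm, to in (("GV", "zygote"), ("zygote", "two-cell"),
                        ("two-cell", "four-cell")):
            if frm in fpkm_wt.columns and to in fpkm_wt.columns:
                out[f"ratio_{to}_vs_{frm}"] = fpkm_wt[to] / fpkm_wt[frm]
    return out
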