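"""3′-UTR length and cis-element (CPE/PAS) analysis.

Cytoplasmic polyadenylation elements (CPE: UUUUAU or UUUUAAU) and
polyadenylation signals (PAS: AAUAAA or AUUAAA) in the 3′-UTR control
cytoplasmic poly(A)-tail dynamics and translational activation during oocyte
maturation. Transcripts cleared by the zygotic (Z-decay) pathway tend to carry
longer 3′-UTRs — and hence more CPEs and PASs — than transcripts cleared by
the maternal (M-decay) pathway; length-matched control sets separate the
motif-count effect from the length effect.

Motif occurrences are counted as distinct start positions per element class
on the sense strand, with overlapping matches allowed; a position matching
UUUUAU inside a UUUUAAU context counts once for the CPE class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import setstats

CPE_MOTIFS = ("UUUUAU", "UUUUAAU")
PAS_MOTIFS = ("AAUAAA", "AUUAAA")

_VALID = set("ACGU")


@dataclass(frozen=True)
class UTRRecord:
    """A per-gene 3′-UTR sequence with its length and cis-element counts."""

    gene: str
    sequence: str
    cpe_count: int
    pas_count: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, gene: str, sequence: str) -> "UTRRecord":
        seq = normalize_rna(sequence)
        cpe, pas = count_motifs(seq)
        return cls(gene=gene, sequence=seq, cpe_count=cpe, pas_count=pas)


def normalize_rna(sequence: str) -> str:
    """Uppercase and transcribe a DNA (ACGT) or RNA (ACGU) string to RNA."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def _match_positions(seq: str, motifs: tuple[str, ...]) -> set[int]:
    positions: set[int] = set()
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            positions.add(start)
            start = seq.find(motif, start + 1)
    return positions


def count_motifs(sequence: str) -> tuple[int, int]:
    """(CPE count, PAS count): distinct match start positions per class.

    Accepts DNA or RNA input; overlapping occurrences are all counted.
    """
    seq = normalize_rna(sequence)
    return (len(_match_positions(seq, CPE_MOTIFS)),
            len(_match_positions(seq, PAS_MOTIFS)))


def load_utrs(fasta_path: str | Path,
              bed_path: str | Path | None = None) -> list[UTRRecord]:
    """Read 3′-UTR sequences from FASTA (DNA or RNA), one record per gene.

    When a gene appears more than once (multiple annotated isoforms), the
    longest sequence is kept. When a 6-column BED of UTR intervals (0-based,
    half-open) is supplied, each record's sequence length must equal its
    interval length.
    """
    best: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = normalize_rna(str(rec.seq))
        if rec.id not in best or len(seq) > len(best[rec.id]):
            best[rec.id] = seq
    if bed_path is not None:
        bed = pd.read_csv(
            bed_path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"start": int, "end": int})
        for row in bed.itertuples(index=False):
            if row.name in best:
                expected = row.end - row.start
                actual = len(best[row.name])
                if actual != expected:
                    raise ValueError(
                        f"UTR length mismatch for {row.name}: FASTA {actual} nt"
                        f" vs BED interval {expected} nt")
    return [UTRRecord.from_sequence(gene, seq)
            for gene, seq in sorted(best.items())]


def utr_table(records: list[UTRRecord]) -> pd.DataFrame:
    """Per-gene table of UTR length and motif counts, indexed by gene."""
    return pd.DataFrame(
        {"length": [r.length for r in records],
         "cpe_count": [r.cpe_count for r in records],
         "pas_count": [r.pas_count for r in records]},
        index=pd.Index([r.gene for r in records], name="gene"))


def length_matched_controls(target_genes, pool_genes,
                            utrs: pd.DataFrame) -> tuple[dict[str, str], float]:
    """Greedy 1:1 nearest-UTR-length matching of controls to targets.

    Targets are processed in decreasing UTR length; each is matched without
    replacement to the pool gene of nearest length (ties broken by
    lexicographic gene identifier). Returns the target → control mapping and
    the absolute difference of the matched median lengths as a QC distance.
    """
    targets = list(target_genes)
    pool = set(pool_genes)
    if pool & set(targets):
        raise ValueError("candidate pool must be disjoint from the target set")
    if len(pool) < len(targets):
        raise ValueError("candidate pool smaller than target set")
    lengths = utrs["length"]
    # deterministic: sort pool by (length, gene id)
    available = sorted(pool, key=lambda g: (lengths[g], g))
    order = sorted(targets, key=lambda g: (-lengths[g], g))
    mapping: dict[str, str] = {}
    for gene in order:
        best = min(available,
                   key=lambda g: (abs(lengths[g] - lengths[gene]), g))
        mapping[gene] = best
        available.remove(best)
    target_median = float(np.median([lengths[g] for g in mapping]))
    control_median = float(np.median([lengths[g] for g in mapping.values()]))
    return mapping, abs(target_median - control_median)


def compare_utr_features(set_a, set_b, utrs: pd.DataFrame,
                         name_a: str = "A", name_b: str = "B") -> pd.DataFrame:
    """Median/quartile summary of UTR length, CPE and PAS counts per set.

    Between-set significance uses the two-tailed unpaired Student's t-test;
    the comparison is reported as not applicable (NaN, 'n.a.') when either
    set has fewer than two members.
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    rows = []
    for feature in ("length", "cpe_count", "pas_count"):
        va = utrs.loc[set_a, feature].to_numpy(float)
        vb = utrs.loc[set_b, feature].to_numpy(float)
        row = {"feature": feature}
        for name, v in ((name_a, va), (name_b, vb)):
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            row[f"{name}_median"] = med
            row[f"{name}_q1"] = q1
            row[f"{name}_q3"] = q3
        if len(va) < 2 or len(vb) < 2:
            row.update({"t": np.nan, "p": np.nan, "stars": "n.a."})
        else:
            t, p, stars = setstats.group_compare(va, vb)
            row.update({"t": t, "p": p, "stars": stars})
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
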