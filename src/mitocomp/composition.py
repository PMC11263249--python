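"""Base-composition statistics and region partitioning of mitogenomes.

Strand-asymmetry statistics follow the standard definitions
``GC skew = (G - C) / (G + C)`` and ``AT skew = (A - T) / (A + T)``;
GC content is ``(G + C) / (A + C + G + T)``.  N bases never enter a
denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import CORE_PCGS, RRNA_GENES, Mitogenome, extract_gene_sequence

#: region classes in precedence order (earlier wins on overlap)
REGION_CLASSES = ("core_pcg", "rna_gene", "uorf", "intron", "intergenic")


@dataclass
class CompositionStats:
    gc_content: float
    gc_skew: float
    at_skew: float
    counts: dict[str, int]


def composition_stats(sequence: str) -> CompositionStats:
    """GC content and GC/AT skews of a sequence (NaN where undefined)."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGTN"}
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    total = a + c + g + t
    gc_content = (g + c) / total if total else math.nan
    gc_skew = (g - c) / (g + c) if (g + c) else math.nan
    at_skew = (a - t) / (a + t) if (a + t) else math.nan
    return CompositionStats(gc_content=gc_content, gc_skew=gc_skew,
                            at_skew=at_skew, counts=counts)


@dataclass
class RegionPartition:
    lengths: dict[str, int]
    percentages: dict[str, float]
    total: int


def partition_regions(genome: Mitogenome) -> RegionPartition:
    """Assign every position to exactly one of the five region classes.

    Overlaps are resolved by precedence core PCG exon > RNA gene > uORF >
    intron > intergenic, so e.g. a uORF inside a cox1 intron counts as uORF
    and the core exons are never eroded by overlapping annotations.
    """
    n = genome.length
    # class codes, higher = stronger; painted weakest-first
    code = {"intergenic": 0, "intron": 1, "uorf": 2, "rna_gene": 3, "core_pcg": 4}
    paint = np.zeros(n, dtype=np.int8)

    def mark(segments, cls):
        lvl = code[cls]
        for s, e in segments:
            if s <= e:
                seg = paint[s:e]
                np.maximum(seg, lvl, out=seg)
            else:  # origin-spanning
                np.maximum(paint[s:], lvl, out=paint[s:])
                np.maximum(paint[:e], lvl, out=paint[:e])

    overlap_warned = False
    for f in genome.features:
        if f.kind == "intron":
            mark(f.segments, "intron")
    for f in genome.features:
        if f.kind == "CDS" and f.gene in CORE_PCGS and len(f.segments) > 1:
            # gaps between exon segments of a split core gene are intronic
            for (s1, e1), (s2, e2) in zip(f.segments, f.segments[1:]):
                if e1 <= s2:
                    mark([(e1, s2)], "intron")
    for f in genome.features:
        if f.kind == "uORF":
            mark(f.segments, "uorf")
    for f in genome.features:
        if f.kind in ("rRNA", "tRNA"):
            mark(f.segments, "rna_gene")
    for f in genome.features:
        if f.kind == "CDS" and f.gene in CORE_PCGS:
            for s, e in f.segments:
                seg = paint[s:e] if s <= e else np.concatenate([paint[s:], paint[:e]])
                if np.any(seg == code["core_pcg"]) and not overlap_warned:
                    warnings.warn(f"{genome.id}: overlapping core genes resolved "
                                  "by precedence")
                    overlap_warned = True
            mark(f.segments, "core_pcg")

    lengths = {cls: int(np.sum(paint == lvl)) for cls, lvl in code.items()}
    lengths = {cls: lengths[cls] for cls in REGION_CLASSES}
    percentages = {cls: (100.0 * ln / n if n else math.nan)
                   for cls, ln in lengths.items()}
    return RegionPartition(lengths=lengths, percentages=percentages, total=n)


def partition_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        part = partition_regions(g)
        row = {"genome_id": g.id, "species": g.species, "total_bp": part.total}
        for cls in REGION_CLASSES:
            row[f"{cls}_bp"] = part.lengths[cls]
            row[f"{cls}_pct"] = round(part.percentages[cls], 2)
        rows.append(row)
    return pd.DataFrame(rows)


def genome_composition_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Whole-genome composition statistics, one row per genome."""
    rows = []
    for g in genomes:
        st = composition_stats(g.sequence)
        rows.append({"genome_id": g.id, "species": g.species,
                     "length_bp": g.length,
                     "gc_content": st.gc_content, "gc_skew": st.gc_skew,
                     "at_skew": st.at_skew,
                     "n_trna": len(g.features_of_kind("tRNA")),
                     "n_introns": len(g.features_of_kind("intron"))})
    return pd.DataFrame(rows)


def per_gene_length_table(genomes: list[Mitogenome],
                          genes: tuple[str, ...] = CORE_PCGS) -> pd.DataFrame:
    """Length/GC/skew per (species, core gene); absent genes yield NA rows.

    Per-gene skews are computed on the coding strand, so their sign can
    differ from the whole-genome skew.
    """
    rows = []
    for g in genomes:
        for gene in genes:
            feat = g.feature_for_gene(gene, kind="CDS")
            if feat is None:
                rows.append({"genome_id": g.id, "species": g.species,
                             "gene": gene, "length": pd.NA,
                             "gc_content": math.nan, "gc_skew": math.nan,
                             "at_skew": math.nan})
                continue
            seq = extract_gene_sequence(g, feat)
            st = composition_stats(seq)
            rows.append({"genome_id": g.id, "species": g.species, "gene": gene,
                         "length": len(seq), "gc_content": st.gc_content,
                         "gc_skew": st.gc_skew, "at_skew": st.at_skew})
    return pd.DataFrame(rows)
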