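"""cox1 intron insertion-position classes (Pcls).

Introns interrupting cox1 are mapped onto a reference cox1 coding sequence:
the coding position immediately 5' of each intron is converted to a
reference coordinate by protein-guided alignment (align translations, expand
back to nucleotides), and introns sharing a reference position form one
position class, named ``P<position>`` with 1-based nucleotide numbering.
Classes present in at least 20% of the species are "common", the rest
"rare".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .align import AA_SCORES, pairwise_global
from .genome_io import (CODE4, GeneticCode, Mitogenome, extract_gene_sequence,
                        translate)

COMMON_THRESHOLD = 0.20


@dataclass
class IntronRecord:
    species: str
    gene: str
    ordinal: int
    interval: tuple[int, int]
    coding_position: int          # species CDS nt immediately 5' of the intron
    intron_type: str = ""         # pass-through annotation label
    mapped_position: int | None = None
    mapping_flag: str = ""


@dataclass
class Pcl:
    position: int
    members: dict[str, str] = field(default_factory=dict)  # species -> type
    status: str = ""

    @property
    def name(self) -> str:
        return f"P{self.position}"


def introns_from_genome(genome: Mitogenome, gene: str = "cox1") -> list[IntronRecord]:
    """Intron records of a gene, from its split CDS feature.

    The species coding position of each intron is the cumulative exon length
    5' of it (in coding orientation); intron_type labels are taken from
    overlapping intron features when present.
    """
    cds = genome.feature_for_gene(gene, kind="CDS")
    if cds is None or len(cds.segments) < 2:
        return []
    intron_feats = [f for f in genome.features
                    if f.kind == "intron" and f.gene == gene]

    def type_for(iv: tuple[int, int]) -> str:
        for f in intron_feats:
            fs, fe = f.segments[0][0], f.segments[-1][1]
            if fs <= iv[0] and iv[1] <= fe + 1 or (fs, fe) == iv:
                return f.qualifiers.get("intron_type", "")
        return ""

    records = []
    segs = cds.segments
    if cds.strand == "-":
        # coding order runs right-to-left on the genome
        coding_segs = segs[::-1]
        gaps = []
        for (s1, e1), (s0, e0) in zip(coding_segs, coding_segs[1:]):
            gaps.append((e0, s1))  # genomic interval of the intron
    else:
        coding_segs = segs
        gaps = [(e1, s2) for (s1, e1), (s2, e2) in zip(segs, segs[1:])]
    cum = 0
    for i, ((s, e), gap) in enumerate(zip(coding_segs, gaps + [None]), start=1):
        cum += e - s
        if gap is None:
            break
        records.append(IntronRecord(species=genome.species, gene=gene,
                                    ordinal=i, interval=gap,
                                    coding_position=cum,
                                    intron_type=type_for(gap)))
    return records


def map_insertion_position(intron: IntronRecord, species_cds: str,
                           reference_cds: str,
                           code: GeneticCode = CODE4) -> int:
    """Reference coding position (1-based nt) of an intron insertion site.

    When species and reference CDS are identical the species position is
    returned unchanged.  Otherwise the two translations are globally aligned
    and the species coordinate is carried through the alignment; a site
    falling in a reference gap is moved to the nearest upstream aligned
    position and flagged.
    """
    p = intron.coding_position
    if not 1 <= p <= len(species_cds):
        raise ValueError(f"coding position {p} outside species CDS")
    if species_cds == reference_cds:
        intron.mapped_position = p
        return p
    prot_s = translate(species_cds, code, internal_stop="keep")
    prot_r = translate(reference_cds, code, internal_stop="keep")
    row_s, row_r, _ = pairwise_global(prot_s, prot_r, AA_SCORES)
    aa_idx = (p - 1) // 3          # 0-based species amino acid
    offset = (p - 1) % 3
    s_seen = r_seen = 0
    ref_aa = None
    flag = ""
    for ch_s, ch_r in zip(row_s, row_r):
        if ch_s != "-":
            if s_seen == aa_idx:
                if ch_r != "-":
                    ref_aa = r_seen
                else:
                    ref_aa = r_seen - 1
                    flag = "reference-gap:nearest-upstream"
                    offset = 2  # end of the upstream reference codon
                break
            s_seen += 1
        if ch_r != "-":
            r_seen += 1
    if ref_aa is None or ref_aa < 0:
        ref_aa, offset, flag = 0, 0, "unalignable:clamped"
    pos = ref_aa * 3 + offset + 1
    pos = min(pos, len(reference_cds))
    intron.mapped_position = pos
    intron.mapping_flag = flag
    return pos


def build_pcl_catalog(introns: list[IntronRecord], species_cds: dict[str, str],
                      reference_cds: str, code: GeneticCode = CODE4) -> list[Pcl]:
    """Group mapped introns into one Pcl per reference position."""
    by_pos: dict[int, Pcl] = {}
    for rec in introns:
        pos = rec.mapped_position
        if pos is None:
            pos = map_insertion_position(rec, species_cds[rec.species],
                                         reference_cds, code)
        pcl = by_pos.setdefault(pos, Pcl(position=pos))
        if rec.species in pcl.members:
            raise ValueError(f"{rec.species}: two introns map to position {pos}")
        pcl.members[rec.species] = rec.intron_type
    return [by_pos[p] for p in sorted(by_pos)]


def classify_common_rare(catalog: list[Pcl], n_species: int,
                         threshold: float = COMMON_THRESHOLD) -> list[Pcl]:
    """Status 'common' iff member count >= ceil(threshold * n_species)."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    cutoff = math.ceil(threshold * n_species)
    for pcl in catalog:
        pcl.status = "common" if len(pcl.members) >= cutoff else "rare"
    return catalog


def pcl_matrix(catalog: list[Pcl], species_order: list[str]) -> pd.DataFrame:
    """Species x Pcl table; cells carry the pass-through intron-type labels."""
    cols = [p.name for p in sorted(catalog, key=lambda p: p.position)]
    data = {p.name: [p.members.get(sp, "") for sp in species_order]
            for p in catalog}
    return pd.DataFrame(data, index=species_order, columns=cols)


def catalog_table(catalog: list[Pcl]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pcl": p.name, "position": p.position, "n_members": len(p.members),
        "status": p.status, "members": ";".join(sorted(p.members)),
        "types": ";".join(sorted(set(filter(None, p.members.values())))),
    } for p in sorted(catalog, key=lambda p: p.position)])


def cox1_pcl_analysis(genomes: list[Mitogenome], reference_species: str,
                      threshold: float = COMMON_THRESHOLD,
                      code: GeneticCode = CODE4) -> tuple[list[Pcl], pd.DataFrame]:
    """End-to-end Pcl catalog + presence matrix for a cohort."""
    species_cds: dict[str, str] = {}
    all_introns: list[IntronRecord] = []
    for g in genomes:
        feat = g.feature_for_gene("cox1", kind="CDS")
        if feat is None:
            continue
        species_cds[g.species] = extract_gene_sequence(g, feat)
        all_introns.extend(introns_from_genome(g))
    if reference_species not in species_cds:
        raise ValueError(f"reference species {reference_species!r} lacks cox1")
    reference = species_cds[reference_species]
    catalog = build_pcl_catalog(all_introns, species_cds, reference, code)
    classify_common_rare(catalog, n_species=len(species_cds), threshold=threshold)
    matrix = pcl_matrix(catalog, sorted(species_cds))
    return catalog, matrix
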