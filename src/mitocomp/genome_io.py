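"""Annotated mitogenome I/O, circular coordinates, translation, ORF scanning.

The coordinate model is 0-based half-open throughout; GenBank 1-based
inclusive coordinates are converted at the I/O boundary.  Circular genomes
are never rotated implicitly: a feature that spans the origin is stored as
two segments, ``[x, L)`` followed by ``[0, y)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

#: the 15 core protein-coding markers of fungal mitogenomes
CORE_PCGS = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6", "rps3",
)
#: the 14 conserved energy-metabolism genes (core set minus rps3)
CONSERVED_PCGS = tuple(g for g in CORE_PCGS if g != "rps3")
RRNA_GENES = ("rnl", "rns")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    pass


@dataclass
class GeneFeature:
    """One annotated feature; multi-segment features are intron-split genes."""

    kind: str  # CDS | tRNA | rRNA | intron | uORF | other
    gene: str
    strand: str  # '+' | '-'
    segments: list[tuple[int, int]]
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise GenomeIOError(f"feature {self.gene}: empty segment list")
        if self.strand not in "+-":
            raise GenomeIOError(f"feature {self.gene}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass
class Mitogenome:
    """A (usually circular) annotated mitochondrial genome."""

    id: str
    species: str
    sequence: str
    topology: str = "circular"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"bad topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def feature_for_gene(self, gene: str, kind: str | None = None) -> GeneFeature | None:
        for f in self.features:
            if f.gene == gene and (kind is None or f.kind == kind):
                return f
        return None


@dataclass(frozen=True)
class GeneticCode:
    """A translation table; stops map to '*'.

    Table 4 (mold/protozoan mitochondrial) reassigns TGA from stop to
    tryptophan, which is why fungal mitochondrial CDSs have only two true
    stop codons (TAA, TAG).
    """

    table_id: int
    codons: dict[str, str]
    start_codons: frozenset[str]

    @classmethod
    def from_table(cls, table_id: int = 4) -> "GeneticCode":
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        codons = dict(tab.forward_table)
        for stop in tab.stop_codons:
            codons[stop] = "*"
        assert len(codons) == 64
        return cls(table_id=table_id, codons=codons,
                   start_codons=frozenset(tab.start_codons))

    def is_stop(self, codon: str) -> bool:
        return self.codons.get(codon) == "*"

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codons.items() if aa == "*")

    def synonymous_families(self) -> dict[str, list[str]]:
        """Amino acid -> sorted codon list (stops grouped under '*')."""
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.codons):
            fams.setdefault(self.codons[codon], []).append(codon)
        return fams


CODE4 = GeneticCode.from_table(4)

#: start codons used for ORF scanning (TTG starts are observed in these genomes)
ORF_START_CODONS = frozenset({"ATG", "GTG", "TTG"})


@dataclass
class Orf:
    start: int
    end: int
    strand: str
    length_codons: int
    protein: str


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_KIND_TO_GENBANK = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                    "intron": "intron", "uORF": "ORF", "other": "misc_feature"}
_GENBANK_TO_KIND = {v: k for k, v in _KIND_TO_GENBANK.items()}


def _location_segments(loc) -> list[tuple[int, int]]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    segs = [(int(p.start), int(p.end)) for p in parts]
    if loc.strand == -1:
        # Biopython lists minus-strand parts in transcription order; store in
        # genome order so extract_gene_sequence can revcomp the concatenate.
        segs = segs[::-1]
    return segs


def read_genbank(path: str | Path) -> list[Mitogenome]:
    """Read all records of a GenBank flat file as Mitogenomes."""
    genomes = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise GenomeIOError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeIOError(f"no GenBank records found in {path}")
    for rec in records:
        topology = rec.annotations.get("topology", "linear")
        species = rec.annotations.get("organism", "") or rec.description or rec.id
        feats: list[GeneFeature] = []
        for f in rec.features:
            if f.type == "source":
                continue
            kind = _GENBANK_TO_KIND.get(f.type, "other")
            quals = {k: ";".join(map(str, v)) for k, v in f.qualifiers.items()}
            gene = quals.get("gene") or quals.get("label") or quals.get("product") or f.type
            if kind == "other" and quals.get("kind") == "uORF":
                kind = "uORF"
            segs = _location_segments(f.location)
            for s, e in segs:
                if e > len(rec.seq) and topology == "linear":
                    raise GenomeIOError(
                        f"{rec.id}: feature {gene} segment [{s},{e}) exceeds "
                        f"linear sequence length {len(rec.seq)}")
            strand = "-" if f.location.strand == -1 else "+"
            feats.append(GeneFeature(kind=kind, gene=gene, strand=strand,
                                     segments=segs, qualifiers=quals))
        genomes.append(Mitogenome(id=rec.id, species=species,
                                  sequence=str(rec.seq).upper(),
                                  topology=topology, features=feats))
    return genomes


def write_genbank(genomes: Iterable[Mitogenome], path: str | Path) -> None:
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id.split(".")[0][:16],
                        description=g.species)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = g.topology
        rec.annotations["organism"] = g.species
        for f in sorted(g.features, key=lambda f: f.start):
            strand = -1 if f.strand == "-" else 1
            segs = f.segments if strand == 1 else f.segments[::-1]
            locs = [SimpleLocation(s, e, strand) for s, e in segs]
            loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            quals: dict[str, list[str]] = {"gene": [f.gene]}
            if f.kind == "uORF":
                quals["kind"] = ["uORF"]
            for k, v in f.qualifiers.items():
                quals.setdefault(k, [v])
            rec.features.append(SeqFeature(loc, type=_KIND_TO_GENBANK.get(f.kind, "misc_feature"),
                                           qualifiers=quals))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as 60-column FASTA; ids must be unique."""
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise GenomeIOError(f"duplicate FASTA ids: {dupes}")
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def feature_table(genomes: Iterable[Mitogenome]) -> pd.DataFrame:
    """Flat per-feature table (TSV-exportable)."""
    rows = []
    for g in genomes:
        for f in g.features:
            rows.append({
                "genome_id": g.id, "species": g.species, "gene": f.gene,
                "kind": f.kind, "strand": f.strand,
                "segments": ";".join(f"{s}-{e}" for s, e in f.segments),
                "length": f.length,
                "qualifiers": ";".join(f"{k}={v}" for k, v in sorted(f.qualifiers.items())),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequence extraction and translation
# ---------------------------------------------------------------------------

def extract_segment(genome: Mitogenome, start: int, end: int) -> str:
    """Extract [start, end); on circular genomes start > end wraps the origin."""
    n = genome.length
    if start <= end:
        if end > n:
            raise GenomeIOError(f"segment [{start},{end}) outside genome of length {n}")
        return genome.sequence[start:end]
    if genome.topology != "circular":
        raise GenomeIOError("wrap-around segment on a linear genome")
    return genome.sequence[start:] + genome.sequence[:end]


def extract_gene_sequence(genome: Mitogenome, feature: GeneFeature) -> str:
    """Spliced, strand-corrected nucleotide sequence of a feature."""
    parts = [extract_segment(genome, s, e) for s, e in feature.segments]
    seq = "".join(parts)
    if feature.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate(cds: str, code: GeneticCode = CODE4, *,
              internal_stop: str = "warn") -> str:
    """Translate an in-frame CDS.

    The trailing stop codon is dropped; a trailing partial codon is dropped
    with a warning; codons containing N yield 'X'.  ``internal_stop`` is one
    of 'warn' (keep '*', warn), 'error', or 'keep'.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise GenomeIOError("CDS shorter than one codon")
    if len(cds) % 3:
        warnings.warn(f"CDS length {len(cds)} not divisible by 3; trailing "
                      f"{len(cds) % 3} nt dropped")
        cds = cds[: len(cds) - len(cds) % 3]
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        aa = code.codons.get(codon, "X")
        aas.append(aa)
    if aas and aas[-1] == "*":
        aas.pop()
    protein = "".join(aas)
    if "*" in protein:
        if internal_stop == "error":
            raise GenomeIOError(f"internal stop codon at aa {protein.index('*') + 1}")
        if internal_stop == "warn":
            warnings.warn("internal stop codon in translation")
    return protein


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def _scan_strand(seq: str, min_orf_codons: int, code: GeneticCode,
                 start_codons: frozenset[str]) -> list[tuple[int, int, str]]:
    """ORFs on the forward strand of ``seq``: (start, end, protein).

    Within each frame, runs between stops yield at most one ORF (from the
    first usable start codon to the stop), which resolves same-frame overlaps
    to the longest ORF.
    """
    out = []
    n = len(seq)
    for frame in range(3):
        start_at: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if code.is_stop(codon):
                if start_at is not None:
                    ncod = (i - start_at) // 3
                    if ncod >= min_orf_codons:
                        prot = translate(seq[start_at:i + 3], code,
                                         internal_stop="keep")
                        out.append((start_at, i + 3, prot))
                start_at = None
            elif start_at is None and codon in start_codons:
                start_at = i
    return out


def find_orfs(genome: Mitogenome, regions: Sequence[tuple[int, int]],
              min_region_nt: int = 300, min_orf_codons: int = 100,
              code: GeneticCode = CODE4,
              start_codons: frozenset[str] = ORF_START_CODONS) -> list[Orf]:
    """Scan regions longer than ``min_region_nt`` for ORFs on both strands.

    Region bounds use genome coordinates; on circular genomes a region with
    start > end wraps the origin.  Returned coordinates are genome
    coordinates of the ORF including its stop codon (strand-aware; for '-'
    ORFs ``start``/``end`` still delimit the genome interval).
    """
    orfs: list[Orf] = []
    n = genome.length
    for rs, re_ in regions:
        rlen = (re_ - rs) if rs <= re_ else (n - rs + re_)
        if rlen < min_region_nt:
            continue
        sub = extract_segment(genome, rs, re_)
        for strand in "+-":
            s = sub if strand == "+" else reverse_complement(sub)
            for a, b, prot in _scan_strand(s, min_orf_codons, code, start_codons):
                if strand == "+":
                    gs, ge = rs + a, rs + b
                else:
                    gs, ge = rs + (rlen - b), rs + (rlen - a)
                if n > 0 and gs >= n:  # wrapped region: back onto the circle
                    gs, ge = gs - n, ge - n
                # an ORF spanning the origin keeps ge > n (end exclusive)
                orfs.append(Orf(start=gs, end=ge, strand=strand,
                                length_codons=len(prot), protein=prot))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def intergenic_regions(genome: Mitogenome,
                       kinds: tuple[str, ...] = ("CDS", "tRNA", "rRNA")) -> list[tuple[int, int]]:
    """Maximal intervals not covered by any feature of the given kinds."""
    covered: list[tuple[int, int]] = []
    for f in genome.features:
        if f.kind in kinds:
            covered.extend(f.segments)
    if not covered:
        return [(0, genome.length)]
    covered.sort()
    merged = [list(covered[0])]
    for s, e in covered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if e1 < s2:
            gaps.append((e1, s2))
    # flank gap, wrapping on circular genomes
    first_s, last_e = merged[0][0], merged[-1][1]
    if genome.topology == "circular":
        if last_e < genome.length or first_s > 0:
            if (genome.length - last_e + first_s) > 0:
                gaps.append((last_e % genome.length, first_s))
    else:
        if first_s > 0:
            gaps.insert(0, (0, first_s))
        if last_e < genome.length:
            gaps.append((last_e, genome.length))
    return gaps
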