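"""Circular gene-order extraction, breakpoint distance, and synteny blocks.

The gene order of a mitogenome is the signed circular sequence of the 17
canonical markers (15 core protein-coding genes plus rnl and rns), rotated
to start at +cox1; tRNAs are excluded by default.  Arrangements are compared
with the signed circular breakpoint distance (adjacencies present in one
order but not the other) and whole-genome collinearity is assessed with
seed-chain-extend synteny blocks above identity/length thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import pandas as pd

from .genome_io import CORE_PCGS, RRNA_GENES, Mitogenome, reverse_complement

CANONICAL_MARKERS = tuple(CORE_PCGS) + tuple(RRNA_GENES)


@dataclass
class GeneOrder:
    species: str
    markers: list[str]  # signed labels, e.g. '+cox1', '-nad2'

    def unsigned(self) -> list[str]:
        return [m[1:] for m in self.markers]


def _flip(marker: str) -> str:
    return ("-" if marker[0] == "+" else "+") + marker[1:]


def extract_gene_order(genome: Mitogenome,
                       markers: tuple[str, ...] = CANONICAL_MARKERS) -> GeneOrder:
    """Signed circular marker order starting at +cox1.

    Markers are sorted by start coordinate on the circle; if cox1 lies on the
    minus strand the whole order is reflected and sign-flipped so cox1 reads
    '+'.  Duplicated canonical markers raise; missing markers are simply
    absent from the order.
    """
    found: dict[str, tuple[int, str]] = {}
    dupes = []
    for f in genome.features:
        if f.gene in markers and f.kind in ("CDS", "rRNA"):
            if f.gene in found:
                dupes.append(f.gene)
                continue
            found[f.gene] = (f.start, f.strand)
    if dupes:
        raise ValueError(f"{genome.id}: duplicate canonical markers {sorted(set(dupes))}")
    ordered = sorted(found, key=lambda g: found[g][0])
    signed = [("+" if found[g][1] == "+" else "-") + g for g in ordered]
    if "cox1" in found:
        i = next(i for i, m in enumerate(signed) if m[1:] == "cox1")
        signed = signed[i:] + signed[:i]
        if signed[0][0] == "-":
            signed = [_flip(m) for m in reversed(signed)]
            signed = signed[-1:] + signed[:-1]  # keep cox1 first after reflection
    return GeneOrder(species=genome.species, markers=signed)


def _adjacencies(markers: list[str]) -> set[tuple[str, str]]:
    """Canonical signed circular adjacency set.

    The adjacency (a, b) read left-to-right equals (-b, -a) read on the other
    strand; each pair is normalized to the lexicographically smaller form.
    """
    adj = set()
    n = len(markers)
    for i in range(n):
        a, b = markers[i], markers[(i + 1) % n]
        alt = (_flip(b), _flip(a))
        adj.add(min((a, b), alt))
    return adj


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Signed circular breakpoint distance on the shared marker set."""
    shared = set(a.unsigned()) & set(b.unsigned())
    if len(shared) < 2:
        raise ValueError("orders share fewer than 2 markers")
    ra = [m for m in a.markers if m[1:] in shared]
    rb = [m for m in b.markers if m[1:] in shared]
    return len(_adjacencies(ra) - _adjacencies(rb))


def order_groups(orders: list[GeneOrder]) -> list[list[str]]:
    """Partition species into identical-arrangement groups (distance 0)."""
    groups: list[tuple[GeneOrder, list[str]]] = []
    for o in orders:
        for rep, members in groups:
            shared_ok = len(set(o.unsigned()) & set(rep.unsigned())) >= 2
            if (shared_ok and breakpoint_distance(o, rep) == 0
                    and breakpoint_distance(rep, o) == 0
                    and set(o.unsigned()) == set(rep.unsigned())):
                members.append(o.species)
                break
        else:
            groups.append((o, [o.species]))
    return [sorted(members) for _, members in groups]


def order_table(orders: list[GeneOrder]) -> pd.DataFrame:
    return pd.DataFrame([{"species": o.species, "order": " ".join(o.markers)}
                         for o in orders])


def breakpoint_matrix(orders: list[GeneOrder]) -> pd.DataFrame:
    names = [o.species for o in orders]
    mat = pd.DataFrame(0, index=names, columns=names)
    for i, a in enumerate(orders):
        for b in orders[i + 1:]:
            d = breakpoint_distance(a, b)
            mat.loc[a.species, b.species] = mat.loc[b.species, a.species] = d
    return mat


# ---------------------------------------------------------------------------
# synteny blocks
# ---------------------------------------------------------------------------

@dataclass
class SyntenyBlock:
    pair: tuple[str, str]
    locus1: tuple[int, int]
    locus2: tuple[int, int]
    strand: str
    identity: float
    length: int


def _seed_chains(sa: str, sb: str, k: int, max_gap: int):
    """(a0,a1,b0,b1) runs of co-diagonal exact k-mer seeds between sa and sb."""
    index: dict[str, list[int]] = {}
    for i in range(len(sa) - k + 1):
        index.setdefault(sa[i:i + k], []).append(i)
    diag: dict[int, list[tuple[int, int]]] = {}
    for j in range(len(sb) - k + 1):
        kmer = sb[j:j + k]
        if "N" in kmer:
            continue
        for i in index.get(kmer, []):
            diag.setdefault(j - i, []).append((i, j))
    chains = []
    for d, plist in diag.items():
        plist = sorted(set(plist))
        rs = prev = plist[0][0]
        for i, _ in plist[1:]:
            if i - prev <= max_gap:
                prev = i
            else:
                chains.append((rs, prev + k, rs + d, prev + k + d))
                rs = prev = i
        chains.append((rs, prev + k, rs + d, prev + k + d))
    return chains


def find_synteny_blocks(a: Mitogenome, b: Mitogenome, min_identity: float = 70.0,
                        min_len: int = 500, seed_k: int = 12,
                        max_chain_gap: int = 300) -> list[SyntenyBlock]:
    """Pairwise collinear blocks on both strands, re-scored by alignment.

    Identity is gap-inclusive: ``100 * (1 - editDistance / alignment_span)``.
    """
    out: list[SyntenyBlock] = []
    for strand in "+-":
        sb_seq = b.sequence if strand == "+" else reverse_complement(b.sequence)
        for a0, a1, b0, b1 in _seed_chains(a.sequence, sb_seq, seed_k, max_chain_gap):
            if a1 - a0 < min_len:
                continue
            s1 = a.sequence[a0:a1]
            s2 = sb_seq[b0:b1]
            res = edlib.align(s1, s2, task="distance")
            ident = 100.0 * (1.0 - res["editDistance"] / max(len(s1), len(s2)))
            if ident < min_identity:
                continue
            if strand == "+":
                locus2 = (b0, b1)
            else:
                n = b.length
                locus2 = (n - b1, n - b0)
            out.append(SyntenyBlock(pair=(a.id, b.id), locus1=(a0, a1),
                                    locus2=locus2, strand=strand,
                                    identity=round(ident, 2),
                                    length=max(a1 - a0, b1 - b0)))
    # containment dedupe, deterministic order
    out.sort(key=lambda r: (-r.length, r.locus1, r.locus2))
    kept: list[SyntenyBlock] = []
    for r in out:
        if not any(q.strand == r.strand
                   and q.locus1[0] <= r.locus1[0] and r.locus1[1] <= q.locus1[1]
                   and q.locus2[0] <= r.locus2[0] and r.locus2[1] <= q.locus2[1]
                   for q in kept):
            kept.append(r)
    kept.sort(key=lambda r: (r.locus1, r.locus2))
    return kept


def synteny_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame([{
        "genome_a": blk.pair[0], "genome_b": blk.pair[1],
        "a_start": blk.locus1[0], "a_end": blk.locus1[1],
        "b_start": blk.locus2[0], "b_end": blk.locus2[1],
        "strand": blk.strand, "identity": blk.identity, "length": blk.length,
    } for blk in blocks])
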