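"""Synthetic annotated mitogenome cohorts with known ground truth.

Coding sequences evolve on a user-supplied tree under the two-rate
Kimura (K80) substitution model with per-gene rate multipliers; genomes are
assembled on a circle in (possibly rearranged) gene order with AT-rich
intergenic spacers, cox1 introns planted at chosen coding positions,
planted uORFs, and planted dispersed/tandem repeats.  Everything is driven
by one integer seed and is byte-reproducible.

The default cohort emulates a 16-taxon set of Hymenochaetales-like
mitogenomes: a 3-species *Sanghuangporus*-like clade with identical gene
order, sister *Inonotus*-like and *Porodaedalea*-like clades, genome sizes
spanning roughly 45-160 kb, ~27% GC, and common/rare cox1 intron position
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .genome_io import CODE4, GeneFeature, GeneticCode, Mitogenome, reverse_complement

_BASES = np.array(list("ACGT"))
_TS_PARTNER = np.array([2, 3, 0, 1])   # A<->G, C<->T
_TV_A = np.array([1, 0, 1, 0])
_TV_B = np.array([3, 2, 3, 2])

#: per-gene CDS lengths in codons (excluding the stop codon)
DEFAULT_GENE_CODONS = {
    "cox1": 530, "cob": 390, "cox2": 250, "cox3": 270, "nad1": 320,
    "nad2": 550, "nad3": 140, "nad4": 480, "nad4l": 90, "nad5": 660,
    "nad6": 220, "atp6": 250, "atp8": 50, "atp9": 75, "rps3": 450,
}
DEFAULT_RNA_LENGTHS = {"rnl": 3000, "rns": 1600}

#: relative substitution-rate multipliers (rps3 fast, atp9 slow)
DEFAULT_RATE_MULTIPLIERS = {
    "rps3": 1.8, "nad3": 1.5, "nad6": 1.4, "atp9": 0.25, "atp8": 0.8,
    "rnl": 0.5, "rns": 0.5,
}

#: gene arrangement of the Sanghuangporus-like trio, starting from cox1
BASE_GENE_ORDER = [
    "cox1", "nad4l", "nad5", "atp9", "cox2", "cob", "cox3", "atp6",
    "nad1", "rnl", "nad4", "rns", "rps3", "atp8", "nad6", "nad2", "nad3",
]

DEFAULT_TREE = (
    "(((((S_sanghuang:0.04,(S_vaninii:0.02,P_gilvus:0.02):0.03):0.06,"
    "(I_hispidus:0.05,I_obliquus:0.05):0.06):0.04,"
    "((P_pini:0.03,P_niemelaei:0.03):0.02,"
    "(P_mongolica:0.03,P_chrysoloma:0.03):0.02):0.05):0.03,"
    "((P_noxius:0.05,P_lamaoensis:0.05):0.03,"
    "(P_viticola:0.06,(C_sulphurascens:0.05,P_ferrugineofuscus:0.05):0.02):0.03):0.03):0.04,"
    "F_mediterranea:0.08,F_palustris:0.12);"
)

SANGHUANGPORUS_CLADE = ("S_sanghuang", "S_vaninii", "P_gilvus")

#: cox1 intron plan: reference coding position -> (intron type, member species)
DEFAULT_INTRON_PLAN = {
    209: ("IA", ("S_sanghuang", "S_vaninii", "P_gilvus", "I_hispidus",
                 "I_obliquus", "P_pini", "P_niemelaei", "P_mongolica",
                 "P_chrysoloma", "P_noxius")),
    728: ("IB", ("S_sanghuang", "S_vaninii", "P_gilvus", "I_hispidus",
                 "I_obliquus", "P_viticola", "P_ferrugineofuscus",
                 "C_sulphurascens", "F_mediterranea", "F_palustris")),
    393: ("IA", ("S_sanghuang", "S_vaninii", "P_gilvus", "P_pini",
                 "P_niemelaei", "P_mongolica", "P_chrysoloma", "P_noxius",
                 "P_lamaoensis")),
    1304: ("I-derived", SANGHUANGPORUS_CLADE),
    88: ("IA", ("I_hispidus",)),
    1450: ("IB", ("F_palustris",)),
}

#: rearrangement events per species, applied to BASE_GENE_ORDER.
#: ("inversion", i, j) reverses and sign-flips order[i:j];
#: ("transposition", i, j, k) moves order[i:j] to before original index k.
DEFAULT_REARRANGEMENT_PLAN: dict[str, list[tuple]] = {
    "I_hispidus": [("inversion", 4, 8)],
    "I_obliquus": [("inversion", 4, 8)],
    "P_pini": [("transposition", 10, 12, 17)],
    "P_niemelaei": [("transposition", 10, 12, 17)],
    "P_mongolica": [("transposition", 10, 12, 17)],
    "P_chrysoloma": [("transposition", 10, 12, 17)],
    "P_noxius": [("inversion", 2, 4)],
    "P_lamaoensis": [("inversion", 2, 4)],
    "C_sulphurascens": [("transposition", 10, 11, 3), ("transposition", 13, 14, 3)],
    "F_palustris": [("inversion", 1, 5), ("transposition", 9, 10, 16)],
}

#: intergenic spacer scale per species (drives the genome-size spread)
DEFAULT_INTERGENIC_SCALE = {
    "I_hispidus": 3.5, "I_obliquus": 2.2, "P_pini": 2.0, "P_noxius": 1.5,
}

PCG_BASE_PREFS = {"A": 0.35, "C": 0.12, "G": 0.15, "T": 0.38}
UORF_BASE_PREFS = {"A": 0.28, "C": 0.24, "G": 0.21, "T": 0.27}
PCG_BOOST = {"TTA": 3.0, "TTT": 2.0, "ATT": 2.0, "AAT": 1.5}
UORF_BOOST = {"CTC": 3.0, "GGA": 2.0, "AGC": 2.0, "CAA": 1.5}


@dataclass
class SimulationSpec:
    tree: str = DEFAULT_TREE
    kappa: float = 2.0
    base_freqs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.36, "C": 0.13, "G": 0.14, "T": 0.37})
    gene_codons: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_CODONS))
    rna_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RNA_LENGTHS))
    rate_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_MULTIPLIERS))
    n_trna: int = 25
    trna_length: int = 72
    intron_plan: dict[int, tuple[str, tuple[str, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_PLAN))
    intron_length: int = 800
    rearrangement_plan: dict[str, list[tuple]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_REARRANGEMENT_PLAN.items()})
    dispersed_repeat_length: int = 500
    tandem_unit: str = "ACGTT"
    tandem_copies: int = 8
    n_intergenic_uorfs: int = 3
    uorf_codons: int = 120
    intergenic_median: float = 500.0
    intergenic_sigma: float = 0.6
    intergenic_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERGENIC_SCALE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        cox1_nt = 3 * self.gene_codons["cox1"]
        for pos in self.intron_plan:
            if not 1 <= pos <= cox1_nt:
                raise ValueError(f"intron position {pos} outside cox1 CDS "
                                 f"(1..{cox1_nt})")


@dataclass
class GroundTruth:
    tree: str
    pairwise_distances: dict[tuple[str, str], float]
    pcl_plan: dict[int, tuple[str, tuple[str, ...]]]
    gene_orders: dict[str, list[str]]
    repeat_loci: dict[str, dict[str, list[tuple[int, int]]]]
    region_lengths: dict[str, dict[str, int]]


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------

def _k80_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(same, transition, each-transversion) probabilities after distance d."""
    e1 = np.exp(-4.0 * d / (kappa + 2.0))
    e2 = np.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_tv = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def evolve_branch(parent: np.ndarray, d: float, kappa: float,
                  rng: np.random.Generator,
                  protect_frame: bool = False,
                  code: GeneticCode = CODE4) -> np.ndarray:
    """Evolve an integer-coded (0..3) sequence along one branch.

    With ``protect_frame`` the sequence is treated as an in-frame CDS and any
    substitution creating an in-frame stop codon is reverted (the terminal
    stop codon, if present, is left untouched by this rule).
    """
    if d <= 0:
        return parent.copy()
    p_same, p_ts, p_tv = _k80_probs(d, kappa)
    u = rng.random(parent.size)
    child = parent.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tva_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tvb_mask = u >= p_same + p_ts + p_tv
    child[ts_mask] = _TS_PARTNER[parent[ts_mask]]
    child[tva_mask] = _TV_A[parent[tva_mask]]
    child[tvb_mask] = _TV_B[parent[tvb_mask]]
    if protect_frame:
        stop_idx = _stop_codon_indices(code)
        ncod = child.size // 3
        cod = child[: 3 * ncod].reshape(ncod, 3)
        packed = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
        parent_cod = parent[: 3 * ncod].reshape(ncod, 3)
        parent_packed = parent_cod[:, 0] * 16 + parent_cod[:, 1] * 4 + parent_cod[:, 2]
        bad = np.isin(packed, stop_idx) & ~np.isin(parent_packed, stop_idx)
        if bad.any():
            cod[bad] = parent_cod[bad]
    return child


def _stop_codon_indices(code: GeneticCode) -> np.ndarray:
    base_idx = {b: i for i, b in enumerate("ACGT")}
    return np.array([base_idx[c[0]] * 16 + base_idx[c[1]] * 4 + base_idx[c[2]]
                     for c in sorted(code.stop_codons)])


def _seq_to_ints(seq: str) -> np.ndarray:
    lookup = np.zeros(256, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)


def _ints_to_seq(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def random_sequence(length: int, rng: np.random.Generator,
                    freqs: dict[str, float] | None = None) -> str:
    freqs = freqs or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    p = np.array([freqs[b] for b in "ACGT"])
    p = p / p.sum()
    return _ints_to_seq(rng.choice(4, size=length, p=p))


def _codon_profile(base_prefs: dict[str, float], boost: dict[str, float],
                   code: GeneticCode = CODE4) -> tuple[list[str], np.ndarray]:
    codons = [c for c in sorted(code.codons) if code.codons[c] != "*"]
    w = np.array([base_prefs[c[0]] * base_prefs[c[1]] * base_prefs[c[2]]
                  * boost.get(c, 1.0) for c in codons])
    return codons, w / w.sum()


def random_cds(n_codons: int, rng: np.random.Generator, profile: str = "pcg",
               code: GeneticCode = CODE4) -> str:
    """ATG + biased internal codons + TAA; no internal stops."""
    prefs, boost = ((PCG_BASE_PREFS, PCG_BOOST) if profile == "pcg"
                    else (UORF_BASE_PREFS, UORF_BOOST))
    codons, p = _codon_profile(prefs, boost, code)
    body = rng.choice(len(codons), size=max(n_codons - 1, 0), p=p)
    return "ATG" + "".join(codons[i] for i in body) + "TAA"


# ---------------------------------------------------------------------------
# tree-based sequence simulation
# ---------------------------------------------------------------------------

def _parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def simulate_on_tree(root_seq: str, tree: dendropy.Tree, kappa: float,
                     rate: float, rng: np.random.Generator,
                     protect_frame: bool = False) -> dict[str, str]:
    """Evolve a root sequence down a tree; returns leaf-name -> sequence."""
    if not root_seq:
        raise ValueError("empty root sequence")
    states = {id(tree.seed_node): _seq_to_ints(root_seq)}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        d = (node.edge.length or 0.0) * rate
        child = evolve_branch(parent_state, d, kappa, rng, protect_frame)
        states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = _ints_to_seq(child)
    if tree.seed_node.is_leaf():
        out[tree.seed_node.taxon.label] = root_seq
    return out


def simulate_alignment_on_tree(spec: SimulationSpec,
                               ) -> tuple[dict[str, dict[str, str]], GroundTruth]:
    """Per-gene leaf sequences (gap-free homologs) plus the ground truth."""
    rng = np.random.default_rng(spec.seed)
    tree = _parse_tree(spec.tree)
    gene_seqs: dict[str, dict[str, str]] = {}
    for gene in sorted(spec.gene_codons):
        root = random_cds(spec.gene_codons[gene], rng, profile="pcg")
        rate = spec.rate_multipliers.get(gene, 1.0)
        gene_seqs[gene] = simulate_on_tree(root, tree, spec.kappa, rate, rng,
                                           protect_frame=True)
    for gene in sorted(spec.rna_lengths):
        root = random_sequence(spec.rna_lengths[gene], rng, spec.base_freqs)
        rate = spec.rate_multipliers.get(gene, 1.0)
        gene_seqs[gene] = simulate_on_tree(root, tree, spec.kappa, rate, rng)
    for i in range(spec.n_trna):
        name = f"trn{i:02d}"
        root = random_sequence(spec.trna_length, rng, spec.base_freqs)
        gene_seqs[name] = simulate_on_tree(root, tree, spec.kappa, 0.3, rng)
    truth = GroundTruth(tree=spec.tree,
                        pairwise_distances=_patristic(tree),
                        pcl_plan=dict(spec.intron_plan),
                        gene_orders={}, repeat_loci={}, region_lengths={})
    return gene_seqs, truth


def _patristic(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


def simulate_pair(distance: float, length: int, kappa: float = 2.0,
                  seed: int = 0) -> tuple[str, str]:
    """Two sequences at a known K2P divergence (for estimator checks)."""
    rng = np.random.default_rng(seed)
    a = rng.choice(4, size=length)
    b = evolve_branch(a, distance, kappa, rng)
    return _ints_to_seq(a), _ints_to_seq(b)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def apply_rearrangements(order: list[tuple[str, int]],
                         events: list[tuple]) -> list[tuple[str, int]]:
    """Apply inversion/transposition events to a signed gene order."""
    order = list(order)
    for ev in events:
        if ev[0] == "inversion":
            _, i, j = ev
            order[i:j] = [(g, -s) for g, s in reversed(order[i:j])]
        elif ev[0] == "transposition":
            _, i, j, k = ev
            block = order[i:j]
            rest = order[:i] + order[j:]
            k_adj = k - (j - i) if k >= j else k
            order = rest[:k_adj] + block + rest[k_adj:]
        else:
            raise ValueError(f"unknown rearrangement event {ev[0]!r}")
    return order


def _gene_order_for(spec: SimulationSpec, species: str) -> list[tuple[str, int]]:
    base = [(g, 1) for g in BASE_GENE_ORDER]
    return apply_rearrangements(base, spec.rearrangement_plan.get(species, []))


def assemble_mitogenome(spec: SimulationSpec, species: str,
                        gene_seqs: dict[str, dict[str, str]],
                        rng: np.random.Generator,
                        ) -> tuple[Mitogenome, dict]:
    """Lay the species' genes on a circle; returns (genome, per-genome truth)."""
    order = _gene_order_for(spec, species)
    scale = spec.intergenic_scale.get(species, 1.0)
    intron_positions = sorted(pos for pos, (_t, members) in spec.intron_plan.items()
                              if species in members)

    parts: list[str] = []
    features: list[GeneFeature] = []
    region = {"core_pcg": 0, "rna_gene": 0, "uorf": 0, "intron": 0, "intergenic": 0}
    truth_repeats: dict[str, list[tuple[int, int]]] = {"dispersed": [], "tandem": []}
    cursor = 0

    def emit(seq: str, cls: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        region[cls] += len(seq)
        return start

    def gap(min_len: int = 60) -> None:
        ln = int(np.clip(rng.lognormal(np.log(spec.intergenic_median * scale),
                                       spec.intergenic_sigma), min_len, 4000 * scale))
        emit(random_sequence(ln, rng, spec.base_freqs), "intergenic")

    # choose decorated gaps deterministically
    n_slots = len(order)
    trna_slots = sorted(rng.choice(n_slots, size=min(spec.n_trna, n_slots),
                                   replace=False)) if spec.n_trna else []
    trna_assign: dict[int, list[str]] = {}
    trna_names = [g for g in sorted(gene_seqs) if g.startswith("trn")]
    for i, name in enumerate(trna_names):
        slot = trna_slots[i % len(trna_slots)] if trna_slots else 0
        trna_assign.setdefault(slot, []).append(name)
    uorf_slots = set(int(x) for x in rng.choice(n_slots, size=min(spec.n_intergenic_uorfs, n_slots), replace=False))
    disp_slots = sorted(int(x) for x in rng.choice(n_slots, size=2, replace=False))
    tandem_slot = int(rng.integers(0, n_slots))
    dispersed_seq = random_sequence(spec.dispersed_repeat_length, rng)

    for slot, (gene, sign) in enumerate(order):
        gap()
        if slot in uorf_slots:
            uorf = random_cds(spec.uorf_codons, rng, profile="uorf")
            start = emit(uorf, "uorf")
            features.append(GeneFeature(kind="uORF", gene=f"orf{slot}",
                                        strand="+", segments=[(start, start + len(uorf))]))
            gap()
        if slot in disp_slots:
            start = emit(dispersed_seq, "intergenic")
            truth_repeats["dispersed"].append((start, start + len(dispersed_seq)))
            gap()
        if slot == tandem_slot:
            block = spec.tandem_unit * spec.tandem_copies
            start = emit(block, "intergenic")
            truth_repeats["tandem"].append((start, start + len(block)))
            gap()
        for trna in trna_assign.get(slot, []):
            seq = gene_seqs[trna][species]
            start = emit(seq, "rna_gene")
            features.append(GeneFeature(kind="tRNA", gene=trna, strand="+",
                                        segments=[(start, start + len(seq))]))
            gap(min_len=30)
        strand = "+" if sign > 0 else "-"
        if gene in spec.rna_lengths:
            seq = gene_seqs[gene][species]
            if strand == "-":
                seq = reverse_complement(seq)
            start = emit(seq, "rna_gene")
            features.append(GeneFeature(kind="rRNA", gene=gene, strand=strand,
                                        segments=[(start, start + len(seq))]))
            continue
        cds = gene_seqs[gene][species]
        if gene == "cox1" and intron_positions:
            features.extend(_emit_cox1(spec, species, cds, strand,
                                       intron_positions, rng, emit, region))
        else:
            gseq = cds if strand == "+" else reverse_complement(cds)
            start = emit(gseq, "core_pcg")
            features.append(GeneFeature(kind="CDS", gene=gene, strand=strand,
                                        segments=[(start, start + len(gseq))]))
    gap()

    sequence = "".join(parts)
    genome = Mitogenome(id=f"SYN_{species}", species=species, sequence=sequence,
                        topology="circular",
                        features=sorted(features, key=lambda f: f.start))
    truth = {
        "gene_order": [("+" if s > 0 else "-") + g for g, s in order],
        "region_lengths": region,
        "repeats": truth_repeats,
        "intron_positions": intron_positions,
    }
    return genome, truth


def _emit_cox1(spec: SimulationSpec, species: str, cds: str, strand: str,
               positions: list[int], rng: np.random.Generator, emit,
               region: dict[str, int]):
    """Emit cox1 with introns at the given coding positions (1-based nt).

    An intron is inserted after coding position p; each intron carries a
    planted internal ORF so intron uORF scanning has a recoverable truth.
    """
    bounds = [0] + list(positions) + [len(cds)]
    exons = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = []
    for pos in positions:
        itype = spec.intron_plan[pos][0]
        flank = spec.intron_length // 2
        core = random_cds(spec.uorf_codons, rng, profile="uorf")
        iseq = (random_sequence(flank, rng, spec.base_freqs) + core
                + random_sequence(flank, rng, spec.base_freqs))
        introns.append((iseq, itype, flank, len(core)))
    # genomic layout of the gene (coding orientation)
    pieces = []
    for i, ex in enumerate(exons):
        pieces.append(("exon", ex, None))
        if i < len(introns):
            pieces.append(("intron",) + (introns[i][0],) + (introns[i][1:],))
    if strand == "-":
        pieces = [(kind, reverse_complement(seq), meta)
                  for kind, seq, meta in reversed(pieces)]
    feats = []
    exon_segments = []
    for kind, seq, meta in pieces:
        if kind == "exon":
            start = emit(seq, "core_pcg")
            exon_segments.append((start, start + len(seq)))
        else:
            itype, flank, core_len = meta
            start = emit(seq, "intron")
            # the embedded ORF is classified as uORF by region precedence
            region["intron"] -= core_len
            region["uorf"] += core_len
            feats.append(GeneFeature(kind="intron", gene="cox1", strand=strand,
                                     segments=[(start, start + len(seq))],
                                     qualifiers={"intron_type": itype}))
            # the planted intronic ORF counts as uORF under region precedence
            if strand == "+":
                u0 = start + flank
            else:
                u0 = start + len(seq) - flank - core_len
            feats.append(GeneFeature(kind="uORF", gene="cox1_orf", strand=strand,
                                     segments=[(u0, u0 + core_len)]))
    feats.append(GeneFeature(kind="CDS", gene="cox1", strand=strand,
                             segments=exon_segments))
    return feats


@dataclass
class Cohort:
    genomes: list[Mitogenome]
    truth: GroundTruth


def make_cohort(spec: SimulationSpec | None = None) -> Cohort:
    """One annotated genome per tree leaf, plus the full ground-truth bundle."""
    spec = spec or SimulationSpec()
    gene_seqs, truth = simulate_alignment_on_tree(spec)
    tree = _parse_tree(spec.tree)
    species_list = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 777]))
    genomes = []
    for species in species_list:
        genome, g_truth = assemble_mitogenome(spec, species, gene_seqs, rng)
        genomes.append(genome)
        truth.gene_orders[species] = g_truth["gene_order"]
        truth.repeat_loci[species] = g_truth["repeats"]
        truth.region_lengths[species] = g_truth["region_lengths"]
    return Cohort(genomes=genomes, truth=truth)


def spec_with(seed: int, **overrides) -> SimulationSpec:
    return replace(SimulationSpec(seed=seed), **overrides)
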