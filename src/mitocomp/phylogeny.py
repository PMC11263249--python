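"""Concatenated datasets, neighbor-joining trees, bootstrap, parsimony.

Five dataset kinds are built from per-gene codon alignments: PCG (14
conserved protein-coding genes concatenated), PCG12 (1st+2nd codon
positions), PCGR and PCG12R (with the rnl/rns rRNA alignments appended),
and AA (translated concatenate).  Trees are inferred by canonical
neighbor joining on K2P (nucleotide) or Poisson-corrected p (amino acid)
distances, with nonparametric bootstrap support and Fitch parsimony
scoring for topology comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .align import Msa
from .genome_io import CODE4, CONSERVED_PCGS, RRNA_GENES, GeneticCode

DATASET_KINDS = ("PCG", "PCG12", "PCGR", "PCG12R", "AA")


@dataclass
class Supermatrix:
    kind: str
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)
    alphabet: str = "dna"

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> list[str]:
        return list(self.rows)


def build_supermatrix(per_gene_msas: dict[str, Msa], dataset_kind: str,
                      code: GeneticCode = CODE4,
                      pcg_markers: tuple[str, ...] = CONSERVED_PCGS,
                      ) -> Supermatrix:
    """Concatenate per-gene alignments into one of the five dataset kinds.

    Species missing a marker are padded with gaps for that partition.
    """
    if dataset_kind not in DATASET_KINDS:
        raise ValueError(f"unknown dataset kind {dataset_kind!r}")
    species = sorted({sp for msa in per_gene_msas.values() for sp in msa.rows})
    markers = [m for m in pcg_markers if m in per_gene_msas]
    rrnas = [m for m in RRNA_GENES if m in per_gene_msas]

    def block(msa: Msa, transform=None) -> dict[str, str]:
        L = msa.length
        out = {}
        for sp in species:
            row = msa.rows.get(sp, "-" * L)
            out[sp] = transform(row) if transform else row
        return out

    def pos12(row: str) -> str:
        return "".join(ch for i, ch in enumerate(row) if i % 3 != 2)

    def to_aa(row: str) -> str:
        aas = []
        for i in range(0, len(row) - len(row) % 3, 3):
            codon = row[i:i + 3]
            if codon == "---":
                aas.append("-")
            elif set(codon) <= set("ACGT"):
                aas.append(code.codons[codon])
            else:
                aas.append("X")
        return "".join(aas)

    parts: list[tuple[str, dict[str, str]]] = []
    if dataset_kind == "AA":
        for m in markers:
            parts.append((m, block(per_gene_msas[m], to_aa)))
        alphabet = "aa"
    else:
        transform = pos12 if dataset_kind in ("PCG12", "PCG12R") else None
        for m in markers:
            parts.append((m, block(per_gene_msas[m], transform)))
        if dataset_kind in ("PCGR", "PCG12R"):
            for m in rrnas:
                parts.append((m, block(per_gene_msas[m])))
        alphabet = "dna"

    rows = {sp: [] for sp in species}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for marker, blk in parts:
        L = len(next(iter(blk.values())))
        partitions[marker] = (offset, offset + L)
        offset += L
        for sp in species:
            rows[sp].append(blk[sp])
    return Supermatrix(kind=dataset_kind,
                       rows={sp: "".join(chunks) for sp, chunks in rows.items()},
                       partitions=partitions, alphabet=alphabet)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _seq_array(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    names = sorted(rows)
    arr = np.frombuffer("".join(rows[n] for n in names).encode(), dtype="S1")
    return names, arr.reshape(len(names), -1)


def k2p_matrix_from_rows(rows: dict[str, str]) -> pd.DataFrame:
    """Pairwise-deletion K2P distance matrix (saturated pairs -> NaN)."""
    names, arr = _seq_array(rows)
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    purine = np.isin(arr, np.array([b"A", b"G"]))
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            m = int(ok.sum())
            if m == 0:
                mat[i, j] = mat[j, i] = math.nan
                continue
            diff = (arr[i] != arr[j]) & ok
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            P, Q = ts / m, tv / m
            w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
            d = (-0.5 * math.log(w1) - 0.25 * math.log(w2)) if (w1 > 0 and w2 > 0) else math.nan
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def p_distance_matrix(rows: dict[str, str], poisson: bool = True) -> pd.DataFrame:
    """Pairwise-deletion p-distance (amino acid), Poisson-corrected by default."""
    names, arr = _seq_array(rows)
    valid = (arr != b"-") & (arr != b"X") & (arr != b"?")
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            m = int(ok.sum())
            if m == 0:
                mat[i, j] = mat[j, i] = math.nan
                continue
            p = float(((arr[i] != arr[j]) & ok).sum()) / m
            if poisson:
                d = -math.log(1 - p) if p < 1 else math.nan
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Canonical neighbor joining; ties broken by lexicographic species pair.

    Negative branch lengths are clamped to zero.  Returns an unrooted
    dendropy Tree.
    """
    D = distances.copy()
    if list(D.index) != list(D.columns):
        raise ValueError("distance matrix index and columns must match")
    if not np.allclose(D.values, D.values.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D.values).any():
        raise ValueError("distance matrix contains missing values")
    labels = {name: f"'{name}'" for name in D.index}  # node id -> newick fragment
    names = list(D.index)
    if len(names) < 2:
        raise ValueError("need at least 2 taxa")

    def clamp(x: float) -> float:
        return max(x, 0.0)

    while len(names) > 3:
        n = len(names)
        dvals = D.loc[names, names].to_numpy()
        r = dvals.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * dvals[i, j] - r[i] - r[j]
                key = (q, str(names[i]), str(names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        a, b = names[i], names[j]
        dij = dvals[i, j]
        va = clamp(0.5 * dij + (r[i] - r[j]) / (2 * (n - 2)))
        vb = clamp(dij - va) if dij - va > 0 else clamp(0.5 * dij + (r[j] - r[i]) / (2 * (n - 2)))
        new = f"({labels[a]}:{va:.10f},{labels[b]}:{vb:.10f})"
        new_id = f"__nj{len(labels)}"
        labels[new_id] = new
        d_new = {}
        for m in names:
            if m in (a, b):
                continue
            d_new[m] = clamp(0.5 * (D.loc[a, m] + D.loc[b, m] - dij))
        names = [m for m in names if m not in (a, b)] + [new_id]
        D = D.drop(index=[a, b], columns=[a, b])
        D.loc[new_id, new_id] = 0.0
        for m, v in d_new.items():
            D.loc[new_id, m] = D.loc[m, new_id] = v
        D = D.loc[names, names]

    if len(names) == 2:
        a, b = names
        d = D.loc[a, b]
        newick = f"({labels[a]}:{clamp(d / 2):.10f},{labels[b]}:{clamp(d / 2):.10f});"
    else:
        a, b, c = names
        dab, dac, dbc = D.loc[a, b], D.loc[a, c], D.loc[b, c]
        va = clamp((dab + dac - dbc) / 2)
        vb = clamp((dab + dbc - dac) / 2)
        vc = clamp((dac + dbc - dab) / 2)
        newick = (f"({labels[a]}:{va:.10f},{labels[b]}:{vb:.10f},"
                  f"{labels[c]}:{vc:.10f});")
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as leaf-name sets, normalized to the side
    not containing the lexicographically first leaf."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    full = set(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            splits.add(frozenset(side))
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    s1, s2 = tree_splits(t1), tree_splits(t2)
    return len(s1 ^ s2)


def is_monophyletic(tree: dendropy.Tree, taxa: set[str]) -> bool:
    """True iff some edge bipartition isolates exactly ``taxa`` (either side)."""
    if not taxa:
        raise ValueError("empty taxa set")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not taxa <= leaves:
        raise ValueError(f"taxa not in tree: {sorted(taxa - leaves)}")
    if taxa == leaves or len(taxa) == 1 or len(taxa) == len(leaves) - 1:
        return True
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if side == taxa or (leaves - side) == taxa:
            return True
    return False


def distance_matrix_for(sm: Supermatrix) -> pd.DataFrame:
    if sm.alphabet == "aa":
        return p_distance_matrix(sm.rows)
    return k2p_matrix_from_rows(sm.rows)


def bootstrap_support(sm: Supermatrix, n_replicates: int = 100,
                      seed: int = 0) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree of the supermatrix with bootstrap split supports (percent).

    Columns are resampled with replacement; the support of each split of the
    full-data tree is the percentage of replicate trees containing it.
    Internal node labels of the returned tree carry the supports.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(distance_matrix_for(sm))
    target_splits = tree_splits(tree)
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    names = sorted(sm.rows)
    arr = np.frombuffer("".join(sm.rows[n] for n in names).encode(), dtype="S1")
    arr = arr.reshape(len(names), -1)
    L = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_rows = {n: arr[i, cols].tobytes().decode() for i, n in enumerate(names)}
        try:
            rep_tree = nj_tree(
                p_distance_matrix(rep_rows) if sm.alphabet == "aa"
                else k2p_matrix_from_rows(rep_rows))
        except ValueError:  # saturated replicate
            continue
        rep_splits = tree_splits(rep_tree)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    _annotate_supports(tree, supports)
    return tree, supports


def _annotate_supports(tree: dendropy.Tree, supports: dict[frozenset[str], float]) -> None:
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref, full = leaves[0], set(leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = full - side
        key = frozenset(side)
        if key in supports:
            node.label = f"{supports[key]:.0f}"


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

_DNA_BITS = {b"A": 1, b"C": 2, b"G": 4, b"T": 8}


def parsimony_score(tree: dendropy.Tree, msa: Msa) -> int:
    """Fitch small-parsimony score of an alignment on a tree topology.

    Gap/ambiguous characters are treated as fully ambiguous states.  For
    amino-acid alignments each distinct residue is its own state.
    """
    tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if tree_leaves != set(msa.rows):
        raise ValueError("tree and alignment leaf sets differ")
    L = msa.length
    if msa.alphabet == "dna":
        full = 15
        def bits_of(row: str) -> np.ndarray:
            a = np.frombuffer(row.encode(), dtype="S1")
            out = np.full(L, full, dtype=np.int64)
            for ch, bit in _DNA_BITS.items():
                out[a == ch] = bit
            return out
    else:
        symbols = sorted({ch for row in msa.rows.values() for ch in row
                          if ch not in "-X?"})
        full = (1 << len(symbols)) - 1 if symbols else 1
        sym_bit = {ch: 1 << i for i, ch in enumerate(symbols)}
        def bits_of(row: str) -> np.ndarray:
            return np.array([sym_bit.get(ch, full) for ch in row], dtype=np.int64)

    # root arbitrarily at an internal node; Fitch score is root-invariant
    rooted = tree.clone(depth=1)
    score = np.zeros(L, dtype=np.int64)

    def post(node) -> np.ndarray:
        if node.is_leaf():
            return bits_of(msa.rows[node.taxon.label])
        child_sets = [post(ch) for ch in node.child_nodes()]
        acc = child_sets[0]
        for cs in child_sets[1:]:
            inter = acc & cs
            union_needed = inter == 0
            score[union_needed] += 1
            acc = np.where(union_needed, acc | cs, inter)
        return acc

    post(rooted.seed_node)
    return int(score.sum())


def write_phylip(rows: dict[str, str], path) -> None:
    """Relaxed-PHYLIP export of an alignment or supermatrix."""
    names = list(rows)
    L = len(rows[names[0]]) if names else 0
    with open(path, "w") as fh:
        fh.write(f" {len(names)} {L}\n")
        for n in names:
            fh.write(f"{n.replace(' ', '_')}  {rows[n]}\n")


def write_alignment_fasta(rows: dict[str, str], path) -> None:
    from .genome_io import write_fasta
    write_fasta(list(rows.items()), path)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               suppress_internal_node_labels=False,
               unquoted_underscores=True)


def read_newick(path_or_string) -> dendropy.Tree:
    s = str(path_or_string)
    if s.strip().startswith("("):
        t = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    else:
        t = dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)
    t.is_rooted = False
    return t
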