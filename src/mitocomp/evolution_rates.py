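"""Pairwise K2P distances and Nei-Gojobori (1986) Ka/Ks.

K2P separates transition (P) and transversion (Q) proportions:
``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``.

NG86 counts synonymous (S) and nonsynonymous (N) sites per codon under the
active genetic code, classifies observed differences by averaging over all
shortest substitution pathways, and applies the Jukes-Cantor correction
``K = -3/4 ln(1 - 4/3 p)`` to the proportions pS and pN.  Mutations that
would create a stop codon are excluded from site counting and pathways
through stop codons are discarded (unless every pathway is blocked).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .genome_io import CODE4, GeneticCode

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass
class PairwiseDistance:
    gene: str
    pair: tuple[str, str]
    P: float
    Q: float
    d_k2p: float          # NaN when saturated
    sites_compared: int
    saturated: bool = False


def k2p_distance(seq_a: str, seq_b: str, gene: str = "",
                 pair: tuple[str, str] = ("a", "b")) -> PairwiseDistance:
    """K2P distance of two aligned sequences (pairwise deletion of gaps/N)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid_chars = np.array([c.encode() for c in "ACGT"])
    ok = np.isin(a, valid_chars) & np.isin(b, valid_chars)
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        return PairwiseDistance(gene, pair, math.nan, math.nan, math.nan, 0, False)
    diff = a != b
    purine = np.isin(a, np.array([b"A", b"G"])) == np.isin(b, np.array([b"A", b"G"]))
    ts = int(np.sum(diff & purine))
    tv = int(np.sum(diff & ~purine))
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return PairwiseDistance(gene, pair, P, Q, math.nan, n, saturated=True)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseDistance(gene, pair, P, Q, d, n)


def k2p_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Symmetric K2P distance matrix over aligned sequences."""
    names = list(seqs)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            d = k2p_distance(seqs[x], seqs[y]).d_k2p
            mat.loc[x, y] = mat.loc[y, x] = d
    return mat


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsRecord:
    gene: str
    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float          # NaN when Ks == 0 or saturated
    codons_compared: int
    saturated: bool = False


def _syn_sites_uncached(codon: str, code: GeneticCode) -> float:
    """Synonymous site count of one codon (0..3, NG86 convention).

    At each position the fraction of single-base changes that are synonymous
    is computed over non-nonsense changes; the three fractions are summed.
    """
    aa = code.codons[codon]
    s = 0.0
    for pos in range(3):
        syn = nonsense = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            mut_aa = code.codons[mut]
            if mut_aa == "*":
                nonsense += 1
            elif mut_aa == aa:
                syn += 1
        denom = 3 - nonsense
        if denom > 0:
            s += syn / denom
    return s


@lru_cache(maxsize=256)
def _syn_sites(codon: str, table_id: int) -> float:
    return _syn_sites_uncached(codon, GeneticCode.from_table(table_id))


def _pathway_changes(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, blocked = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.codons[nxt] == "*" and nxt != c2:
                blocked = True
            if code.codons[nxt] == code.codons[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in results if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_kaks(seq_a: str, seq_b: str, code: GeneticCode = CODE4,
              gene: str = "", pair: tuple[str, str] = ("a", "b")) -> KaKsRecord:
    """NG86 Ka/Ks for a codon-aligned in-frame pair.

    Codons containing a gap, N, or a stop (in either sequence) are dropped
    entirely.  Site counts are averaged over the two sequences.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be divisible by 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    S = N = Sd = Nd = 0.0
    ncod = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if not (set(ca) <= _VALID and set(cb) <= _VALID):
            continue
        if code.codons[ca] == "*" or code.codons[cb] == "*":
            continue
        ncod += 1
        sa = _syn_sites(ca, code.table_id)
        sb = _syn_sites(cb, code.table_id)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
        sd, nd = _pathway_changes(ca, cb, code)
        Sd += sd
        Nd += nd
    if ncod == 0:
        nan = math.nan
        return KaKsRecord(gene, pair, 0, 0, 0, 0, nan, nan, nan, nan, nan, 0)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks, Ka = _jc(pS), _jc(pN)
    saturated = math.isnan(Ks) or math.isnan(Ka)
    ratio = math.nan
    if not saturated and Ks > 0:
        ratio = Ka / Ks
    return KaKsRecord(gene, pair, S, N, Sd, Nd, pS, pN, Ks, Ka, ratio,
                      ncod, saturated)


def per_gene_summary(k2p_records: list[PairwiseDistance],
                     kaks_records: list[KaKsRecord]) -> pd.DataFrame:
    """Per-gene means over all species pairs (missing values excluded)."""
    rows: dict[str, dict[str, list[float]]] = {}
    for r in k2p_records:
        rows.setdefault(r.gene, {"k2p": [], "ka": [], "ks": [], "ratio": []})
        if not math.isnan(r.d_k2p):
            rows[r.gene]["k2p"].append(r.d_k2p)
    for r in kaks_records:
        rows.setdefault(r.gene, {"k2p": [], "ka": [], "ks": [], "ratio": []})
        if not math.isnan(r.Ka):
            rows[r.gene]["ka"].append(r.Ka)
        if not math.isnan(r.Ks):
            rows[r.gene]["ks"].append(r.Ks)
        if not math.isnan(r.ratio):
            rows[r.gene]["ratio"].append(r.ratio)
    out = []
    for gene, vals in sorted(rows.items()):
        out.append({
            "gene": gene,
            "mean_k2p": float(np.mean(vals["k2p"])) if vals["k2p"] else math.nan,
            "mean_ka": float(np.mean(vals["ka"])) if vals["ka"] else math.nan,
            "mean_ks": float(np.mean(vals["ks"])) if vals["ks"] else math.nan,
            "mean_kaks": float(np.mean(vals["ratio"])) if vals["ratio"] else math.nan,
            "n_pairs_k2p": len(vals["k2p"]),
        })
    return pd.DataFrame(out)
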