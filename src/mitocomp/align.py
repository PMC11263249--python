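"""Multiple sequence alignment: pairwise affine-gap alignment plus a
deterministic star-progressive merge.

The center sequence (smallest summed k-mer distance to all others) is
aligned pairwise against every other sequence and the pairwise gaps are
threaded into a single MSA ("once a gap, always a gap").  Codon mode aligns
translations and expands each amino-acid column back to three nucleotide
columns, so gaps always appear in multiples of three.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from Bio import Align

from .genome_io import CODE4, GeneticCode

GAP = "-"

# alignment scores (nucleotide): match +1, mismatch -1, gap open -2, extend -1
NT_SCORES = {"match": 1.0, "mismatch": -1.0, "open": -2.0, "extend": -1.0}
AA_SCORES = {"match": 2.0, "mismatch": -1.0, "open": -5.0, "extend": -1.0}


@dataclass
class Msa:
    marker: str
    rows: dict[str, str]
    alphabet: str = "dna"  # 'dna' | 'aa'

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError(f"{self.marker}: unequal row lengths {lens}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.rows.values())


def _make_aligner(scores: dict[str, float]) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scores["match"]
    al.mismatch_score = scores["mismatch"]
    al.open_gap_score = scores["open"]
    al.extend_gap_score = scores["extend"]
    return al


def pairwise_global(a: str, b: str, scores: dict[str, float] | None = None,
                    ) -> tuple[str, str, float]:
    """Best global affine-gap alignment of two sequences: (row_a, row_b, score)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    al = _make_aligner(scores or NT_SCORES)
    aln = al.align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def _kmer_profile(seq: str, k: int = 6) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        prof[w] = prof.get(w, 0) + 1
    return prof


def kmer_distance(a: str, b: str, k: int = 6) -> float:
    pa, pb = _kmer_profile(a, k), _kmer_profile(b, k)
    shared = sum(min(pa[w], pb.get(w, 0)) for w in pa)
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom if denom > 0 else 1.0


def _ins_counts(center_row: str) -> list[int]:
    """Gap run lengths before each center residue (+ trailing run)."""
    ncenter = len(center_row.replace(GAP, ""))
    ins = [0] * (ncenter + 1)
    pos = 0
    for ch in center_row:
        if ch == GAP:
            ins[pos] += 1
        else:
            pos += 1
    return ins


def _thread(center: str, other_rows: dict[str, tuple[str, str]]) -> dict[str, str]:
    """Merge pairwise center-alignments into one MSA (gap threading)."""
    ncenter = len(center)
    master = [0] * (ncenter + 1)
    parsed = {}
    for name, (crow, srow) in other_rows.items():
        ins = _ins_counts(crow)
        parsed[name] = (crow, srow, ins)
        for i, g in enumerate(ins):
            master[i] = max(master[i], g)
    rows: dict[str, str] = {}
    # center row
    out = []
    for i in range(ncenter + 1):
        out.append(GAP * master[i])
        if i < ncenter:
            out.append(center[i])
    center_aligned = "".join(out)
    for name, (crow, srow, ins) in parsed.items():
        out, pos, j = [], 0, 0
        chunk: list[str] = []
        for ch_c, ch_s in zip(crow, srow):
            if ch_c == GAP:
                chunk.append(ch_s)
            else:
                out.append("".join(chunk) + GAP * (master[pos] - len(chunk)))
                out.append(ch_s)
                chunk = []
                pos += 1
        out.append("".join(chunk) + GAP * (master[ncenter] - len(chunk)))
        rows[name] = "".join(out)
    return center_aligned, rows


def align_progressive(seqs: dict[str, str], alphabet: str = "dna",
                      marker: str = "", scores: dict[str, float] | None = None,
                      ) -> Msa:
    """Star-progressive MSA around the k-mer-central sequence (deterministic)."""
    if any(not s for s in seqs.values()):
        raise ValueError("empty sequence in alignment input")
    names = sorted(seqs)
    if len(names) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if scores is None:
        scores = NT_SCORES if alphabet == "dna" else AA_SCORES
    if len({seqs[n] for n in names}) == 1:
        return Msa(marker=marker, rows={n: seqs[n] for n in names}, alphabet=alphabet)
    # center: minimal summed k-mer distance, ties broken by name
    sums = {n: sum(kmer_distance(seqs[n], seqs[m]) for m in names if m != n)
            for n in names}
    center_name = min(names, key=lambda n: (sums[n], n))
    center = seqs[center_name]
    pair_rows = {}
    for n in names:
        if n == center_name:
            continue
        crow, srow, _ = pairwise_global(center, seqs[n], scores)
        pair_rows[n] = (crow, srow)
    center_aligned, rows = _thread(center, pair_rows)
    rows[center_name] = center_aligned
    return Msa(marker=marker, rows={n: rows[n] for n in names}, alphabet=alphabet)


def align_codon(seqs: dict[str, str], marker: str = "",
                code: GeneticCode = CODE4) -> Msa:
    """Protein-guided codon alignment: gaps only in multiples of 3.

    Trailing partial codons are trimmed; stop/ambiguous codons translate to
    placeholder symbols and are aligned with match/mismatch scoring.
    """
    trimmed = {n: s[: len(s) - len(s) % 3] for n, s in seqs.items()}
    prots = {}
    for n, s in trimmed.items():
        aa = "".join(code.codons.get(s[i:i + 3], "X") for i in range(0, len(s), 3))
        prots[n] = aa
    prot_msa = align_progressive(prots, alphabet="aa", marker=marker)
    rows = {}
    for n, arow in prot_msa.rows.items():
        nt, j = [], 0
        for ch in arow:
            if ch == GAP:
                nt.append(GAP * 3)
            else:
                nt.append(trimmed[n][3 * j: 3 * j + 3])
                j += 1
        rows[n] = "".join(nt)
    return Msa(marker=marker, rows=rows, alphabet="dna")


def trim_columns(msa: Msa, max_gap_fraction: float = 0.5,
                 codon: bool = False) -> Msa:
    """Drop columns whose gap fraction exceeds the threshold.

    In codon mode a whole codon column triple is dropped when any of its
    three columns fails the filter.
    """
    nrow = len(msa.rows)
    L = msa.length
    rows_arr = np.frombuffer("".join(msa.rows.values()).encode(), dtype="S1")
    rows_arr = rows_arr.reshape(nrow, L)
    gap_frac = np.mean(rows_arr == b"-", axis=0)
    keep = gap_frac <= max_gap_fraction
    if codon:
        L3 = L - L % 3
        cod = keep[:L3].reshape(-1, 3).all(axis=1)
        keep = np.repeat(cod, 3)
        if L % 3:
            keep = np.concatenate([keep, np.zeros(L % 3, dtype=bool)])
    if not keep.any():
        raise ValueError("trimming removed every column")
    idx = np.flatnonzero(keep)
    new_rows = {n: "".join(s[i] for i in idx) for n, s in msa.rows.items()}
    return Msa(marker=msa.marker, rows=new_rows, alphabet=msa.alphabet)
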