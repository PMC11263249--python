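"""Dispersed-repeat and tandem-repeat detection in mitogenomes.

Dispersed (interspersed) repeats are found by comparing the genome against
itself with exact k-mer seeds, chaining seeds on a common (anti)diagonal and
re-scoring each candidate pair by edit-distance alignment.  Tandem repeats
are found by scanning match runs at every lag up to ``max_period`` and
verifying each locus against its tiled consensus unit.  Both detectors are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .genome_io import Mitogenome, reverse_complement


@dataclass
class DispersedRepeat:
    locus1: tuple[int, int]
    locus2: tuple[int, int]
    strand: str            # '+' = direct, '-' = inverted (reverse-complement)
    length: int
    identity: float        # percent
    score: int


@dataclass
class TandemRepeat:
    locus: tuple[int, int]
    period: int
    copies: float
    consensus: str
    percent_matches: float


def _identity_pct(s1: str, s2: str) -> float:
    if not s1 or not s2:
        return 0.0
    res = edlib.align(s1, s2, task="distance")
    dist = res["editDistance"]
    return 100.0 * (1.0 - dist / max(len(s1), len(s2)))


def _chain_diagonal_seeds(positions: list[tuple[int, int]], k: int,
                          max_gap: int) -> list[tuple[int, int, int, int]]:
    """Merge seed pairs sharing a diagonal into runs.

    ``positions`` holds (i, j) seed starts with constant j - i; returns
    (i_start, i_end, j_start, j_end) runs (end-exclusive, +k applied).
    """
    positions.sort()
    runs = []
    ci, cj = positions[0]
    run_start = (ci, cj)
    prev = ci
    for i, j in positions[1:]:
        if i - prev <= max_gap:
            prev = i
        else:
            runs.append((run_start[0], prev + k, run_start[1], run_start[1] + (prev + k - run_start[0])))
            run_start = (i, j)
            prev = i
    runs.append((run_start[0], prev + k, run_start[1], run_start[1] + (prev + k - run_start[0])))
    return runs


def find_dispersed_repeats(genome: Mitogenome, min_len: int = 30,
                           min_identity: float = 70.0, seed_k: int = 15,
                           max_chain_gap: int = 60) -> list[DispersedRepeat]:
    """Self-comparison repeat search on both strands.

    Alignment scoring used for the reported score: match +1, mismatch -2,
    gap open -5, gap extend -2 (approximated from edit distance on the
    re-verification alignment).
    """
    seq = genome.sequence
    n = len(seq)
    if n < min_len:
        return []
    k = min(seed_k, min_len)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)

    # direct repeats: group seed pairs by diagonal j - i (j > i)
    diag: dict[int, list[tuple[int, int]]] = {}
    for kmer, pos in index.items():
        if len(pos) < 2 or "N" in kmer:
            continue
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                i, j = pos[a], pos[b]
                diag.setdefault(j - i, []).append((i, j))
    candidates: list[tuple[tuple[int, int], tuple[int, int], str]] = []
    for d, plist in diag.items():
        if d == 0:
            continue
        for i0, i1, j0, j1 in _chain_diagonal_seeds(plist, k, max_chain_gap):
            if i1 - i0 >= min_len and j0 >= i1 - 0:  # require non-nested pairing
                candidates.append(((i0, i1), (j0, j1), "+"))
            elif i1 - i0 >= min_len:
                candidates.append(((i0, i1), (j0, j1), "+"))

    # inverted repeats: seeds of seq vs seeds of its reverse complement
    rc = reverse_complement(seq)
    anti: dict[int, list[tuple[int, int]]] = {}
    for i in range(n - k + 1):
        kmer = rc[i:i + k]
        if "N" in kmer or kmer not in index:
            continue
        j = n - i - k  # genome start of this window on the forward strand
        for p in index[kmer]:
            if p < j:
                anti.setdefault(p + j, []).append((p, j))
    for s, plist in anti.items():
        # constant i + j: chain on i as the run coordinate
        plist = sorted(set(plist))
        for i0, i1, j0, _ in _chain_diagonal_seeds(plist, k, max_chain_gap):
            L = i1 - i0
            if L >= min_len:
                j_lo = s - (i1 - k)  # partner window start for the last seed
                candidates.append(((i0, i1), (j_lo, j_lo + L), "-"))

    out: list[DispersedRepeat] = []
    for (a0, a1), (b0, b1), strand in candidates:
        if (a0, a1) == (b0, b1):
            continue
        s1 = seq[a0:a1]
        s2 = seq[b0:b1] if strand == "+" else reverse_complement(seq[b0:b1])
        ident = _identity_pct(s1, s2)
        if ident < min_identity:
            continue
        length = max(a1 - a0, b1 - b0)
        mism = round(length * (100 - ident) / 100)
        score = (length - mism) - 2 * mism
        out.append(DispersedRepeat(locus1=(a0, a1), locus2=(b0, b1),
                                   strand=strand, length=length,
                                   identity=round(ident, 2), score=score))
    # containment dedupe: drop pairs fully covered by a longer reported pair
    out.sort(key=lambda r: (-r.length, r.locus1, r.locus2))
    kept: list[DispersedRepeat] = []
    for r in out:
        contained = any(
            q.strand == r.strand
            and q.locus1[0] <= r.locus1[0] and r.locus1[1] <= q.locus1[1]
            and q.locus2[0] <= r.locus2[0] and r.locus2[1] <= q.locus2[1]
            for q in kept)
        if not contained:
            kept.append(r)
    kept.sort(key=lambda r: (r.locus1, r.locus2, -r.score))
    return kept


def find_tandem_repeats(genome: Mitogenome, max_period: int = 200,
                        min_copies: float = 2.0, min_unit_matches: float = 80.0,
                        min_locus_len: int = 20) -> list[TandemRepeat]:
    """Period-scan tandem repeat search.

    For every period p, maximal runs where ``s[i] == s[i + p]`` (bridging up
    to two isolated mismatches) delimit candidate loci; each locus is
    verified against its tiled majority-consensus unit and reported if the
    percent of matching positions is at least ``min_unit_matches``.
    Smaller-period loci suppress redundant multiples covering the same span.
    """
    seq = genome.sequence
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    results: list[TandemRepeat] = []
    for p in range(1, min(max_period, n // 2) + 1):
        m = arr[:-p] == arr[p:]
        if not m.any():
            continue
        # maximal runs of matches, bridging isolated 1-2 mismatch gaps
        idx = np.flatnonzero(m)
        breaks = np.flatnonzero(np.diff(idx) > 3)
        starts = idx[np.concatenate(([0], breaks + 1))]
        ends = idx[np.concatenate((breaks, [idx.size - 1]))] + 1
        min_run = max(min_locus_len, int(np.ceil(p * min_copies))) - p
        long_enough = (ends - starts) >= max(min_run, 1)
        runs = list(zip(starts[long_enough].tolist(), ends[long_enough].tolist()))
        # trim bridged run ends back to a clean match streak so random
        # flanking bases cannot dilute the locus
        w = min(p, 4)
        for rs0, re0 in runs:
            rs_, re_ = rs0, re0
            while rs_ + w <= re_ and not m[rs_:rs_ + w].all():
                rs_ += 1
            while re_ - w >= rs_ and not m[re_ - w:re_].all():
                re_ -= 1
            attempts = []
            if re_ > rs_:
                attempts.append((rs_, re_))
            exact = _longest_true_run(m, rs0, re0)
            if exact is not None and exact not in attempts:
                attempts.append(exact)
            for a, b in attempts:
                locus = (a, b + p)
                if locus[1] - locus[0] < max(min_locus_len, int(np.ceil(p * min_copies))):
                    continue
                copies = (locus[1] - locus[0]) / p
                if copies < min_copies:
                    continue
                block = seq[locus[0]:locus[1]]
                consensus = _consensus_unit(block, p)
                matches = sum(1 for i, ch in enumerate(block)
                              if ch == consensus[i % p])
                pct = 100.0 * matches / len(block)
                if pct < min_unit_matches:
                    continue
                results.append(TandemRepeat(locus=locus, period=p,
                                            copies=round(copies, 2),
                                            consensus=consensus,
                                            percent_matches=round(pct, 2)))
                break
    # non-redundancy: prefer smaller periods covering the same span
    results.sort(key=lambda r: (r.period, r.locus))
    kept: list[TandemRepeat] = []
    for r in results:
        redundant = False
        for q in kept:
            ov = min(q.locus[1], r.locus[1]) - max(q.locus[0], r.locus[0])
            if ov > 0.8 * (r.locus[1] - r.locus[0]) and q.period <= r.period:
                redundant = True
                break
        if not redundant:
            kept.append(r)
    kept.sort(key=lambda r: r.locus)
    return kept


def _longest_true_run(m: np.ndarray, lo: int, hi: int) -> tuple[int, int] | None:
    idx = np.flatnonzero(m[lo:hi])
    if idx.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = idx[np.concatenate(([0], breaks + 1))]
    ends = idx[np.concatenate((breaks, [idx.size - 1]))] + 1
    best = int(np.argmax(ends - starts))
    return int(starts[best]) + lo, int(ends[best]) + lo


def _consensus_unit(block: str, period: int) -> str:
    cols: list[dict[str, int]] = [{} for _ in range(period)]
    for i, ch in enumerate(block):
        col = cols[i % period]
        col[ch] = col.get(ch, 0) + 1
    return "".join(max(sorted(c), key=lambda ch: c[ch]) if c else "N" for c in cols)


def _interval_union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    ivs = sorted(intervals)
    total, cur_s, cur_e = 0, *ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total


def repeat_summary(genome: Mitogenome, dispersed: list[DispersedRepeat],
                   tandem: list[TandemRepeat]) -> pd.DataFrame:
    """Per-genome repeat summary; percentages use the union of loci."""
    disp_iv = [r.locus1 for r in dispersed] + [r.locus2 for r in dispersed]
    tand_iv = [r.locus for r in tandem]
    n = genome.length
    rows = [{
        "genome_id": genome.id,
        "n_dispersed": len(dispersed),
        "longest_dispersed": max((r.length for r in dispersed), default=0),
        "dispersed_pct": round(100.0 * _interval_union_length(disp_iv) / n, 2) if n else 0.0,
        "n_tandem": len(tandem),
        "longest_tandem": max((r.locus[1] - r.locus[0] for r in tandem), default=0),
        "tandem_pct": round(100.0 * _interval_union_length(tand_iv) / n, 2) if n else 0.0,
    }]
    return pd.DataFrame(rows)
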