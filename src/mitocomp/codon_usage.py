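"""Codon counting, RSCU, amino-acid usage, and PCA of RSCU vectors.

RSCU (relative synonymous codon usage) of codon *j* in a synonymous family
of size *k* is the observed count divided by the family mean, so a uniformly
used family has RSCU 1 for every member.  Under translation table 4 the stop
family is {TAA, TAG} (TGA encodes tryptophan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .genome_io import CODE4, GeneticCode

ALL_CODONS = tuple(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG")


@dataclass
class CodonUsageTable:
    scope: str
    counts: dict[str, int]
    rscu: dict[str, float]
    aa_totals: dict[str, int]
    start_codons: dict[str, str] = field(default_factory=dict)
    stop_codons: dict[str, str] = field(default_factory=dict)


def count_codons(cds_set: Sequence[str] | Mapping[str, str],
                 code: GeneticCode = CODE4, scope: str = "core-concatenate",
                 ) -> CodonUsageTable:
    """Count frame-0 codons over a set of CDSs.

    Accepts a list of sequences or a gene->sequence mapping (the mapping form
    also records the start and stop codon of each gene).  Codons containing N
    are skipped.
    """
    if isinstance(cds_set, Mapping):
        items = list(cds_set.items())
    else:
        items = [(f"seq{i}", s) for i, s in enumerate(cds_set)]
    counts = {c: 0 for c in ALL_CODONS}
    starts: dict[str, str] = {}
    stops: dict[str, str] = {}
    for name, seq in items:
        seq = seq.upper()
        if len(seq) < 3:
            raise ValueError(f"{name}: CDS shorter than one codon")
        codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
        for codon in codons:
            if codon in counts:
                counts[codon] += 1
        starts[name] = codons[0]
        if code.is_stop(codons[-1]):
            stops[name] = codons[-1]
    return CodonUsageTable(scope=scope, counts=counts,
                           rscu=rscu(counts, code), aa_totals=aa_usage(counts, code),
                           start_codons=starts, stop_codons=stops)


def rscu(counts: Mapping[str, int], code: GeneticCode = CODE4,
         include_stops: bool = True) -> dict[str, float]:
    """RSCU per codon; families with zero total get NaN for every member."""
    out: dict[str, float] = {}
    for aa, family in code.synonymous_families().items():
        if aa == "*" and not include_stops:
            for codon in family:
                out[codon] = float("nan")
            continue
        total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for codon in family:
            out[codon] = (counts.get(codon, 0) * k / total) if total else float("nan")
    return out


def aa_usage(counts: Mapping[str, int], code: GeneticCode = CODE4) -> dict[str, int]:
    """Amino-acid totals implied by codon counts; stops tallied under '*'."""
    totals: dict[str, int] = {aa: 0 for aa in code.synonymous_families()}
    for codon, n in counts.items():
        aa = code.codons.get(codon)
        if aa is not None:
            totals[aa] += n
    return totals


def codon_table_frame(table: CodonUsageTable, code: GeneticCode = CODE4) -> pd.DataFrame:
    rows = [{"codon": c, "aa": code.codons[c], "count": table.counts[c],
             "rscu": table.rscu[c]} for c in ALL_CODONS]
    return pd.DataFrame(rows)


@dataclass
class RscuPca:
    row_labels: list[str]
    codons: list[str]
    scores: np.ndarray        # rows x 2
    explained_variance_ratio: np.ndarray


def rscu_matrix(tables: Mapping[str, CodonUsageTable],
                code: GeneticCode = CODE4, include_stops: bool = False,
                impute: float = 1.0) -> pd.DataFrame:
    """Rows = scopes/species, columns = codons, values = RSCU.

    Families absent from a row are imputed to the family-neutral value 1.0
    so the matrix is complete for PCA.
    """
    fams = code.synonymous_families()
    codons = [c for aa, fam in sorted(fams.items()) for c in fam
              if (include_stops or aa != "*")]
    data = {}
    for label, tab in tables.items():
        row = [tab.rscu.get(c, float("nan")) for c in codons]
        data[label] = [impute if np.isnan(v) else v for v in row]
    return pd.DataFrame.from_dict(data, orient="index", columns=codons)


def rscu_pca(matrix: pd.DataFrame, n_components: int = 2) -> RscuPca:
    """PCA of RSCU rows (covariance of centered columns, deterministic signs).

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making scores reproducible across library versions.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("constant RSCU matrix: explained variance undefined")
    n_components = min(n_components, min(X.shape) - 0, X.shape[0] - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(scores.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
            pca.components_[j] *= -1
    return RscuPca(row_labels=list(matrix.index), codons=list(matrix.columns),
                   scores=scores[:, :2],
                   explained_variance_ratio=pca.explained_variance_ratio_)


def start_stop_table(genomes_cds: Mapping[str, Mapping[str, str]],
                     code: GeneticCode = CODE4) -> pd.DataFrame:
    """Start/stop codon per gene per species (species -> gene -> CDS)."""
    rows = []
    for species, cds_map in genomes_cds.items():
        tab = count_codons(cds_map, code, scope="per-gene")
        for gene in cds_map:
            rows.append({"species": species, "gene": gene,
                         "start_codon": tab.start_codons.get(gene, ""),
                         "stop_codon": tab.stop_codons.get(gene, "")})
    return pd.DataFrame(rows)
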