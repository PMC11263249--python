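"""End-to-end orchestration over a set of annotated mitogenomes.

Runs every analysis stage (composition, codon usage/RSCU + PCA, K2P and
Ka/Ks, repeats, cox1 Pcls, gene order + synteny, phylogeny) and writes a
TSV/Newick report bundle with a run manifest.  Stages degrade gracefully:
pairwise stages are skipped with a warning when fewer than two genomes are
supplied, and missing genes produce explicit NA rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import Msa, align_codon, align_progressive, trim_columns
from .codon_usage import count_codons, codon_table_frame, rscu_matrix, rscu_pca
from .composition import (genome_composition_table, partition_table,
                          per_gene_length_table)
from .evolution_rates import (k2p_distance, ng86_kaks, per_gene_summary)
from .gene_order import (breakpoint_matrix, extract_gene_order,
                         find_synteny_blocks, order_groups, order_table,
                         synteny_table)
from .genome_io import (CORE_PCGS, Mitogenome, extract_gene_sequence,
                        feature_table, read_genbank)
from .intron_pcl import catalog_table, cox1_pcl_analysis
from .phylogeny import (DATASET_KINDS, bootstrap_support, build_supermatrix,
                        distance_matrix_for, is_monophyletic, nj_tree,
                        write_newick)


@dataclass
class PipelineConfig:
    input_paths: list[str] = field(default_factory=list)
    output_dir: str = "mitocomp_out"
    reference_species: str | None = None    # Pcl reference; default: first genome
    dataset_kinds: tuple[str, ...] = DATASET_KINDS
    synteny_min_identity: float = 70.0
    synteny_min_len: int = 500
    trim_gap_fraction: float = 0.5
    common_pcl_fraction: float = 0.20
    repeat_min_len: int = 30
    repeat_min_identity: float = 70.0
    bootstrap_replicates: int = 100
    monophyly_taxa: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.common_pcl_fraction <= 1:
            raise ValueError("common_pcl_fraction must be in (0, 1]")
        if not 0 <= self.trim_gap_fraction <= 1:
            raise ValueError("trim_gap_fraction must be in [0, 1]")


def load_genomes(paths: list[str]) -> list[Mitogenome]:
    genomes: list[Mitogenome] = []
    for p in paths:
        genomes.extend(read_genbank(p))
    return genomes


def core_gene_sequences(genomes: list[Mitogenome]) -> dict[str, dict[str, str]]:
    """gene -> species -> spliced CDS (core genes present in each genome)."""
    out: dict[str, dict[str, str]] = {}
    for g in genomes:
        for gene in CORE_PCGS:
            feat = g.feature_for_gene(gene, kind="CDS")
            if feat is not None:
                out.setdefault(gene, {})[g.species] = extract_gene_sequence(g, feat)
    return out


def aligned_core_genes(genomes: list[Mitogenome],
                       trim_gap_fraction: float = 0.5) -> dict[str, Msa]:
    """Codon-aware alignments of the core genes plus rnl/rns alignments."""
    msas: dict[str, Msa] = {}
    gene_seqs = core_gene_sequences(genomes)
    for gene, seqs in gene_seqs.items():
        if len(seqs) < 2:
            continue
        msa = align_codon(seqs, marker=gene)
        msas[gene] = trim_columns(msa, trim_gap_fraction, codon=True)
    for rgene in ("rnl", "rns"):
        seqs = {}
        for g in genomes:
            feat = g.feature_for_gene(rgene, kind="rRNA")
            if feat is not None:
                seqs[g.species] = extract_gene_sequence(g, feat)
        if len(seqs) >= 2:
            msas[rgene] = trim_columns(align_progressive(seqs, marker=rgene),
                                       trim_gap_fraction)
    return msas


def rates_stage(msas: dict[str, Msa]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    k2p_records, kaks_records, rows = [], [], []
    for gene in sorted(msas):
        if gene in ("rnl", "rns"):
            continue
        msa = msas[gene]
        species = sorted(msa.rows)
        for i, x in enumerate(species):
            for y in species[i + 1:]:
                rec = k2p_distance(msa.rows[x], msa.rows[y], gene, (x, y))
                k2p_records.append(rec)
                kk = ng86_kaks(msa.rows[x], msa.rows[y], gene=gene, pair=(x, y))
                kaks_records.append(kk)
                rows.append({"gene": gene, "sp1": x, "sp2": y,
                             "k2p": rec.d_k2p, "P": rec.P, "Q": rec.Q,
                             "ka": kk.Ka, "ks": kk.Ks, "kaks": kk.ratio})
    summary = per_gene_summary(k2p_records, kaks_records)
    pairwise = pd.DataFrame(rows)
    return pairwise, summary, pd.DataFrame()


def run_pipeline(config: PipelineConfig,
                 genomes: list[Mitogenome] | None = None) -> dict:
    """Run all stages; returns the report bundle as a dict of tables/paths."""
    if genomes is None:
        genomes = load_genomes(config.input_paths)
    if not genomes:
        raise ValueError("no input genomes")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"genomes": genomes}
    single = len(genomes) < 2
    if single:
        warnings.warn("single genome: pairwise stages skipped")

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")

    # composition
    bundle["composition"] = genome_composition_table(genomes)
    bundle["partition"] = partition_table(genomes)
    bundle["per_gene"] = per_gene_length_table(genomes)
    bundle["features"] = feature_table(genomes)
    save(bundle["composition"], "composition.tsv")
    save(bundle["partition"], "region_partition.tsv")
    save(bundle["per_gene"], "per_gene_stats.tsv")
    save(bundle["features"], "features.tsv")

    # codon usage + RSCU (+ PCA over PCG and uORF concatenates)
    gene_seqs = core_gene_sequences(genomes)
    rscu_tables = {}
    codon_rows = []
    for g in genomes:
        core = {gene: seqs[g.species] for gene, seqs in gene_seqs.items()
                if g.species in seqs}
        if not core:
            continue
        tab = count_codons(core, scope="core-concatenate")
        rscu_tables[f"{g.species}|PCG"] = tab
        df = codon_table_frame(tab)
        df.insert(0, "species", g.species)
        df.insert(1, "scope", "PCG")
        codon_rows.append(df)
        uorfs = {f"{f.gene}_{i}": extract_gene_sequence(g, f)
                 for i, f in enumerate(g.features_of_kind("uORF"))}
        if uorfs:
            utab = count_codons(uorfs, scope="uORF-concatenate")
            rscu_tables[f"{g.species}|uORF"] = utab
            udf = codon_table_frame(utab)
            udf.insert(0, "species", g.species)
            udf.insert(1, "scope", "uORF")
            codon_rows.append(udf)
    if codon_rows:
        bundle["codon_usage"] = pd.concat(codon_rows, ignore_index=True)
        save(bundle["codon_usage"], "codon_usage.tsv")
    if len(rscu_tables) >= 3:
        mat = rscu_matrix(rscu_tables)
        try:
            pca = rscu_pca(mat)
            bundle["rscu_pca"] = pd.DataFrame(
                {"label": pca.row_labels,
                 "pc1": pca.scores[:, 0],
                 "pc2": pca.scores[:, 1] if pca.scores.shape[1] > 1 else 0.0})
            save(bundle["rscu_pca"], "rscu_pca.tsv")
        except ValueError as exc:
            warnings.warn(f"RSCU PCA skipped: {exc}")

    if not single:
        msas = aligned_core_genes(genomes, config.trim_gap_fraction)
        bundle["msas"] = msas
        pairwise, summary, _ = rates_stage(msas)
        bundle["rates_pairwise"] = pairwise
        bundle["rates_summary"] = summary
        save(pairwise, "rates_pairwise.tsv")
        save(summary, "rates_per_gene.tsv")

    # repeats
    from .repeats import find_dispersed_repeats, find_tandem_repeats, repeat_summary
    rep_rows = []
    for g in genomes:
        disp = find_dispersed_repeats(g, min_len=config.repeat_min_len,
                                      min_identity=config.repeat_min_identity)
        tand = find_tandem_repeats(g)
        rep_rows.append(repeat_summary(g, disp, tand))
    bundle["repeats"] = pd.concat(rep_rows, ignore_index=True)
    save(bundle["repeats"], "repeats.tsv")

    # Pcl catalog
    ref = config.reference_species or genomes[0].species
    try:
        catalog, matrix = cox1_pcl_analysis(genomes, ref,
                                            threshold=config.common_pcl_fraction)
        bundle["pcl_catalog"] = catalog_table(catalog)
        bundle["pcl_matrix"] = matrix
        save(bundle["pcl_catalog"], "pcl_catalog.tsv")
        matrix.to_csv(outdir / "pcl_matrix.tsv", sep="\t")
    except ValueError as exc:
        warnings.warn(f"Pcl stage skipped: {exc}")

    # gene order + synteny
    orders = [extract_gene_order(g) for g in genomes]
    bundle["orders"] = orders
    bundle["order_table"] = order_table(orders)
    bundle["order_groups"] = order_groups(orders)
    save(bundle["order_table"], "gene_orders.tsv")
    if not single:
        bundle["breakpoints"] = breakpoint_matrix(orders)
        bundle["breakpoints"].to_csv(outdir / "breakpoint_matrix.tsv", sep="\t")
        blocks = []
        for i, a in enumerate(genomes):
            for b in genomes[i + 1:]:
                blocks.extend(find_synteny_blocks(
                    a, b, config.synteny_min_identity, config.synteny_min_len))
        bundle["synteny"] = synteny_table(blocks)
        save(bundle["synteny"], "synteny_blocks.tsv")

    # phylogeny
    if not single and len(genomes) >= 4 and "msas" in bundle:
        trees = {}
        for kind in config.dataset_kinds:
            sm = build_supermatrix(bundle["msas"], kind)
            tree, supports = bootstrap_support(
                sm, n_replicates=config.bootstrap_replicates, seed=config.seed)
            trees[kind] = tree
            write_newick(tree, outdir / f"tree_{kind}.nwk")
        bundle["trees"] = trees
        if config.monophyly_taxa:
            bundle["monophyly"] = {
                kind: is_monophyletic(tree, set(config.monophyly_taxa))
                for kind, tree in trees.items()}

    manifest = {
        "mitocomp_version": __version__,
        "seed": config.seed,
        "n_genomes": len(genomes),
        "genome_ids": [g.id for g in genomes],
        "config": {k: v for k, v in vars(config).items()
                   if not isinstance(v, (list,)) or k == "input_paths"},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def summarize(bundle: dict) -> str:
    """One-page text summary of the report bundle."""
    genomes = bundle["genomes"]
    sizes = [g.length for g in genomes]
    lines = [
        "mitocomp run summary",
        "====================",
        f"genomes: {len(genomes)}",
        f"size range: {min(sizes):,} - {max(sizes):,} bp",
    ]
    if "partition" in bundle:
        mean_ig = bundle["partition"]["intergenic_pct"].mean()
        lines.append(f"mean intergenic: {mean_ig:.2f}%")
    if "pcl_catalog" in bundle:
        cat = bundle["pcl_catalog"]
        lines.append(f"cox1 Pcls: {len(cat)} "
                     f"({int((cat['status'] == 'common').sum())} common, "
                     f"{int((cat['status'] == 'rare').sum())} rare)")
    else:
        lines.append("cox1 Pcls: skipped")
    if "order_groups" in bundle:
        sizes_g = sorted((len(gp) for gp in bundle["order_groups"]), reverse=True)
        lines.append(f"gene-order groups: {len(sizes_g)} (sizes {sizes_g})")
    if "monophyly" in bundle:
        for kind, mono in bundle["monophyly"].items():
            lines.append(f"monophyly[{kind}]: {'yes' if mono else 'no'}")
    elif "trees" in bundle:
        lines.append("monophyly: no taxa set configured")
    else:
        lines.append("phylogeny: skipped")
    return "\n".join(lines)
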