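"""Tabular report builders shared by the CLI, the analysis drivers and
the acceptance machinery.  All rounding is presentational; the underlying
module functions keep full precision."""

from __future__ import annotations

import itertools

import pandas as pd

from . import codons as cod
from .composition import CompositionStats, genome_report
from .divergence import (Alignment, ng86_pair, sliding_window_diversity,
                         ungapped_codon_alignment)
from .genome import Mitogenome, feature_sequence
from .structure import intergenic_spacers, pair_classes


def _stats_row(stats: CompositionStats) -> dict:
    return {
        "A": stats.A, "C": stats.C, "G": stats.G, "T": stats.T,
        "length": stats.length_counted,
        "AT_pct": 100 * stats.at_content,
        "GC_pct": 100 * stats.gc_content,
        "AT_skew": stats.at_skew,
        "GC_skew": stats.gc_skew,
    }


def genome_summary_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        stats = genome_report(g)["whole_genome"]
        rows.append({
            "genome": g.id,
            "length": len(g.sequence),
            "n_PCG": len(g.features_of_type("PCG")),
            "n_tRNA": len(g.features_of_type("tRNA")),
            "n_rRNA": len(g.features_of_type("rRNA")),
            **_stats_row(stats),
        })
    return pd.DataFrame(rows)


def composition_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """One row per (genome, category): whole genome, gene classes, codon
    positions, and every individual gene (sense strand)."""
    rows = []
    for g in genomes:
        for category, stats in genome_report(g).items():
            rows.append({"genome": g.id, "category": category,
                         **_stats_row(stats)})
    return pd.DataFrame(rows)


def rscu_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Per-codon counts and RSCU per genome, pooled, and the per-genome
    mean RSCU (the default averaging convention)."""
    tables = {}
    for g in genomes:
        seqs = [feature_sequence(g, f) for f in g.features_of_type("PCG")]
        tables[g.id] = cod.count_codons(seqs)
    pooled = sum(tables.values(), cod.CodonUsageTable())
    mean = cod.mean_rscu(list(tables.values()))
    rows = []
    for codon in cod.SENSE_CODONS:
        row = {
            "codon": cod.as_rna(codon),
            "amino_acid": cod.CODON_TO_AA[codon],
        }
        for gid, table in tables.items():
            row[f"count_{gid}"] = table.counts.get(codon, 0)
            row[f"RSCU_{gid}"] = cod.rscu(table)[codon]
        row["count_pooled"] = pooled.counts.get(codon, 0)
        row["RSCU_pooled"] = cod.rscu(pooled)[codon]
        row["RSCU_mean"] = mean[codon]
        rows.append(row)
    return pd.DataFrame(rows)


def codon_count_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Headline codon tallies: all complete codons and the stop-excluded
    count, per genome."""
    rows = []
    for g in genomes:
        seqs = [feature_sequence(g, f) for f in g.features_of_type("PCG")]
        table = cod.count_codons(seqs)
        rows.append({"genome": g.id,
                     "total_codons": table.total_codons,
                     "sense_codons": table.sense_codon_count})
    return pd.DataFrame(rows)


def amino_acid_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    seqs = [feature_sequence(g, f)
            for g in genomes for f in g.features_of_type("PCG")]
    freqs = cod.amino_acid_frequencies(cod.count_codons(seqs))
    return pd.DataFrame(
        [{"amino_acid": aa, "three_letter": cod.AA_THREE[aa],
          "pct": pct} for aa, pct in sorted(freqs.items())])


def startstop_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        for f in g.features_of_type("PCG"):
            tc = cod.terminal_codons(feature_sequence(g, f))
            rows.append({"genome": g.id, "gene": f.name,
                         "start": tc.start, "start_class": tc.start_class,
                         "stop": tc.stop, "stop_class": tc.stop_class})
    return pd.DataFrame(rows)


def spacer_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        spacers, overlaps = intergenic_spacers(g)
        for s in spacers:
            rows.append({"genome": g.id, "kind": "spacer", "left": s.left,
                         "right": s.right, "length": s.length,
                         "start": s.start})
        for o in overlaps:
            rows.append({"genome": g.id, "kind": "overlap", "left": o.left,
                         "right": o.right, "length": -o.length,
                         "start": -1})
    return pd.DataFrame(rows)


def pairclass_table(structures_by_genome: dict[str, dict[str, tuple[str, str]]]
                    ) -> pd.DataFrame:
    """Pair-class counts per (genome, tRNA) from given structures."""
    rows = []
    for gid, structures in structures_by_genome.items():
        for name, (seq, db) in structures.items():
            pc = pair_classes(seq, db)
            rows.append({
                "genome": gid, "tRNA": name,
                "watson_crick": pc.watson_crick,
                "GU_wobble": pc.gu_wobble,
                "mismatch": pc.mismatch,
                "mismatch_identities": ",".join(pc.mismatch_identities),
            })
    return pd.DataFrame(rows)


def window_table(alignment: Alignment, window: int = 200,
                 step: int = 25) -> pd.DataFrame:
    values = sliding_window_diversity(alignment, window, step)
    return pd.DataFrame([{
        "start": w.start, "end": w.end, "mid": w.midpoint, "pi": w.pi,
        "sites": w.sites_used, "partial": w.partial} for w in values])


def dnds_table(genomes: list[Mitogenome],
               genes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Pairwise Nei-Gojobori rates for every genome pair x PCG.

    Requires equal-length orthologs (identity codon alignment); genes
    missing from any genome are skipped.
    """
    from .genome import PCG_ORDER
    genes = genes or PCG_ORDER
    rows = []
    for gene in genes:
        present = [(g.id, feature_sequence(g, g.get_feature(gene)))
                   for g in genomes if g.get_feature(gene) is not None]
        if len(present) < 2:
            continue
        for (id1, s1), (id2, s2) in itertools.combinations(present, 2):
            aln = ungapped_codon_alignment([id1, id2], [s1, s2])
            rates = ng86_pair(aln.rows[0], aln.rows[1])
            rows.append({
                "genome1": id1, "genome2": id2, "gene": gene,
                "N": rates.N_sites, "S": rates.S_sites,
                "Nd": rates.Nd, "Sd": rates.Sd,
                "dN": rates.dN, "dS": rates.dS, "ratio": rates.ratio,
            })
    return pd.DataFrame(rows)


def gene_diversity_table(genomes: list[Mitogenome],
                         ftypes: tuple[str, ...] = ("PCG", "tRNA", "rRNA")
                         ) -> pd.DataFrame:
    """Per-gene nucleotide diversity across genomes (equal-length
    orthologs only; others skipped)."""
    from .divergence import nucleotide_diversity
    rows = []
    gene_names = {f.name: f.ftype for g in genomes for f in g.features
                  if f.ftype in ftypes}
    for gene, ftype in gene_names.items():
        seqs, labels = [], []
        for g in genomes:
            f = g.get_feature(gene)
            if f is not None:
                labels.append(g.id)
                seqs.append(feature_sequence(g, f))
        if len(seqs) < 2 or len({len(s) for s in seqs}) != 1:
            continue
        pi = nucleotide_diversity(Alignment(labels, seqs))
        rows.append({"gene": gene, "ftype": ftype, "n": len(seqs), "pi": pi})
    return pd.DataFrame(rows)
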