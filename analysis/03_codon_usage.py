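"""Codon usage of the 13 protein-coding genes under translation table 5.

Writes codon counts, per-genome and pooled RSCU, amino-acid
frequencies and start/stop codon classes; prints the headline numbers
(codons per genome, most/least used codons, terminal-codon pattern).

Usage:  python analysis/03_codon_usage.py
"""

from pathlib import Path

from mitocomp.io import read_genbank
from mitocomp.tables import (amino_acid_table, codon_count_table,
                             rscu_table, startstop_table)

DATA = Path("results/data/cohort")
OUT = Path("results/analysis")


def main() -> None:
    genomes = []
    for path in sorted(DATA.glob("*.gb")):
        with open(path) as fh:
            genomes.extend(read_genbank(fh))
    OUT.mkdir(parents=True, exist_ok=True)

    counts = codon_count_table(genomes)
    counts.to_csv(OUT / "codon_counts.tsv", sep="\t", index=False)
    print(f"complete codons per genome: {counts.total_codons.tolist()} "
          f"(stop-excluded: {counts.sense_codons.tolist()})")

    rscu = rscu_table(genomes)
    rscu.to_csv(OUT / "rscu.tsv", sep="\t", index=False)
    top = rscu.nlargest(3, "RSCU_mean")[["codon", "amino_acid",
                                         "RSCU_mean"]]
    print("most used codons (mean RSCU): "
          + ", ".join(f"{r.codon} ({r.amino_acid}) {r.RSCU_mean:.2f}"
                      for r in top.itertuples()))

    aa = amino_acid_table(genomes)
    aa.to_csv(OUT / "amino_acid_freqs.tsv", sep="\t", index=False)
    ordered = aa.sort_values("pct", ascending=False)
    print(f"most frequent amino acid: {ordered.iloc[0].three_letter} "
          f"({ordered.iloc[0].pct:.1f}%); least frequent: "
          f"{ordered.iloc[-1].three_letter} ({ordered.iloc[-1].pct:.2f}%)")

    ss = startstop_table(genomes)
    ss.to_csv(OUT / "start_stop.tsv", sep="\t", index=False)
    atp6 = ss[ss.gene == "ATP6"].start_class.unique().tolist()
    print(f"start codons: ATN throughout except ATP6 ({atp6}); "
          f"stop codons all {ss.stop_class.unique().tolist()}")


if __name__ == "__main__":
    main()
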