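"""Generate the synthetic study inputs.

Writes four independently sampled annotated mitogenomes (the
composition/codon-usage cohort) and a six-taxon orthologous family
evolved along a known tree (the diversity/selection/phylogeny cohort)
under results/data/, as GenBank flat files, feature tables, tRNA
structure files and YAML truth logs.

Usage:  python analysis/01_simulate_genomes.py [--seed 1]
"""

import argparse
from pathlib import Path

import yaml

from mitocomp.io import write_feature_table, write_genbank
from mitocomp.structure import write_structures
from mitocomp.synthetic import (FamilySpec, evolve_genome_family,
                                simulate_study_genomes)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default="results/data")
    args = parser.parse_args()
    out = Path(args.out)
    (out / "cohort").mkdir(parents=True, exist_ok=True)
    (out / "family").mkdir(parents=True, exist_ok=True)

    genomes, truths = simulate_study_genomes(n=4, seed=args.seed)
    for g, t in zip(genomes, truths):
        with open(out / "cohort" / f"{g.id}.gb", "w") as fh:
            write_genbank([g], fh)
        with open(out / "cohort" / f"{g.id}.features.tsv", "w") as fh:
            write_feature_table(g, fh)
        with open(out / "cohort" / f"{g.id}.structures.txt", "w") as fh:
            write_structures(t["structures"], fh)
        slim = {k: v for k, v in t.items()
                if k not in ("genes", "structures", "spacer_sequences")}
        with open(out / "cohort" / f"{g.id}.truth.yaml", "w") as fh:
            yaml.safe_dump(slim, fh)
    print(f"cohort: {len(genomes)} genomes, lengths "
          f"{[len(g.sequence) for g in genomes]}")

    family, truth = evolve_genome_family(FamilySpec(seed=args.seed))
    for g in family:
        with open(out / "family" / f"{g.id}.gb", "w") as fh:
            write_genbank([g], fh)
    with open(out / "family" / "generating_tree.nwk", "w") as fh:
        fh.write(truth["tree"] + "\n")
    events = {p: b["nonsynonymous"] for p, b in truth["branches"].items()}
    print(f"family: {len(family)} taxa evolved along the known tree; "
          f"nonsynonymous events per branch: {events}")


if __name__ == "__main__":
    main()
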