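"""Shared fixtures: toy genomes, synthetic study data, accession loading."""

from __future__ import annotations

from pathlib import Path

import pytest

from mitocomp.genome import GeneFeature, Mitogenome
from mitocomp.synthetic import (FamilySpec, GenomeSpec,
                                evolve_genome_family, simulate_mitogenome)

ACCESSION_DIR = Path(__file__).resolve().parent.parent / "data" / "accessions"

#: The deposited study records: four newly sequenced genomes plus the
#: congener used in the diversity/selection comparisons.
STUDY_ACCESSIONS = {
    "MN531846": "Hg_albomaculatus",
    "MN531847": "Hg_leucocelaenus",
    "MN531848": "Hg_spegazzinii",
    "MN531849": "Hg_tropicalis",
}
COMPARISON_ACCESSION = {"NC_028025": "Hg_janthinomys"}


def load_accessions(which: dict[str, str] | None = None) -> dict:
    """Load deposited GenBank records from data/accessions/.

    The records are not redistributable inside this repository; fetch
    them once with ``python scripts/fetch_accessions.py`` (network
    required).  Analyses depending on them fail with this message until
    the files are present.
    """
    from mitocomp.io import read_genbank

    which = which or STUDY_ACCESSIONS
    genomes = {}
    missing = []
    for acc, label in which.items():
        path = ACCESSION_DIR / f"{acc}.gb"
        if not path.exists():
            missing.append(acc)
            continue
        with open(path) as fh:
            (g,) = read_genbank(fh)
        genomes[label] = g
    if missing:
        raise AssertionError(
            f"GenBank records {missing} not found under {ACCESSION_DIR}; "
            "run `python scripts/fetch_accessions.py` (requires network) "
            "to download the deposited study genomes")
    return genomes


@pytest.fixture(scope="session")
def toy_genome() -> Mitogenome:
    """60 bp circular genome with one gene per class and a wrap feature."""
    #           0         1         2         3         4         5
    #           0123456789012345678901234567890123456789012345678901234567890
    sequence = "ATGAAATTTGGGCCCTAAACGTACGTACGTAAATTTCCCGGGTTTAAACCCTTTGGGAAA"
    features = [
        GeneFeature("ND2", "PCG", 0, 18, "J"),          # ATG...TAA
        GeneFeature("tRNA-Ile", "tRNA", 20, 40, "J"),
        GeneFeature("rRNA-12S", "rRNA", 42, 54, "N"),
        GeneFeature("tRNA-Val", "tRNA", 57, 3, "J", wraps_origin=True),
    ]
    return Mitogenome(id="toy", sequence=sequence, features=features)


@pytest.fixture(scope="session")
def synthetic_genome():
    return simulate_mitogenome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def genome_family():
    return evolve_genome_family(FamilySpec(seed=1))
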