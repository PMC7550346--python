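"""Download the deposited Haemagogus mitogenome records from NCBI.

Fetches the GenBank flat files used by the reported-value acceptance
tests into data/accessions/.  Requires network access; the library
itself never performs I/O beyond the streams it is given, so this is
the only place a download happens.

Usage:  python scripts/fetch_accessions.py [--out data/accessions]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

ACCESSIONS = {
    "MN531846": "Haemagogus albomaculatus",
    "MN531847": "Haemagogus leucocelaenus",
    "MN531848": "Haemagogus spegazzinii",
    "MN531849": "Haemagogus tropicalis",
    "NC_028025": "Haemagogus janthinomys",
    "NC_006817": "Aedes albopictus (outgroup)",
}


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode({
        "db": "nucleotide", "id": accession,
        "rettype": "gb", "retmode": "text",
    })
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/accessions")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    for accession, species in ACCESSIONS.items():
        target = out / f"{accession}.gb"
        if target.exists():
            print(f"{accession} ({species}): already present")
            continue
        print(f"{accession} ({species}): fetching ...")
        text = fetch(accession)
        if "LOCUS" not in text.split("\n", 1)[0]:
            print(f"  unexpected response for {accession}", file=sys.stderr)
            return 1
        target.write_text(text)
        time.sleep(0.4)  # NCBI rate courtesy
    print(f"records in {out}/")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
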