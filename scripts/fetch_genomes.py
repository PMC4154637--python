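#!/usr/bin/env python
"""Download the Streptomyces genomes needed for the published-count
RiPP checks into data/genomes/ (requires network access; the files are
multi-megabyte and are never committed).

Complete (single-record) genomes are fetched from NCBI efetch by
accession.  Two of the nine strains are multi-contig WGS drafts whose
contig sets are easiest to obtain via NCBI `datasets`; instructions are
printed for those.

Usage:  python scripts/fetch_genomes.py [--only key[,key...]]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "genomes"

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=fasta&retmode=text&id={acc}"
)

# key -> (accession, description)
ACCESSIONS = {
    "coelicolor": ("AL645882", "Streptomyces coelicolor A3(2) chromosome"),
    "albus": ("CP004370", "Streptomyces albus J1074 chromosome"),
    "griseus": ("AP009493", "Streptomyces griseus IFO 13350 chromosome"),
    "lividans": ("CP009124", "Streptomyces lividans TK24 chromosome"),
    "sviceus": ("CM000951", "Streptomyces sviceus ATCC 29083 chromosome (WGS scaffold)"),
}

WGS_DRAFTS = {
    "roseosporus": "Streptomyces roseosporus NRRL 15998 (WGS draft; fetch all "
                   "contigs, e.g. `datasets download genome taxon "
                   "'Streptomyces roseosporus NRRL 15998'`, and save the "
                   "concatenated FASTA as data/genomes/roseosporus.fasta)",
    "sp_e14": "Streptomyces sp. E14 (WGS draft; fetch all contigs and save "
              "as data/genomes/sp_e14.fasta)",
}


def fetch(key: str, acc: str) -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    dest = OUT_DIR / f"{key}.fasta"
    if dest.exists():
        print(f"  {key}: already present ({dest})")
        return
    url = EFETCH.format(acc=acc)
    print(f"  {key}: downloading {acc} ...")
    with urllib.request.urlopen(url, timeout=600) as resp:
        data = resp.read()
    if not data.startswith(b">"):
        raise RuntimeError(f"{key}: response does not look like FASTA")
    dest.write_bytes(data)
    print(f"  {key}: wrote {len(data) / 1e6:.1f} MB to {dest}")


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--only", default=None,
                    help="comma-separated subset of genome keys")
    args = ap.parse_args()
    wanted = set(args.only.split(",")) if args.only else set(ACCESSIONS) | set(WGS_DRAFTS)

    failures = []
    for key, (acc, desc) in ACCESSIONS.items():
        if key not in wanted:
            continue
        try:
            fetch(key, acc)
        except Exception as err:  # noqa: BLE001 - report and continue
            failures.append(key)
            print(f"  {key}: FAILED ({err})", file=sys.stderr)
    for key, note in WGS_DRAFTS.items():
        if key in wanted and not (OUT_DIR / f"{key}.fasta").exists():
            print(f"  {key}: manual step required — {note}")
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
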