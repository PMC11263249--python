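#!/usr/bin/env python
"""Fetch the six deposited Hymenochaetales mitogenome records from NCBI.

Downloads GenBank flat files into data/reference/ for the regression test in
tests/test_acceptance.py.  Requires network access; the records are not
vendored because of their size.

Usage:  python scripts/fetch_reference_genomes.py
"""

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "ON969135": "Inonotus hispidus",
    "OP265749": "Phellinus gilvus",
    "OP141808": "Phellinus viticola",
    "OP141806": "Porodaedalea chrysoloma",
    "OP141805": "Phellinus ferrugineofuscus",
    "OP141804": "Porodaedalea niemelaei",
}

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text")


def main() -> int:
    outdir = Path(__file__).resolve().parent.parent / "data" / "reference"
    outdir.mkdir(parents=True, exist_ok=True)
    failures = 0
    for acc, species in ACCESSIONS.items():
        dest = outdir / f"{acc}.gb"
        if dest.exists():
            print(f"{acc} ({species}): already present")
            continue
        url = EFETCH.format(acc=acc)
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                data = resp.read()
            dest.write_bytes(data)
            print(f"{acc} ({species}): {len(data):,} bytes")
        except Exception as exc:
            print(f"{acc} ({species}): FAILED ({exc})", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
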