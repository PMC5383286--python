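"""Fetch the 20 Charadriiformes mitogenome GenBank records from NCBI.

Usage:  python scripts/fetch_accessions.py [--out data/accessions]

Downloads each accession of the published 20-genome cohort as a GenBank
flat file via NCBI E-utilities.  Requires network access; the package's
tests never call this script, and no downloaded data is redistributed.
"""

from __future__ import annotations

import argparse
import time
import urllib.request
from pathlib import Path

ACCESSIONS = ["AY074886", "KP757766", "KM404175", "KM873665", "KM577158",
              "KJ631049", "KJ631048", "KM434134", "AY074885", "KP742478",
              "KY056596", "JX155863", "KM577662", "JQ071443", "KM507782",
              "AY293619", "KC760146", "KT350612", "KM401546", "AP009042"]

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gb&retmode=text")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("data/accessions"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=60) as r:
            dest.write_bytes(r.read())
        print(f"{acc}: fetched {dest.stat().st_size} bytes")
        time.sleep(0.4)  # NCBI rate courtesy


if __name__ == "__main__":
    main()
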