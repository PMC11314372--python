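"""Fetch real GenBank protein fixtures for the full table-reproduction test.

NETWORK-DEPENDENT helper: downloads a handful of protein accessions from
NCBI E-utilities into tests/fixtures/accessions/, where the acceptance
test picks them up automatically. The offline test suite runs without
these fixtures; fetching them enables the numeric comparison against the
published per-protein feature table.

    python scripts/fetch_fixtures.py
"""

from __future__ import annotations

import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "OAO95078.1",      # AtPCS1, annotated triad reference
    "RCJ37125.1",      # N. punctiforme group-1 PCS
    "XP_005536287.1",  # C. merolae group-2 PCS
]

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
OUT_DIR = Path(__file__).resolve().parent.parent / "tests" / "fixtures" / "accessions"


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode({
        "db": "protein", "id": accession, "rettype": "fasta", "retmode": "text",
    })
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=30) as fh:
        return fh.read().decode()


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        path = OUT_DIR / f"{acc}.fasta"
        if path.exists():
            print(f"{acc}: already fetched")
            continue
        text = fetch(acc)
        if not text.startswith(">"):
            raise RuntimeError(f"{acc}: unexpected response")
        # normalise the header to the bare accession
        body = text.split("\n", 1)[1]
        path.write_text(f">{acc}\n{body}")
        print(f"{acc}: wrote {path}")
        time.sleep(0.4)  # NCBI rate limit


if __name__ == "__main__":
    main()
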