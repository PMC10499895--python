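#!/usr/bin/env python
"""Fetch the GRCh38 chromosome 19 region around TCF3 intron 16.

Downloads chr19:1,605,001-1,630,000 (1-based, covering the 3289-bp intron at
1,615,822-1,619,110 plus flank to the nearest BamHI/SphI/TaqI sites) from the
UCSC REST API and writes it as an uncompressed FASTA where the control-band
prediction and criterion 5 expect it. Needs network access; run once.

Usage:
    python scripts/fetch_reference.py [--out PATH]
"""

from __future__ import annotations

import argparse
import json
import sys
import urllib.request
from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parents[1]
DEFAULT_OUT = REPO_ROOT / "src" / "fusionbreak" / "data" / "external" / \
    "grch38_tcf3_region.fa"

START_0BASED = 1_605_000   # UCSC half-open coordinates
END = 1_630_000
URL = ("https://api.genome.ucsc.edu/getData/sequence?"
       f"genome=hg38;chrom=chr19;start={START_0BASED};end={END}")


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=DEFAULT_OUT)
    args = parser.parse_args(argv)

    with urllib.request.urlopen(URL, timeout=60) as response:
        payload = json.load(response)
    seq = payload["dna"].upper()
    if len(seq) != END - START_0BASED:
        print(f"unexpected sequence length {len(seq)}", file=sys.stderr)
        return 1

    args.out.parent.mkdir(parents=True, exist_ok=True)
    header = f">chr19:{START_0BASED + 1}-{END} GRCh38 TCF3 intron 16 region"
    lines = [header] + [seq[i:i + 70] for i in range(0, len(seq), 70)]
    args.out.write_text("\n".join(lines) + "\n")
    print(f"wrote {args.out} ({len(seq)} bp)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
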