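#!/usr/bin/env python
"""Optionally fetch the real ARHGAP31 coding sequence (NM_020754.4).

Requires network access to NCBI E-utilities.  The downloaded FASTA is a
drop-in replacement for the synthetic surrogate CDS built by
``aoskit.synthetic.surrogate_cds`` (same wild-type protein length).

Usage::

    python scripts/fetch_reference_cds.py --out NM_020754.4_cds.fasta
"""

from __future__ import annotations

import argparse
import sys
import urllib.request

URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id=NM_020754.4&rettype=fasta_cds_na&retmode=text"
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="NM_020754.4_cds.fasta")
    args = parser.parse_args()
    try:
        with urllib.request.urlopen(URL, timeout=30) as response:
            data = response.read().decode()
    except OSError as exc:
        sys.exit(f"could not reach NCBI ({exc}); the synthetic surrogate "
                 "CDS (aoskit.synthetic.surrogate_cds) remains available")
    if not data.startswith(">"):
        sys.exit("unexpected response from NCBI (not FASTA)")
    with open(args.out, "w") as fh:
        fh.write(data)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
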