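#!/usr/bin/env python
"""Fetch the deposited parent (E06) and humanized-variant (huE06 v1.1) VNAR
sequences from the RCSB (entries 4HGK and 4HGM, each a VNAR-HSA complex)
and write them to docs/sequences/vnar_sequences.fasta for the sequence-level
acceptance check.

Needs network access; the analysis environment itself never downloads.
The VNAR chain is identified as the shortest polymer entity of each entry.
"""

import json
import urllib.request
from pathlib import Path

ENTRIES = {"4HGK": "E06", "4HGM": "huE06_v1.1"}
OUT = Path(__file__).resolve().parent / "sequences" / "vnar_sequences.fasta"


def entity_sequences(pdb_id: str):
    url = (
        "https://data.rcsb.org/rest/v1/core/entry/" + pdb_id
    )
    entry = json.load(urllib.request.urlopen(url))
    n_entities = entry["rcsb_entry_info"]["polymer_entity_count_protein"]
    seqs = []
    for entity_id in range(1, n_entities + 1):
        eurl = (
            f"https://data.rcsb.org/rest/v1/core/polymer_entity/{pdb_id}/{entity_id}"
        )
        entity = json.load(urllib.request.urlopen(eurl))
        seqs.append(entity["entity_poly"]["pdbx_seq_one_letter_code_can"])
    return seqs


def main():
    OUT.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for pdb_id, name in ENTRIES.items():
        seqs = entity_sequences(pdb_id)
        vnar = min(seqs, key=len)  # VNAR (~100 aa) vs HSA (~580 aa)
        records.append(f">{name} {pdb_id} VNAR chain\n{vnar}\n")
        print(f"{name}: {len(vnar)} residues from {pdb_id}")
    OUT.write_text("".join(records))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
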