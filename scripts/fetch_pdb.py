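#!/usr/bin/env python
"""Download the reference crystal structures into data/pdb/.

Fetches the 20 comparative-dataset entries plus the ligand-free AaegOBP22
form (6og0) from the RCSB. Needs network access; the analysis itself runs
entirely offline once the files are local.

Usage: python scripts/fetch_pdb.py [--dest data/pdb]
"""

import argparse
import sys
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cadyn.datasets import APO_HOLO_PAIR, OBP_DATASET  # noqa: E402

URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dest", default="data/pdb", type=Path)
    args = ap.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    ids = [e.pdb_id for e in OBP_DATASET] + [APO_HOLO_PAIR["apo"]]
    failed = []
    for pdb_id in ids:
        out = args.dest / f"{pdb_id}.pdb"
        if out.exists():
            print(f"{pdb_id}: already present")
            continue
        try:
            urllib.request.urlretrieve(URL.format(pdb_id=pdb_id.upper()), out)
            print(f"{pdb_id}: fetched")
        except Exception as exc:           # noqa: BLE001
            failed.append(pdb_id)
            print(f"{pdb_id}: FAILED ({exc})")
    if failed:
        print(f"failed: {failed}")
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
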