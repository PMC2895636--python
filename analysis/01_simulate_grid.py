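#!/usr/bin/env python
"""Simulate and classify a reduced conductance-grid database.

The full study grid is 6 levels per conductance (6^8 ~ 1.7M models, a
cluster-scale run); this driver builds the desk-scale 3-level analogue
(3^8 = 6,561 models, minutes on one core) with the default 10-s protocol and
writes it to scratch/reduced_db.tsv.  Re-runs resume from the checkpoint
directory under scratch/.
"""

import argparse
import sys
import time

from condcorr.database import write_db
from condcorr.synth import make_reduced_grid_db


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--levels", type=int, default=3)
    ap.add_argument("--out", default="scratch/reduced_db.tsv")
    ap.add_argument("--checkpoint-dir", default="scratch/grid_checkpoints")
    args = ap.parse_args(argv)

    t0 = time.time()
    db = make_reduced_grid_db(levels=args.levels, checkpoint_dir=args.checkpoint_dir)
    write_db(db, args.out)
    counts = db.records["activity_class"].value_counts()
    print(f"simulated {len(db)} models in {time.time() - t0:.0f} s -> {args.out}")
    for cls, n in counts.items():
        print(f"  {cls:>20s}: {n:6d} ({100 * n / len(db):.1f}%)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
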