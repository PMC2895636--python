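#!/usr/bin/env python
"""Partition the reduced database and screen all conductance pairs.

Loads scratch/reduced_db.tsv, enumerates the 47 reference-mode sub-populations,
scans every population with at least --min-pop models for pairwise linear
dependence (chi^2 > 500, |rho| > 0.2), and writes the tidy results, the
population x pair sign matrix, the flagged-for-review list, and tally counts
under results/.

Note: the chi-squared cutoff is deliberately N-dependent, so the 6,561-model
reduced grid clears it far less often than the 1.7M-model study database —
correlation counts here are not comparable to the full-scale tallies.
"""

import argparse
import json
import sys
import warnings

import pandas as pd

from condcorr.correlate import results_frame, scan, sign_matrix
from condcorr.database import reference_populations, read_db


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--db", default="scratch/reduced_db.tsv")
    ap.add_argument("--min-pop", type=int, default=50)
    ap.add_argument("--out-prefix", default="results/scan")
    args = ap.parse_args(argv)

    db = read_db(args.db)
    pops = reference_populations(db)
    sizes = pd.DataFrame(
        {"population": [p.label for p in pops], "size": [p.size for p in pops]}
    )
    sizes.to_csv(f"{args.out_prefix}_populations.tsv", sep="\t", index=False)
    print(f"{len(pops)} populations; {sum(p.size >= args.min_pop for p in pops)} "
          f"with >= {args.min_pop} models")

    all_results = {}
    for pop in pops:
        if pop.size < args.min_pop:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            all_results[pop.label] = scan(db, pop)
    summary = pd.concat(
        [results_frame(r) for r in all_results.values()], ignore_index=True
    )
    summary.to_csv(f"{args.out_prefix}_results.tsv", sep="\t", index=False)
    sign_matrix(all_results).to_csv(f"{args.out_prefix}_sign_matrix.tsv", sep="\t")
    summary[summary["flagged_visual"]].to_csv(
        f"{args.out_prefix}_flagged.tsv", sep="\t", index=False
    )

    corr = summary[summary["is_correlation"]]
    calcium = corr[corr["pair"].str.contains("CaT|CaS")]
    tallies = {
        "populations_scanned": len(all_results),
        "pairs_tested": int(len(summary)),
        "correlations": int(len(corr)),
        "negative": int((corr["slope_sign"] == "-").sum()),
        "involving_calcium": int(len(calcium)),
        "flagged_for_review": int(summary["flagged_visual"].sum()),
    }
    with open(f"{args.out_prefix}_tallies.json", "w") as fh:
        json.dump(tallies, fh, indent=1)
    print(json.dumps(tallies, indent=1))
    return 0


if __name__ == "__main__":
    sys.exit(main())
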