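#!/usr/bin/env python
"""Correlation-based populations and enrichment controls on the reduced grid.

For every scanned population of the reduced simulated database that shows at
least one correlation, builds the 3% masks, forms the correlation-based
populations (single-mask and all-masks conjunction), and reports %Success and
f_Success against matched random-mask controls and ideal diagonal-band masks.
Writes results/enrichment.tsv and results/enrichment_controls.tsv.
"""

import argparse
import sys
import warnings

import numpy as np
import pandas as pd

from condcorr.cbpop import (
    ideal_linear_mask,
    mask_from_correlation,
    random_control_masks,
    select_cb_population,
    success,
    success_frame,
)
from condcorr.correlate import histogram2d, scan
from condcorr.database import reference_populations, read_db


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--db", default="scratch/reduced_db.tsv")
    ap.add_argument("--min-pop", type=int, default=50)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-controls", type=int, default=50)
    args = ap.parse_args(argv)

    db = read_db(args.db)
    rng = np.random.default_rng(args.seed)
    reports, controls = [], []
    for pop in reference_populations(db):
        if pop.size < args.min_pop:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = [r for r in scan(db, pop) if r.is_correlation]
        if not corr:
            continue
        masks = []
        for r in corr:
            m = mask_from_correlation(histogram2d(db, pop, r.pair))
            if m.empty:
                continue
            masks.append(m)
            cb = select_cb_population(db, [m], label=f"cb[{pop.label}:{'/'.join(r.pair)}]")
            if cb.size:
                reports.append(success(db, cb, pop))
            # matched random controls: same cell count, random pair
            for ctrl in random_control_masks(
                args.n_controls, m.n_cells, db.n_levels, rng, db.conductance_names
            ):
                cbc = select_cb_population(db, [ctrl], label="random")
                if cbc.size:
                    controls.append(success(db, cbc, pop))
            # ideal-band sanity check on a random pair
            pairs = list(zip(db.conductance_names, db.conductance_names[1:]))
            ideal = ideal_linear_mask(
                pairs[rng.integers(len(pairs))], db.n_levels, width=2,
                sign="+" if rng.random() < 0.5 else "-",
            )
            cbi = select_cb_population(db, [ideal], label="ideal")
            if cbi.size:
                controls.append(success(db, cbi, pop))
        if len(masks) > 1:
            cb = select_cb_population(db, masks, label=f"cb[{pop.label}:all]")
            if cb.size:
                rep = success(db, cb, pop)
                rep.n_masks = len(masks)
                reports.append(rep)

    success_frame(reports).to_csv("results/enrichment.tsv", sep="\t", index=False)
    success_frame(controls).to_csv("results/enrichment_controls.tsv", sep="\t", index=False)
    fr = success_frame(reports)
    fc = success_frame(controls)
    if len(fr):
        single = fr[fr["n_masks"] == 1]["f_success"]
        multi = fr[fr["n_masks"] > 1]["f_success"]
        print(f"correlation-based: n={len(fr)}, "
              f"single-mask mean f={single.mean():.2f} (sd {single.std():.2f})"
              + (f", multi-mask mean f={multi.mean():.2f}" if len(multi) else ""))
    if len(fc):
        print(f"controls: n={len(fc)}, mean f={fc['f_success'].mean():.2f} "
              f"(sd {fc['f_success'].std():.2f})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
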