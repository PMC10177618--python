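#!/usr/bin/env python
"""Per-cell morphometrics on the default snapshots: aspect-ratio coefficients,
orientation-class fractions, AP-oriented spindle fractions and filopodia
statistics per region and stage."""

from pathlib import Path

import numpy as np
import pandas as pd

from psmflow import default_config, generate_stage_snapshot
from psmflow.geometry import filopodia_stats, orientation_fractions, spindle_ap_fraction
from psmflow.pipeline import _aspect_table, _region_cells, _regions_present
from psmflow.types import cell_ellipsoid

OUT = Path(__file__).resolve().parents[1] / "results" / "morphometrics"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    shape_rows, orient_rows, spindle_rows, filo_rows = [], [], [], []
    for stage in cfg.stages():
        snap = generate_stage_snapshot(cfg, stage, SEED)
        for region, (mean, sd, n) in _aspect_table(snap).items():
            shape_rows.append({"stage": stage, "region": region, "mean_ar": mean, "sd": sd, "n": n})
        for region in _regions_present(snap):
            cells = _region_cells(snap, region)
            fr = orientation_fractions((cell_ellipsoid(c) for c in cells), snap.frame, cfg.min_ar)
            for cls, v in fr.items():
                orient_rows.append({"stage": stage, "region": region, "class": cls, "fraction": v})
            f1, f5, fmean, fmax = filopodia_stats(cells, region)
            filo_rows.append(
                {"stage": stage, "region": region, "frac_ge1": f1, "frac_ge5": f5,
                 "mean_um": fmean, "max_um": fmax}
            )
        frac = spindle_ap_fraction(snap.divisions, snap.frame, cfg.cone_half_angle_deg)
        spindle_rows.append({"stage": stage, "ap_fraction_pct": 100 * frac, "n_events": len(snap.divisions)})
        print(f"stage {stage}: AP-oriented divisions {100 * frac:.1f}% of {len(snap.divisions)} events")
    pd.DataFrame(shape_rows).to_csv(OUT / "aspect_ratios.tsv", sep="\t", index=False)
    pd.DataFrame(orient_rows).to_csv(OUT / "orientation_fractions.tsv", sep="\t", index=False)
    pd.DataFrame(spindle_rows).to_csv(OUT / "spindle_fractions.tsv", sep="\t", index=False)
    pd.DataFrame(filo_rows).to_csv(OUT / "filopodia.tsv", sep="\t", index=False)
    print(f"wrote morphometrics tables to {OUT}")


if __name__ == "__main__":
    main()
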