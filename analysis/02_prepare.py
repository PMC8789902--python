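"""Prune collinear covariates and build the grouped design matrix.

Applies the |r| >= 0.7 Pearson rule to all continuous covariate pairs
(keeping the higher-priority member, here input order) and encodes the
survivors plus the land-cover factor into the standardized, dummy-coded,
group-indexed design used by the occupancy model.  Writes the correlation
report and the design report (groups, baselines, standardization constants)
needed to reproduce the fit.
"""

import json
from pathlib import Path

import pandas as pd

from edna_occupancy import CovariateTable, build_design_matrix, prune_correlated

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main():
    table = CovariateTable.from_frame(pd.read_csv(OUT / "covariates.csv"))
    retained, report = prune_correlated(table, threshold=0.7)
    report.to_csv(OUT / "correlation_report.csv", index=False)
    dropped = sorted(set(table.continuous) - set(retained))
    print(f"continuous covariates: {len(table.continuous)}, retained "
          f"{len(retained) - len(table.categorical)}, dropped {dropped}")
    offending = report[report["dropped"] != ""]
    for _, row in offending.iterrows():
        print(f"  |r({row.covariate_a}, {row.covariate_b})| = "
              f"{abs(row.pearson_r):.2f} -> dropped {row.dropped}")

    design = build_design_matrix(table, retained)
    design.write_report(OUT / "design_report.json")
    (OUT / "formula.json").write_text(json.dumps(retained))
    print(f"design: {design.X.shape[0]} sites x {design.X.shape[1]} columns in "
          f"{len(design.covariate_groups)} candidate groups "
          f"(baseline land cover: {design.baseline.get('landcover')})")


if __name__ == "__main__":
    main()
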