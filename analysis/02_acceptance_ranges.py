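#!/usr/bin/env python
"""Fit the statistical range of acceptance per regulatory category.

Reads results/measurements.csv, applies QC and LOQ substitution, fits the
lognormal acceptance range (cv20 convention) and decides pass/fail against
each category's regulatory threshold. Writes results/acceptance_report.csv.
"""

import argparse
from pathlib import Path

from msfd9 import apply_loq_policy, assess, load_catalog, load_measurements, qc_filter
from msfd9.acceptance_stats import write_acceptance_report

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

catalog = load_catalog("builtin")
ms, errors = load_measurements(args.outdir / "measurements.csv", catalog)
assert not errors, f"{len(errors)} malformed rows"
ms, report = qc_filter(ms, catalog)
print(f"QC: kept {report.n_kept}/{report.n_input} "
      f"(removed {report.removed_by_rule or 'none'})")
ms = apply_loq_policy(ms, "half_loq")

by_cat = {}
for m in ms:
    by_cat.setdefault(m.category_code, []).append(m.concentration)

decisions = []
for code in sorted(by_cat):
    d = assess(by_cat[code], catalog[code].limit_value, category_code=code)
    decisions.append(d)
    r = d.range
    verdict = "PASS" if d.passed else "FAIL"
    gate = "" if d.normality_ok else "  [lognormality questionable]"
    print(f"{code:40s} n={r.n:5d} gm={r.gm:8.4f} emp_p90={r.empirical_p90:8.4f} "
          f"TL={r.tl:6.3g} -> {verdict}{gate}")

write_acceptance_report(decisions, args.outdir / "acceptance_report.csv")
print(f"wrote {args.outdir / 'acceptance_report.csv'}")
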