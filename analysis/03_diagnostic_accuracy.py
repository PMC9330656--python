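#!/usr/bin/env python
"""Diagnostic-accuracy statistics from the published count tables.

No raw fluorescence data are published, so this step works from the printed
counts (rtquic.study_counts): positivity percents with exact 95% CIs for
every group, the first-round swab-site comparison (Fisher's exact test and
Cramér's V), the second-round paired agger-nasi vs middle-turbinate
agreement (exact McNemar and Cohen's kappa), and the OR-rule CSF+swab
combination. Writes results/stats/diagnostics.json and a flat CSV.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rtquic import study_counts
from rtquic.diagnostics import proportion_summary
from rtquic.pipeline import stats_from_paired_table
from rtquic.pipeline import stats_from_counts


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, (k, n) in [
        ("NS-AN PD, first round", study_counts.FIRST_ROUND_AN_PD),
        ("NS-MT PD, first round", study_counts.FIRST_ROUND_MT_PD),
        ("non-PD, first round", study_counts.FIRST_ROUND_NON_PD),
        ("PD overall, first round", study_counts.FIRST_ROUND_PD_OVERALL),
        ("NS-AN PD, second round", study_counts.SECOND_ROUND_AN_PD),
        ("NS-MT PD, second round", study_counts.SECOND_ROUND_MT_PD),
        ("CSF PD", study_counts.CSF_PD),
        ("CSF + swab combined, PD", study_counts.COMBINED_CSF_OM_PD),
    ]:
        s = proportion_summary(k, n)
        rows.append({"group": label, "positive": k, "total": n,
                     "percent": s.percent_rounded,
                     "ci95_low": round(s.ci_low, 3), "ci95_high": round(s.ci_high, 3)})
    summary = pd.DataFrame(rows)
    print(summary.to_string(index=False))
    summary.to_csv(args.out_dir / "positivity_summary.csv", index=False)

    site = stats_from_counts(pd.DataFrame([
        {"group": "NS_AN", "positive": 27, "total": 32},
        {"group": "NS_MT", "positive": 5, "total": 11},
    ]))
    paired = stats_from_paired_table(study_counts.SECOND_ROUND_PAIRED_TABLE)
    blob = {"first_round_site_comparison": site, "second_round_paired": paired}
    (args.out_dir / "diagnostics.json").write_text(
        json.dumps(blob, indent=2, sort_keys=True) + "\n")

    print(f"\nfirst round, AN vs MT in PD: Fisher p = {site['fisher_p']:.3f}, "
          f"Cramér's V = {site['cramers_v']:.2f}")
    print(f"second round, paired AN vs MT: kappa = {paired['kappa']:.2f} "
          f"(95% CI {paired['kappa_ci'][0]:.2f} to {paired['kappa_ci'][1]:.2f}), "
          f"exact McNemar p = {paired['mcnemar_p']:.3f}")
    print(f"wrote {args.out_dir / 'diagnostics.json'}")


if __name__ == "__main__":
    main()
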