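"""Score band compliance per subject and compare the two etiology groups.

For each subject with documented intent to maintain burst suppression, reports
the percent of intent-period time spent above / within / below the reference
band (BSP 0.8 ± 0.15) and the binary accurate/reliable control labels; then
fits the uniform-prior Beta-binomial posterior for each group's probability of
accurate (reliable) control and the Monte Carlo probability that the aRSE
group is better controlled than the nRSE group.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from bspquant.pipeline import PipelineConfig, compliance_stage


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args(argv)

    cfg = PipelineConfig(seed=args.seed)
    manifest = pd.read_csv(args.cohort / "subjects" / "subjects.tsv", sep="\t")
    table = compliance_stage(cfg, manifest, args.cohort / "subjects", args.out)
    print(table.to_string(index=False, float_format="%.1f"))
    print(f"\nmedian PTi {table['PTi'].median():.0f}%  "
          f"PTa {table['PTa'].median():.0f}%  PTb {table['PTb'].median():.0f}%")
    print("\ngroup posteriors:")
    print(pd.read_csv(args.out / "group_report.tsv", sep="\t", comment="#")
          .to_string(index=False, float_format="%.3f"))
    cmp_path = args.out / "group_comparison.tsv"
    if cmp_path.exists():
        print(pd.read_csv(cmp_path, sep="\t", comment="#")
              .to_string(index=False, float_format="%.3f"))


if __name__ == "__main__":
    sys.exit(main())
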