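"""Segment each subject's EEG into a global binary burst/suppression signal.

Applies the preprocessing chain — >500 µV epoch rejection, 0.5–55 Hz zero-phase
band-pass, average montage — then per-channel envelope binarization and a
cross-channel majority vote, and writes per-epoch suppressed/valid counts for
the BSP stage.
"""

import argparse
import sys
import time
from pathlib import Path

import pandas as pd

from bspquant.pipeline import PipelineConfig, segment_subject


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args(argv)

    cfg = PipelineConfig()
    manifest = pd.read_csv(args.cohort / "subjects" / "subjects.tsv", sep="\t")
    for sid in manifest["subject_id"]:
        t0 = time.time()
        segment_subject(cfg, args.cohort / "subjects" / sid, args.out / sid)
        counts = pd.read_csv(args.out / sid / "counts.tsv", sep="\t", comment="#")
        missing = int((counts["n_valid_samples"] == 0).sum())
        frac = counts["n_suppressed_samples"].sum() / counts["n_valid_samples"].sum()
        print(f"{sid}: {len(counts)} epochs, {missing} rejected, "
              f"suppressed fraction {frac:.3f} ({time.time() - t0:.0f} s)")


if __name__ == "__main__":
    sys.exit(main())
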