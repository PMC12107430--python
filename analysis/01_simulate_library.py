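"""Simulate a doped single-mutant library SMARTI time course.

Generates a desk-scale but structurally faithful dataset: two replicates of
a doped single-mutant library at the study doping rate (0.6% per
alternative base), seven timepoints from 0 to 60 min, 20,000 reads per
sample. To keep per-variant coverage meaningful at this depth, the
mutagenized window is narrowed to the 20 positions around pseudoknot III
(6096-6115) — the full 188-position library needs study-scale sequencing
depth for per-variant kinetics. Most variants sit at the wild-type truth
(amplitude 18%, k 0.15/min); variants of known character — improved,
impaired, and nearly dead — carry their own truths so the downstream
fitting has signal to recover.

FASTQ goes to scratch/analysis/fastq (regenerable bulk data); the truth
table and sample sheet go to results/.
"""
import pathlib
import sys

import pandas as pd

from smarti.reference import LibraryDesign, WILD_TYPE, parse_variant_label
from smarti.report import simulate_dataset
from smarti.simulate import KineticTruth, TruthSet, synthetic_reference

ROOT = pathlib.Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2024

DEMO_DESIGN = LibraryDesign("pkiii_window", ((6096, 6115),), 0.006)

# amplitude (% cleaved), k (1/min) — wild-type default plus variants with
# improved, impaired, and abolished loading
TRUTHS = {
    "WT": (18.0, 0.15),
    "U6101A": (27.0, 0.15),   # improved plateau, wild-type rate
    "A6102U": (21.6, 0.165),  # mildly improved
    "G6103C": (9.0, 0.06),    # impaired plateau and rate
    "G6104A": (1.8, 0.05),    # effectively nonfunctional
}


def main() -> None:
    reference = synthetic_reference(0)
    truths = {}
    for label, (amp, k) in TRUTHS.items():
        key = parse_variant_label(label, reference)
        truths[key] = KineticTruth(key, Y0=0.0, amplitude=amp, k=k)
    truth_set = TruthSet(truths=truths, default=truths[WILD_TYPE])

    out = ROOT / "scratch" / "analysis" / "fastq"
    sheet = simulate_dataset(
        reference, DEMO_DESIGN, truth_set, out, master_seed=SEED,
        replicates=("rep1", "rep2"), n_reads=20_000,
    )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    sheet.to_csv(results / "sample_sheet.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"variant": v, "amplitude_truth": a, "k_truth": k} for v, (a, k) in TRUTHS.items()]
    ).to_csv(results / "analysis_truths.tsv", sep="\t", index=False)

    print(f"simulated {len(sheet)} samples ({sheet['replicate'].nunique()} replicates, "
          f"{sheet['time_min'].nunique()} timepoints, 20000 reads each) with seed {SEED}")
    print(f"sample sheet -> {results / 'sample_sheet.tsv'}")
    print(f"truth table  -> {results / 'analysis_truths.tsv'}")


if __name__ == "__main__":
    main()
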