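"""Build the result surfaces: amplitude heatmap, fold-change scatter, and a
normalized dual-luciferase example.

The heatmap table holds the replicate-averaged amplitude for every
(position, alternative base) cell of the single-mutant design that passed
the amplitude filter; the scatter table pairs each variant's amplitude and
rate fold changes. The luciferase table demonstrates ratio normalization to
wild type with propagated error on synthetic triplicates.
"""
import pathlib

import pandas as pd

from smarti.kinetics import FilterConfig, KineticFit, filter_amplitude
from smarti.reference import LibraryDesign
from smarti.report import (
    LuciferaseTriplicate,
    fold_changes_vs_wt,
    heatmap_table,
    luciferase_normalize,
    scatter_table,
)
from smarti.simulate import synthetic_reference

ROOT = pathlib.Path(__file__).resolve().parents[1]

DEMO_DESIGN = LibraryDesign("pkiii_window", ((6096, 6115),), 0.006)

# synthetic triplicates: a wild type, an improved mutant, and a near-dead one
LUC_SAMPLES = [
    LuciferaseTriplicate("WT", (0.92, 1.00, 1.08)),
    LuciferaseTriplicate("U6101A", (1.00, 1.09, 1.20)),
    LuciferaseTriplicate("G6104A", (0.07, 0.08, 0.09)),
]


def main() -> None:
    results = ROOT / "results"
    reference = synthetic_reference(0)
    design = DEMO_DESIGN
    cfg = FilterConfig()

    fits_df = pd.read_csv(results / "fits.tsv", sep="\t")
    fits = [
        KineticFit(
            r.variant, r.replicate, r.Y0, r.amplitude, r.k,
            r.sd_Y0, r.sd_amplitude, r.sd_k,
            converged=bool(r.converged), k_reliable=bool(r.k_reliable),
            fallback_amplitude=None if pd.isna(r.fallback_amplitude) else r.fallback_amplitude,
            n_points=int(r.n_points),
        )
        for r in fits_df.itertuples()
    ]

    amp_kept = filter_amplitude(fits, cfg)
    heat = heatmap_table(amp_kept, reference, design)
    heat.to_csv(results / "heatmap.tsv", sep="\t", index=False)
    filled = int(heat[list("ACGU")].notna().to_numpy().sum())
    print(f"heatmap: {len(heat)} positions, {filled} filled cells "
          f"(max {3 * len(heat)}) -> {results / 'heatmap.tsv'}")

    folds = fold_changes_vs_wt(fits, cfg)
    scatter = scatter_table(folds)
    scatter.to_csv(results / "scatter.tsv", sep="\t", index=False)
    print(f"scatter: {len(scatter)} variants with both folds detectable "
          f"-> {results / 'scatter.tsv'}")

    luc = luciferase_normalize(LUC_SAMPLES, "WT")
    luc.to_csv(results / "luciferase.tsv", sep="\t", index=False)
    print("luciferase (synthetic triplicates):")
    for row in luc.itertuples():
        print(f"  {row.label:<8} {row.normalized:.2f} ± {row.propagated_error:.2f}")


if __name__ == "__main__":
    main()
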