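"""Result surfaces and pipeline orchestration.

Produces the analysis's reportable tables — the single-mutant amplitude
heatmap table, the fold-change scatter table, and normalized dual-luciferase
activities — and wires the whole simulate → process → quantify → fit →
report chain behind one entry point. Outputs are plain TSV tables
(plotting-ready) rather than rendered figures.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import kinetics, quantify
from .kinetics import FilterConfig, KineticFit, fits_to_frame
from .readproc import process_fastq
from .reference import (
    LibraryDesign,
    ReferenceConstruct,
    design_from_dict,
    load_reference,
    parse_variant_label,
    positions_of,
    study_designs,
)
from .simulate import (
    DEFAULT_TIMEPOINTS,
    AdapterSpec,
    KineticTruth,
    TimepointSample,
    TruthSet,
    derive_seed,
    simulate_timepoint_fastq,
    synthetic_reference,
)

logger = logging.getLogger("smarti")

_ALT_COLUMNS = ("A", "C", "G", "U")


def heatmap_table(
    fits: Iterable[KineticFit],
    reference: ReferenceConstruct,
    design: LibraryDesign,
) -> pd.DataFrame:
    """Position-by-alternative matrix of replicate-averaged amplitude.

    Input fits must already be amplitude-filtered single-mutant fits
    (fallback amplitudes included). One row per design position with the
    wild-type base marked; cells without any passing fit stay NaN, and the
    wild-type base's own cell is always NaN.
    """
    cells: dict[tuple[int, str], list[float]] = {}
    for f in fits:
        key = parse_variant_label(f.variant, reference)
        if key.n_substitutions != 1:
            continue
        (pos, _ref, alt) = key.substitutions[0]
        amp = f.effective_amplitude
        if amp is not None:
            cells.setdefault((pos, alt), []).append(amp)
    rows = []
    for pos in positions_of(design):
        row: dict = {"position": pos, "wt_base": reference.base_at(pos)}
        for alt in _ALT_COLUMNS:
            vals = cells.get((pos, alt))
            row[alt] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["position", "wt_base", *_ALT_COLUMNS])


def scatter_table(fold_records: Iterable[kinetics.FoldChangeRecord]) -> pd.DataFrame:
    """Tidy (variant, mean fold amplitude, mean fold k) rows for variants
    whose amplitude and rate folds are both detectable; the wild-type row is
    (1, 1) by construction."""
    rows = [
        {
            "variant": r.variant,
            "mean_fold_amplitude": r.mean_fold_amplitude,
            "mean_fold_k": r.mean_fold_k,
        }
        for r in fold_records
        if r.amplitude_detectable and r.rate_detectable
    ]
    return pd.DataFrame(rows, columns=["variant", "mean_fold_amplitude", "mean_fold_k"])


@dataclass(frozen=True)
class LuciferaseTriplicate:
    """Replicate Fluc/Rluc ratio measurements for one construct."""

    label: str
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ratios) < 1 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive and non-empty")


def luciferase_normalize(
    samples: Sequence[LuciferaseTriplicate], wt_label: str = "WT"
) -> pd.DataFrame:
    """Normalize mean Fluc/Rluc ratios to wild type with propagated error.

    For sample mean m and SD s, the normalized activity is v = m / m_wt with
    error v * sqrt((s/m)^2 + (s_wt/m_wt)^2) (relative errors in quadrature).
    """
    by_label = {s.label: s for s in samples}
    if wt_label not in by_label:
        raise ValueError(f"wild-type label {wt_label!r} missing")
    stats = {}
    for s in samples:
        m = float(np.mean(s.ratios))
        if m <= 0:
            raise ValueError(f"nonpositive mean ratio for {s.label!r}")
        sd = float(np.std(s.ratios, ddof=1)) if len(s.ratios) >= 2 else float("nan")
        stats[s.label] = (m, sd)
    m_wt, s_wt = stats[wt_label]
    rows = []
    for s in samples:
        m, sd = stats[s.label]
        v = m / m_wt
        err = v * np.sqrt((sd / m) ** 2 + (s_wt / m_wt) ** 2)
        rows.append(
            {
                "label": s.label,
                "mean_ratio": m,
                "sd_ratio": sd,
                "normalized": v,
                "propagated_error": float(err),
                "n": len(s.ratios),
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "mean_ratio", "sd_ratio", "normalized", "propagated_error", "n"]
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(
    reference: ReferenceConstruct,
    design: LibraryDesign | None,
    truths: TruthSet,
    out_dir,
    master_seed: int,
    replicates: Sequence[str] = ("rep1", "rep2"),
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    n_reads: int = 20000,
    adapter: AdapterSpec | None = None,
    variant_mix: dict | None = None,
    error_rate: float = 0.0,
    write_truth: bool = False,
) -> pd.DataFrame:
    """Simulate a demultiplexed FASTQ dataset and return its sample sheet
    (columns ``replicate``, ``time_min``, ``fastq``, ``seed``). Each sample's
    seed derives deterministically from the master seed."""
    adapter = adapter or AdapterSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mix = None
    if variant_mix is not None:
        mix = [
            (parse_variant_label(label, reference), int(n))
            for label, n in variant_mix.items()
        ]
    rows = []
    for rep in replicates:
        for t in timepoints:
            seed = derive_seed(master_seed, rep, f"t{t:g}")
            sample = TimepointSample(rep, float(t), int(n_reads), seed)
            fastq = out_dir / f"{rep}_t{t:g}.fastq"
            truth = out_dir / f"{rep}_t{t:g}.truth.tsv" if write_truth else None
            simulate_timepoint_fastq(
                reference, design, truths, sample, adapter,
                out_fastq=fastq, truth_tsv=truth,
                variant_mix=mix, error_rate=error_rate,
            )
            rows.append(
                {"replicate": rep, "time_min": float(t), "fastq": str(fastq), "seed": seed}
            )
    sheet = pd.DataFrame(rows, columns=["replicate", "time_min", "fastq", "seed"])
    sheet.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
    return sheet


def process_samples(
    sample_sheet: pd.DataFrame,
    reference: ReferenceConstruct,
    adapter: AdapterSpec | None = None,
    max_mutations: int = 2,
    dedup_umi: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Process every sample in a sheet; returns the tidy count table and the
    pooled discard statistics."""
    adapter = adapter or AdapterSpec()
    per_sample = []
    discards: dict[str, int] = {}
    for row in sample_sheet.itertuples():
        res = process_fastq(
            row.fastq, reference, adapter,
            max_mutations=max_mutations, dedup_umi=dedup_umi,
        )
        per_sample.append((row.replicate, row.time_min, res.counts))
        for reason, n in res.discards.items():
            discards[reason] = discards.get(reason, 0) + n
    return quantify.aggregate_counts(per_sample), discards


def fit_all(
    pct_table: pd.DataFrame,
    weight_binomial: bool = False,
    bootstrap: int = 0,
    seed: int | None = None,
) -> list[KineticFit]:
    """Fit every (variant, replicate) time course in a percent-cleaved
    table."""
    fits = []
    pairs = pct_table[["variant", "replicate"]].drop_duplicates().itertuples(index=False)
    for variant, replicate in pairs:
        tc = quantify.time_course(pct_table, variant, replicate)
        if len(tc) < 2:
            continue
        fits.append(
            kinetics.fit_one_phase(
                tc, variant=variant, replicate_id=replicate,
                weight_binomial=weight_binomial, bootstrap=bootstrap, seed=seed,
            )
        )
    return fits


def fold_changes_vs_wt(
    fits: Iterable[KineticFit], cfg: FilterConfig | None = None, wt_label: str = "WT"
) -> list[kinetics.FoldChangeRecord]:
    """Fold-change records for every variant against the wild type."""
    cfg = cfg or FilterConfig()
    by_variant: dict[str, list[KineticFit]] = {}
    for f in fits:
        by_variant.setdefault(f.variant, []).append(f)
    wt_fits = by_variant.get(wt_label, [])
    if not wt_fits:
        raise ValueError(f"no wild-type ({wt_label!r}) fits present")
    return [
        kinetics.fold_change(vfits, wt_fits, cfg)
        for variant, vfits in sorted(by_variant.items())
    ]


def folds_to_frame(records: Iterable[kinetics.FoldChangeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "variant": r.variant,
                "mean_fold_amplitude": r.mean_fold_amplitude,
                "sd_fold_amplitude": r.sd_fold_amplitude,
                "mean_fold_k": r.mean_fold_k,
                "sd_fold_k": r.sd_fold_k,
                "n_replicates": r.n_replicates,
                "n_amplitude": r.n_amplitude,
                "n_rate": r.n_rate,
                "amplitude_detectable": r.amplitude_detectable,
                "rate_detectable": r.rate_detectable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant", "mean_fold_amplitude", "sd_fold_amplitude",
            "mean_fold_k", "sd_fold_k", "n_replicates",
            "n_amplitude", "n_rate", "amplitude_detectable", "rate_detectable",
        ],
    )


def _reference_from_config(cfg: dict) -> ReferenceConstruct:
    ref_cfg = cfg.get("reference", {})
    if "fasta" in ref_cfg:
        return load_reference(
            ref_cfg["fasta"],
            genomic_offset=int(ref_cfg["genomic_offset"]),
            cleavage_position=int(ref_cfg["cleavage_position"]),
            first_codon_span=tuple(ref_cfg["first_codon_span"]),
        )
    return synthetic_reference(int(ref_cfg.get("synthetic_seed", 0)))


def _design_from_config(cfg: dict) -> LibraryDesign | None:
    dcfg = cfg.get("design")
    if dcfg is None:
        return None
    if isinstance(dcfg, str):
        designs = study_designs()
        if dcfg not in designs:
            raise ValueError(f"unknown study design {dcfg!r}")
        return designs[dcfg]
    return design_from_dict(dcfg)


def _truths_from_config(cfg: dict, reference: ReferenceConstruct) -> TruthSet:
    tcfg = cfg.get("truths", {})
    def _truth(variant, spec):
        return KineticTruth(
            variant, Y0=float(spec.get("Y0", 0.0)),
            amplitude=float(spec["amplitude"]), k=float(spec["k"]),
        )
    default = None
    if "default" in tcfg:
        default = _truth(parse_variant_label("WT", reference), tcfg["default"])
    truths = {}
    for label, spec in tcfg.get("variants", {}).items():
        key = parse_variant_label(label, reference)
        truths[key] = _truth(key, spec)
    return TruthSet(truths=truths, default=default)


def run_pipeline(config: dict, seed: int, out_dir) -> dict[str, str]:
    """Run simulate → process → quantify → fit → report from a config
    mapping; deterministic given the seed. Returns the written table paths.

    Config keys: ``reference`` (fasta+landmarks or synthetic_seed),
    ``design`` (study design name or mapping), ``truths`` (default +
    per-variant one-phase parameters), ``replicates``, ``timepoints``,
    ``n_reads``, optional ``variant_mix``, ``error_rate``, ``min_total``,
    ``filters``, ``dedup_umi``, ``weight_binomial``, ``bootstrap``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        reference = _reference_from_config(config)
        design = _design_from_config(config)
        truths = _truths_from_config(config, reference)
        if design is None and "variant_mix" not in config:
            raise ValueError("config needs a 'design' or a 'variant_mix'")
        cfg_filters = FilterConfig(**config.get("filters", {}))
        adapter = AdapterSpec(**config.get("adapter", {}))
        logger.info("seed=%d config=%s", seed, json.dumps(config, default=str))

        sheet = simulate_dataset(
            reference, design, truths, out_dir / "fastq", master_seed=seed,
            replicates=config.get("replicates", ("rep1", "rep2")),
            timepoints=config.get("timepoints", DEFAULT_TIMEPOINTS),
            n_reads=int(config.get("n_reads", 20000)),
            adapter=adapter,
            variant_mix=config.get("variant_mix"),
            error_rate=float(config.get("error_rate", 0.0)),
        )
        logger.info("simulated %d samples", len(sheet))

        counts, discards = process_samples(
            sheet, reference, adapter,
            max_mutations=int(config.get("max_mutations", 2)),
            dedup_umi=bool(config.get("dedup_umi", False)),
        )
        logger.info("discards: %s", discards)
        pct = quantify.percent_cleaved_table(
            counts, min_total=int(config.get("min_total", quantify.DEFAULT_MIN_TOTAL))
        )
        fits = fit_all(
            pct,
            weight_binomial=bool(config.get("weight_binomial", False)),
            bootstrap=int(config.get("bootstrap", 0)),
            seed=seed,
        )
        logger.info(
            "fitted %d time courses; amplitude filter passes %d; rate filter passes %d",
            len(fits),
            len(kinetics.filter_amplitude(fits, cfg_filters)),
            len(kinetics.filter_rate(fits, cfg_filters)),
        )
        folds = fold_changes_vs_wt(fits, cfg_filters)

        paths = {"log": str(log_path), "sample_sheet": str(out_dir / "fastq" / "sample_sheet.tsv")}
        pct.to_csv(out_dir / "percent_cleaved.tsv", sep="\t", index=False)
        paths["percent_cleaved"] = str(out_dir / "percent_cleaved.tsv")
        fits_to_frame(fits).to_csv(out_dir / "fits.tsv", sep="\t", index=False)
        paths["fits"] = str(out_dir / "fits.tsv")
        folds_to_frame(folds).to_csv(out_dir / "folds.tsv", sep="\t", index=False)
        paths["folds"] = str(out_dir / "folds.tsv")
        scatter_table(folds).to_csv(out_dir / "scatter.tsv", sep="\t", index=False)
        paths["scatter"] = str(out_dir / "scatter.tsv")
        if design is not None:
            amp_kept = kinetics.filter_amplitude(fits, cfg_filters)
            heatmap_table(amp_kept, reference, design).to_csv(
                out_dir / "heatmap.tsv", sep="\t", index=False
            )
            paths["heatmap"] = str(out_dir / "heatmap.tsv")
        logger.info("wrote %s", sorted(paths))
        return paths
    finally:
        logger.removeHandler(handler)
        handler.close()
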