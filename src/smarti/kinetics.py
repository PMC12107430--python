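"""One-phase association fitting, screening filters, and fold changes.

Each percent-cleaved time course is fit to

    Y = Y0 + amplitude * (1 - exp(-k x))

by bounded nonlinear least squares (Y0 and amplitude in [0, 100] percent,
k > 0 per minute). Parameter SDs come from the asymptotic covariance
(Jacobian-based) by default; a seeded residual bootstrap is available.
Residuals are unweighted — percent values are fitted directly — with
optional binomial weighting by per-point coverage.

Screening uses the strict inequalities of the assay's reporting rules:
amplitudes are reported when sd(amplitude) < 10 percentage points; rate
constants when amplitude > 5%, k < 0.7 min^-1, and sd(k) < k. A variant is
called nonfunctional when its amplitude is below 5% in every replicate.
Fold changes divide the mutant value by the wild-type value within each
replicate and average the per-replicate folds.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

FIT_MAX_ITER = 500
FIT_TOL = 1e-8
_K_INIT = 0.1


def one_phase(x, y0, amplitude, k):
    return y0 + amplitude * (1.0 - np.exp(-k * np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class KineticFit:
    """Fitted one-phase association parameters for one time course."""

    variant: str
    replicate_id: str
    Y0: float
    amplitude: float
    k: float
    sd_Y0: float
    sd_amplitude: float
    sd_k: float
    converged: bool
    k_reliable: bool = True
    fallback_amplitude: float | None = None
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.k > 0 and self.amplitude >= 0 and 0 <= self.Y0 <= 100):
                raise ValueError("converged fit violates parameter bounds")
            if self.fallback_amplitude is not None:
                raise ValueError("fallback_amplitude only applies to unconverged fits")

    @property
    def effective_amplitude(self) -> float | None:
        """Fitted amplitude, or the first-to-last-point fallback when the
        curve could not be fit."""
        return self.amplitude if self.converged else self.fallback_amplitude


@dataclass(frozen=True)
class FilterConfig:
    """Reporting thresholds (strict inequalities as printed)."""

    max_amplitude_sd: float = 10.0  # percentage points
    min_amplitude_for_rate: float = 5.0  # percent
    max_k: float = 0.7  # 1/min
    nonfunctional_cut: float = 5.0  # percent

    def __post_init__(self) -> None:
        if min(self.max_amplitude_sd, self.min_amplitude_for_rate, self.max_k, self.nonfunctional_cut) <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass(frozen=True)
class FoldChangeRecord:
    """Replicate-averaged mutant/wild-type ratios for amplitude and rate."""

    variant: str
    mean_fold_amplitude: float  # NaN when not detectable
    sd_fold_amplitude: float
    mean_fold_k: float
    sd_fold_k: float
    n_replicates: int
    n_amplitude: int = 0
    n_rate: int = 0

    @property
    def amplitude_detectable(self) -> bool:
        return self.n_amplitude > 0

    @property
    def rate_detectable(self) -> bool:
        return self.n_rate > 0


def fallback_amplitude(times: Sequence[float], values: Sequence[float]) -> float:
    """Difference between the last and first time point values, used when a
    curve cannot be fit. Negative results are reported as-is."""
    if len(values) < 2:
        raise ValueError("fallback amplitude needs at least 2 points")
    order = np.argsort(np.asarray(times, dtype=float), kind="stable")
    vals = np.asarray(values, dtype=float)[order]
    return float(vals[-1] - vals[0])


def fit_one_phase(
    timecourse: pd.DataFrame,
    variant: str = "",
    replicate_id: str = "",
    weight_binomial: bool = False,
    bootstrap: int = 0,
    seed: int | None = None,
) -> KineticFit:
    """Fit one time course (columns ``time_min``, ``pct_cleaved``, optional
    ``n_total``).

    Requires at least 4 points including one at time zero; otherwise the fit
    is not attempted and only the fallback amplitude is reported. A constant
    time course yields amplitude 0 with Y0 at that constant; k is then
    unidentifiable and flagged unreliable. The fit is sorted by time first,
    so it is exactly invariant to input point ordering.
    """
    tc = timecourse.sort_values(["time_min", "pct_cleaved"]).reset_index(drop=True)
    x = tc["time_min"].to_numpy(dtype=float)
    y = tc["pct_cleaved"].to_numpy(dtype=float)
    n_points = len(tc)

    def _fallback(reason_k_reliable: bool = False) -> KineticFit:
        fb = fallback_amplitude(x, y) if n_points >= 2 else None
        return KineticFit(
            variant, replicate_id,
            Y0=float("nan"), amplitude=float("nan"), k=float("nan"),
            sd_Y0=float("nan"), sd_amplitude=float("nan"), sd_k=float("nan"),
            converged=False, k_reliable=reason_k_reliable,
            fallback_amplitude=fb, n_points=n_points,
        )

    if n_points < 4 or not np.any(x == 0):
        return _fallback()

    if np.ptp(y) == 0.0:
        # Flat course: amplitude is zero and k drops out of the model.
        return KineticFit(
            variant, replicate_id,
            Y0=float(y[0]), amplitude=0.0, k=_K_INIT,
            sd_Y0=0.0, sd_amplitude=0.0, sd_k=float("inf"),
            converged=True, k_reliable=False, n_points=n_points,
        )

    p0 = [float(np.clip(y[0], 0, 100)), float(np.clip(y[-1] - y[0], 0, 100)), _K_INIT]
    sigma = None
    if weight_binomial and "n_total" in tc:
        n = tc["n_total"].to_numpy(dtype=float)
        p = np.clip(y / 100.0, 1e-6, 1 - 1e-6)
        sigma = 100.0 * np.sqrt(p * (1 - p) / n)
    try:
        popt, pcov = curve_fit(
            one_phase, x, y, p0=p0,
            bounds=([0.0, 0.0, 1e-9], [100.0, 100.0, np.inf]),
            sigma=sigma, absolute_sigma=False,
            maxfev=FIT_MAX_ITER * 10, ftol=FIT_TOL, xtol=FIT_TOL, gtol=FIT_TOL,
        )
    except RuntimeError:
        return _fallback()

    if bootstrap > 0:
        sds = _bootstrap_sds(x, y, popt, bootstrap, seed)
    else:
        with np.errstate(invalid="ignore"):
            sds = np.sqrt(np.diag(pcov))
    y0, amp, k = (float(v) for v in popt)
    return KineticFit(
        variant, replicate_id,
        Y0=y0, amplitude=amp, k=max(k, 1e-9),
        sd_Y0=float(sds[0]), sd_amplitude=float(sds[1]), sd_k=float(sds[2]),
        converged=True, k_reliable=bool(np.isfinite(sds[2])), n_points=n_points,
    )


def _bootstrap_sds(x, y, popt, n_boot: int, seed: int | None) -> np.ndarray:
    """Residual-resampling bootstrap SDs for (Y0, amplitude, k)."""
    rng = np.random.default_rng(seed)
    fitted = one_phase(x, *popt)
    resid = y - fitted
    draws = []
    for _ in range(n_boot):
        yb = np.clip(fitted + rng.choice(resid, size=len(resid), replace=True), 0, 100)
        try:
            pb, _ = curve_fit(
                one_phase, x, yb, p0=popt,
                bounds=([0.0, 0.0, 1e-9], [100.0, 100.0, np.inf]),
                maxfev=FIT_MAX_ITER * 10,
            )
            draws.append(pb)
        except RuntimeError:
            continue
    if len(draws) < 2:
        return np.full(3, np.nan)
    return np.std(np.asarray(draws), axis=0, ddof=1)


def filter_amplitude(
    fits: Iterable[KineticFit], cfg: FilterConfig, include_fallback: bool = True
) -> list[KineticFit]:
    """Fits whose amplitude is reportable: converged with
    sd(amplitude) < ``max_amplitude_sd`` (strict), plus — for the amplitude
    surface — unconverged fits carrying a fallback amplitude."""
    kept = []
    for f in fits:
        if f.converged:
            if f.sd_amplitude < cfg.max_amplitude_sd:
                kept.append(f)
        elif include_fallback and f.fallback_amplitude is not None:
            kept.append(f)
    return kept


def filter_rate(fits: Iterable[KineticFit], cfg: FilterConfig) -> list[KineticFit]:
    """Fits whose rate constant is reportable: amplitude > 5%, k < 0.7/min,
    and sd(k) < k (all strict)."""
    return [
        f
        for f in fits
        if f.converged
        and f.amplitude > cfg.min_amplitude_for_rate
        and f.k < cfg.max_k
        and f.sd_k < f.k
    ]


def call_nonfunctional(
    fits_by_replicate: dict[str, KineticFit], cfg: FilterConfig
) -> bool | None:
    """True when the variant's amplitude is below ``nonfunctional_cut`` in
    every replicate; ``None`` (indeterminate) with fewer than 2 replicates."""
    if len(fits_by_replicate) < 2:
        return None
    amps = [f.effective_amplitude for f in fits_by_replicate.values()]
    if any(a is None for a in amps):
        return None
    return all(a < cfg.nonfunctional_cut for a in amps)


def fold_change(
    mutant_fits: Iterable[KineticFit],
    wt_fits: Iterable[KineticFit],
    cfg: FilterConfig | None = None,
) -> FoldChangeRecord:
    """Replicate-paired mutant/wild-type fold changes.

    For each replicate present in both fit sets, the amplitude fold is
    computed when both fits pass the amplitude filter and the rate fold when
    both pass the rate filter; per-replicate folds are then averaged (SD
    with ddof=1 over >=2 folds). Replicates where the wild-type value is
    zero are excluded. A parameter with no passing replicate is reported as
    NaN — "not detectable".
    """
    cfg = cfg or FilterConfig()
    mut = {f.replicate_id: f for f in mutant_fits}
    wt = {f.replicate_id: f for f in wt_fits}
    shared = sorted(set(mut) & set(wt))
    variant = next(iter(mut.values())).variant if mut else ""

    amp_pass_m = {f.replicate_id for f in filter_amplitude(mut.values(), cfg)}
    amp_pass_w = {f.replicate_id for f in filter_amplitude(wt.values(), cfg)}
    rate_pass_m = {f.replicate_id for f in filter_rate(mut.values(), cfg)}
    rate_pass_w = {f.replicate_id for f in filter_rate(wt.values(), cfg)}

    amp_folds, k_folds = [], []
    for rep in shared:
        if rep in amp_pass_m and rep in amp_pass_w:
            wt_amp = wt[rep].effective_amplitude
            mut_amp = mut[rep].effective_amplitude
            if wt_amp:  # zero wild-type value leaves the fold undefined
                amp_folds.append(mut_amp / wt_amp)
        if rep in rate_pass_m and rep in rate_pass_w:
            if wt[rep].k:
                k_folds.append(mut[rep].k / wt[rep].k)

    def _mean_sd(folds: list[float]) -> tuple[float, float]:
        if not folds:
            return float("nan"), float("nan")
        mean = float(np.mean(folds))
        sd = float(np.std(folds, ddof=1)) if len(folds) >= 2 else float("nan")
        return mean, sd

    mean_a, sd_a = _mean_sd(amp_folds)
    mean_k, sd_k = _mean_sd(k_folds)
    return FoldChangeRecord(
        variant=variant,
        mean_fold_amplitude=mean_a,
        sd_fold_amplitude=sd_a,
        mean_fold_k=mean_k,
        sd_fold_k=sd_k,
        n_replicates=len(shared),
        n_amplitude=len(amp_folds),
        n_rate=len(k_folds),
    )


def fits_to_frame(fits: Iterable[KineticFit]) -> pd.DataFrame:
    """Fixed-column tidy table of fits (the per-variant fit table)."""
    rows = []
    for f in fits:
        rows.append(
            {
                "variant": f.variant,
                "replicate": f.replicate_id,
                "Y0": f.Y0,
                "amplitude": f.amplitude,
                "k": f.k,
                "sd_Y0": f.sd_Y0,
                "sd_amplitude": f.sd_amplitude,
                "sd_k": f.sd_k,
                "converged": f.converged,
                "k_reliable": f.k_reliable,
                "fallback_amplitude": f.fallback_amplitude,
                "n_points": f.n_points,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant", "replicate", "Y0", "amplitude", "k",
            "sd_Y0", "sd_amplitude", "sd_k",
            "converged", "k_reliable", "fallback_amplitude", "n_points",
        ],
    )
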