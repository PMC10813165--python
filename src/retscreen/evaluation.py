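"""Validation experiments: recovery, calibration, power and oracle checks.

Each function here re-runs part of the pipeline from scratch on seeded
synthetic inputs and returns the measured quantity.  They are shared by
the test suite and by ``scripts/acceptance.py``, which reports their
outputs.  Brute-force oracles in this module are deliberately written
as independent (slow, per-pixel / per-grid-point) implementations of
the things they check.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AcquisitionSpec
from .decompose import DecomposeConfig, decompose, decompose_cohort, fit_p3, p3_sse_objective
from .oct import ThicknessMap, etdrs_quadrant_means
from .stats import mixed_anova, mixed_anova_wide, normalize_to_baseline, rout_outliers
from .synthetic import (
    CohortDesign,
    WaveformModelParams,
    simulate_cohort,
    simulate_cohort_amplitudes,
    simulate_waveform,
)

__all__ = [
    "filter_contract",
    "recovery_errors",
    "noiseless_recovery_errors",
    "grid_oracle_gap",
    "null_anova_rejection_rates",
    "cohort_effect_recovery",
    "ensemble_normalized_means",
    "interaction_power_within_hom",
    "rout_gross_outlier_detection_rate",
    "rout_false_flag_rate",
    "etdrs_brute_force",
    "etdrs_oracle_max_deviation",
]


# ---------------------------------------------------------------------------
# Filters


def filter_contract() -> dict[str, float]:
    """Computed magnitude responses at the contractual frequencies."""
    from .filters import lowpass_transfer

    acq = AcquisitionSpec()
    g_acq = acq.band_gain([0.3, 1000.0])
    return {
        "p2_lowpass_gain_dc": float(lowpass_transfer(0.0, 46.9)),
        "p2_lowpass_gain_46p9": float(lowpass_transfer(46.9, 46.9)),
        "acq_bandpass_gain_0p3": float(g_acq[0]),
        "acq_bandpass_gain_1000": float(g_acq[1]),
    }


# ---------------------------------------------------------------------------
# Parameter recovery


def recovery_errors(n_waveforms: int = 100, seed: int = 0) -> pd.DataFrame:
    """Percent recovery errors on seeded noisy waveforms with varied amplitudes."""
    rng = np.random.default_rng(seed)
    base = WaveformModelParams()
    acq = AcquisitionSpec()
    cfg = DecomposeConfig()
    rows = []
    for i in range(n_waveforms):
        u = float(rng.lognormal(mean=0.0, sigma=0.2))
        rm_true = base.p3.rm_p3_uV * u
        p2_true = base.p2_amp_uV * u
        params = replace(
            base,
            p3=replace(base.p3, rm_p3_uV=rm_true),
            p2_amp_uV=p2_true,
            op_atoms=tuple((c, f, a * u, w) for c, f, a, w in base.op_atoms),
        )
        w = simulate_waveform(params, acq=acq, seed=rng)
        p3, p2 = decompose(w, cfg)
        rows.append(
            {
                "rm_err_pct": 100.0 * (p3.rm_p3_uV - rm_true) / rm_true,
                "p2_err_pct": 100.0 * (p2.peak_amplitude_uV - p2_true) / p2_true,
            }
        )
    return pd.DataFrame(rows)


def noiseless_recovery_errors(seed: int = 0) -> dict[str, float]:
    """Percent errors on a noise-free record (systematic distortion only)."""
    params = replace(WaveformModelParams(), noise_sd_uV=0.0)
    w = simulate_waveform(params, seed=seed)
    p3, p2 = decompose(w)
    return {
        "rm_err_pct": 100.0 * (p3.rm_p3_uV - params.p3.rm_p3_uV) / params.p3.rm_p3_uV,
        "p2_err_pct": 100.0 * (p2.peak_amplitude_uV - params.p2_amp_uV) / params.p2_amp_uV,
    }


def grid_oracle_gap(n_fixtures: int = 20, seed: int = 0) -> pd.DataFrame:
    """Refined-fit SSE against an exhaustive coarse-grid search on the same objective.

    The grid spans rm 100-800 uV (15 points), S 20-2000 (15 log points)
    and td 2-8 ms (7 points); the optimiser must do at least as well.
    """
    rng = np.random.default_rng(seed)
    base = WaveformModelParams()
    acq = AcquisitionSpec()
    rm_grid = np.linspace(100.0, 800.0, 15)
    s_grid = np.logspace(np.log10(20.0), np.log10(2000.0), 15)
    td_grid = np.arange(2.0, 9.0) / 1000.0
    rows = []
    for i in range(n_fixtures):
        params = replace(
            base,
            p3=replace(
                base.p3,
                rm_p3_uV=float(rng.uniform(250, 550)),
                sensitivity_S=float(rng.uniform(80, 600)),
                t_delay_s=float(rng.uniform(0.002, 0.008)),
            ),
        )
        w = simulate_waveform(params, acq=acq, seed=rng)
        fit = fit_p3(w, acq=acq)
        residuals, window = p3_sse_objective(w, acq=acq)
        best_grid = np.inf
        for rm in rm_grid:
            for s in s_grid:
                for td in td_grid:
                    sse = float(np.sum(residuals(np.array([rm, s, td])) ** 2))
                    if sse < best_grid:
                        best_grid = sse
        rows.append({"refined_sse": fit.sse, "grid_sse": best_grid})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA calibration and power


def null_anova_rejection_rates(
    n_reps: int = 2000,
    seed: int = 0,
    n_per_group: int = 10,
    n_timepoints: int = 7,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the mixed ANOVA under a compound-symmetric null."""
    rng = np.random.default_rng(seed)
    labels = ["a"] * n_per_group + ["b"] * n_per_group
    rej_inter = rej_between = 0
    for _ in range(n_reps):
        subj = rng.standard_normal((2 * n_per_group, 1))
        y = subj + rng.standard_normal((2 * n_per_group, n_timepoints))
        res = mixed_anova_wide(y, labels)
        rej_inter += res.effects["interaction"].p < alpha
        rej_between += res.effects["between"].p < alpha
    return {
        "interaction_rate": rej_inter / n_reps,
        "between_rate": rej_between / n_reps,
    }


def _truth_to_measure_table(truth: pd.DataFrame, col: str = "p2_amp_true_uV") -> pd.DataFrame:
    return truth.rename(columns={col: "value"}).assign(measure="amp")[
        ["subject_id", "genotype", "treatment", "time_min", "measure", "value"]
    ]


def cohort_effect_recovery(seed: int = 0) -> pd.DataFrame:
    """Full waveform->decomposition->normalisation pipeline on one default cohort.

    Returns per-group normalised 30-min group means +/- SEM for both
    measures, next to the generating growth target.
    """
    design = CohortDesign(seed=seed)
    waves, truth = simulate_cohort(design)
    dec = decompose_cohort(waves)
    long = dec.melt(
        id_vars=["subject_id", "genotype", "treatment", "time_min"],
        value_vars=["rm_p3_uV", "p2_peak_uV"],
        var_name="measure",
        value_name="value",
    ).dropna(subset=["value"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = normalize_to_baseline(long)
    end_t = max(design.timepoints_min)
    rows = []
    for (geno, treat, meas), g in norm[norm.time_min == end_t].groupby(
        ["genotype", "treatment", "measure"]
    ):
        group = f"{geno}_{treat}"
        rows.append(
            {
                "group": group,
                "measure": meas,
                "mean_norm": g["value"].mean(),
                "sem": g["value"].std(ddof=1) / np.sqrt(len(g)),
                "n": len(g),
                "target": 100.0 * design.growth_end[group],
            }
        )
    return pd.DataFrame(rows)


def ensemble_normalized_means(n_cohorts: int = 200, seed: int = 0) -> pd.DataFrame:
    """Amplitude-level ensemble bias check of normalised 30-min group means."""
    acc: dict[str, list[float]] = {}
    sems: dict[str, list[float]] = {}
    for i in range(n_cohorts):
        design = CohortDesign(seed=seed + i)
        truth = simulate_cohort_amplitudes(design)
        tab = _truth_to_measure_table(truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = normalize_to_baseline(tab)
        end = norm[norm.time_min == max(design.timepoints_min)]
        for (geno, treat), g in end.groupby(["genotype", "treatment"]):
            grp = f"{geno}_{treat}"
            acc.setdefault(grp, []).append(g["value"].mean())
            sems.setdefault(grp, []).append(g["value"].std(ddof=1) / np.sqrt(len(g)))
    design = CohortDesign()
    rows = []
    for grp, means in acc.items():
        rows.append(
            {
                "group": grp,
                "ensemble_mean": float(np.mean(means)),
                "typical_sem": float(np.mean(sems[grp])),
                "target": 100.0 * design.growth_end[grp],
            }
        )
    return pd.DataFrame(rows)


def interaction_power_within_hom(
    n_cohorts: int = 500,
    seed: int = 0,
    alpha: float = 0.01,
) -> float:
    """Fraction of simulated cohorts whose within-HOM time x treatment interaction
    on baseline-normalised amplitudes is significant at ``alpha``."""
    rej = 0
    for i in range(n_cohorts):
        design = CohortDesign(seed=seed + i)
        truth = simulate_cohort_amplitudes(design)
        hom = truth[truth.genotype == "HOM"]
        tab = _truth_to_measure_table(hom)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = normalize_to_baseline(tab)
        res = mixed_anova(norm, "amp", between="treatment")
        rej += res.effects["interaction"].p < alpha
    return rej / n_cohorts


# ---------------------------------------------------------------------------
# ROUT behaviour


def rout_gross_outlier_detection_rate(n_reps: int = 200, seed: int = 0) -> float:
    """Detection rate of a single gross (>10 robust SD) outlier in clean data."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        v = rng.standard_normal(12)
        v = np.append(v, 20.0)  # ~20 robust SDs from the centre
        rep = rout_outliers(v, q=0.01)
        hits += (len(v) - 1) in rep.flagged
    return hits / n_reps


def rout_false_flag_rate(n_reps: int = 2000, seed: int = 0, n: int = 12) -> float:
    """Fraction of clean Gaussian vectors with at least one flagged point."""
    rng = np.random.default_rng(seed)
    flagged = 0
    for _ in range(n_reps):
        rep = rout_outliers(rng.standard_normal(n), q=0.01)
        flagged += not rep.is_empty
    return flagged / n_reps


# ---------------------------------------------------------------------------
# ETDRS oracle


def etdrs_brute_force(m: ThicknessMap, diameters=(1.0, 3.0, 6.0)) -> dict[str, float]:
    """Independent per-pixel double-loop computation of the quadrant means."""
    sums = {q: 0.0 for q in ("superior", "inferior", "nasal", "temporal")}
    counts = {q: 0 for q in sums}
    nr, nc = m.grid.shape
    for r in range(nr):
        for c in range(nc):
            dy = (r - m.centre_px[0]) * m.pitch_mm[0]
            dx = (c - m.centre_px[1]) * m.pitch_mm[1]
            dist = (dx * dx + dy * dy) ** 0.5
            if not (diameters[1] / 2.0 <= dist < diameters[2] / 2.0):
                continue
            x = dx if m.eye == "OD" else -dx
            theta = np.degrees(np.arctan2(-dy, x)) % 360.0
            if 45.0 <= theta < 135.0:
                q = "superior"
            elif 135.0 <= theta < 225.0:
                q = "temporal"
            elif 225.0 <= theta < 315.0:
                q = "inferior"
            else:
                q = "nasal"
            v = m.grid[r, c]
            if not np.isnan(v):
                sums[q] += v
                counts[q] += 1
    return {q: (sums[q] / counts[q] if counts[q] else float("nan")) for q in sums}


def etdrs_oracle_max_deviation(n_maps: int = 20, seed: int = 0) -> float:
    """Largest |vectorised - brute force| quadrant mean over random maps (um)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_maps):
        n = int(rng.integers(60, 110))
        grid = rng.uniform(150.0, 300.0, size=(n, n))
        grid[rng.random(grid.shape) < 0.05] = np.nan
        pitch = float(rng.uniform(0.05, 0.12))
        centre = (n / 2 + float(rng.uniform(-3, 3)), n / 2 + float(rng.uniform(-3, 3)))
        m = ThicknessMap(grid, (pitch, pitch), centre, eye="OD")
        fast = etdrs_quadrant_means(m).quadrant_means_um
        slow = etdrs_brute_force(m)
        for q in slow:
            if np.isnan(slow[q]) and np.isnan(fast[q]):
                continue
            worst = max(worst, abs(fast[q] - slow[q]))
    return worst
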