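"""Seeded synthetic cohorts: scotopic flash ERG waveforms and OCT thickness tables.

The waveform generator builds each record as an additive sum of the
components the decomposition is meant to separate —

* a delayed-Gaussian photoreceptoral P3 (negative, saturating at -RmP3),
* an ON-bipolar P2 modelled as a unit-peak gamma kernel (peak ~80 ms),
* oscillatory potentials as Gabor bursts at 100-140 Hz over 15-40 ms,
* optional slow drift, plus white Gaussian noise,

then passes the sum through the acquisition band-pass (0.3-1000 Hz,
zero phase).  Cohorts follow a four-group repeated-measures design
(WT/HOM x VEH/L-DOPA, baseline then every 5 min to 30 min) with
per-subject baseline scalers, per-subject drug-response slopes and
per-record physiological jitter; every record's true component
amplitudes are returned in a ground-truth table so recovery can be
tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AcquisitionSpec, ERGWaveform, GROUPS
from .decompose import P3Params, p3_model_trace

__all__ = [
    "WaveformModelParams",
    "CohortDesign",
    "OCTLayerSpec",
    "OCTCohortDesign",
    "OCT_LAYERS",
    "gamma_kernel",
    "generative_components",
    "simulate_waveform",
    "simulate_cohort",
    "simulate_cohort_amplitudes",
    "simulate_oct_cohort",
]

OCT_LAYERS = ("RNFL", "GCIPL", "INL", "OPL", "ONL", "TRT")

_DEFAULT_OPS = (
    (0.024, 110.0, 40.0, 0.004),
    (0.032, 125.0, 28.0, 0.004),
    (0.040, 135.0, 18.0, 0.004),
)


@dataclass(frozen=True)
class WaveformModelParams:
    """Generative parameters of one synthetic flash ERG.

    ``op_atoms`` are Gabor bursts (center_s, freq_Hz, amp_uV, width_s)
    standing in for the oscillatory potentials; their frequencies must
    lie in the 60-200 Hz OP band so that the 46.9 Hz P2 low-pass can
    remove them.
    """

    p3: P3Params = P3Params(rm_p3_uV=400.0, sensitivity_S=250.0, t_delay_s=0.004)
    p2_amp_uV: float = 600.0
    p2_tau_s: float = 0.018
    p2_shape: int = 6
    op_atoms: Sequence[tuple[float, float, float, float]] = _DEFAULT_OPS
    drift_amp_uV: float = 0.0
    noise_sd_uV: float = 10.0
    drift_freq_hz: float = 0.8

    def __post_init__(self) -> None:
        for name in ("p2_amp_uV", "p2_tau_s", "drift_amp_uV", "noise_sd_uV"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for field {name!r}")
        if self.p2_amp_uV < 0:
            raise ValueError("p2_amp_uV must be non-negative")
        if self.p2_tau_s <= 0:
            raise ValueError("p2_tau_s must be positive")
        if self.p2_shape < 2:
            raise ValueError("p2_shape must be an integer >= 2")
        if self.noise_sd_uV < 0:
            raise ValueError("noise_sd_uV must be non-negative")
        for atom in self.op_atoms:
            c, f, a, w = atom
            if not all(np.isfinite(x) for x in atom):
                raise ValueError("non-finite value in field 'op_atoms'")
            if not (60.0 <= f <= 200.0):
                raise ValueError(f"OP atom frequency {f} Hz outside the 60-200 Hz band")
            if w <= 0:
                raise ValueError("OP atom width must be positive")


def gamma_kernel(t_s, tau_s: float, shape: int) -> np.ndarray:
    """Unit-peak gamma kernel  (t/t*)^(n-1) exp((n-1) - t/tau),  t* = (n-1) tau.

    The standard descriptive b-wave shape: zero at t <= 0, single peak at
    t* with value 1, controllable rise/decay via tau and the order n.
    """
    t = np.asarray(t_s, dtype=float)
    n1 = shape - 1
    tpk = n1 * tau_s
    out = np.zeros_like(t)
    pos = t > 0.0
    out[pos] = (t[pos] / tpk) ** n1 * np.exp(n1 - t[pos] / tau_s)
    return out


def generative_components(
    params: WaveformModelParams,
    t_s,
    flash_energy_log: float = 2.07,
) -> dict[str, np.ndarray]:
    """Noise-free generative components on a time grid (oracle for tests)."""
    t = np.asarray(t_s, dtype=float)
    p3 = p3_model_trace(params.p3, t, flash_energy_log)
    p2 = params.p2_amp_uV * gamma_kernel(t, params.p2_tau_s, params.p2_shape)
    ops = np.zeros_like(t)
    for c, f, a, w in params.op_atoms:
        ops += a * np.exp(-((t - c) ** 2) / (2.0 * w**2)) * np.cos(2.0 * np.pi * f * (t - c))
    ops[t <= 0.0] = 0.0
    return {"p3": p3, "p2": p2, "ops": ops}


def simulate_waveform(
    params: WaveformModelParams,
    flash_energy_log: float = 2.07,
    acq: AcquisitionSpec | None = None,
    seed: int | np.random.Generator | None = 0,
    meta: Mapping | None = None,
) -> ERGWaveform:
    """Generate one synthetic flash ERG record (deterministic for a fixed seed)."""
    acq = acq or AcquisitionSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = acq.time_grid()
    comps = generative_components(params, t, flash_energy_log)
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    drift = params.drift_amp_uV * np.sin(2.0 * np.pi * params.drift_freq_hz * (t - t[0]) + phase)
    noise = rng.normal(0.0, params.noise_sd_uV, t.size) if params.noise_sd_uV > 0 else np.zeros_like(t)
    raw = comps["p3"] + comps["p2"] + comps["ops"] + drift + noise
    return ERGWaveform(
        samples_uV=acq.bandpass(raw),
        fs_hz=acq.fs_hz,
        t0_s=float(t[0]),
        flash_energy_log=flash_energy_log,
        meta=dict(meta or {}),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative lognormal factor with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass
class CohortDesign:
    """Four-group repeated-measures ERG cohort design.

    ``growth_end`` gives each group's multiplicative amplitude factor at
    the final timepoint; growth ramps linearly from 1 at baseline unless
    an explicit per-timepoint curve is supplied in ``growth_curves``.
    ``genotype_scale`` attenuates HOM baseline amplitudes.  Between-
    subject variability is a single lognormal scaler per subject applied
    to both RmP3 and P2; ``growth_slope_sd`` adds per-subject drug-
    response heterogeneity (a factor on growth-1) and ``record_cv`` a
    per-record physiological jitter — both enter the ground truth.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"WT_VEH": 11, "WT_LDOPA": 11, "HOM_VEH": 13, "HOM_LDOPA": 11}
    )
    timepoints_min: Sequence[float] = (0, 5, 10, 15, 20, 25, 30)
    genotype_scale: float = 0.75
    growth_end: Mapping[str, float] = field(
        default_factory=lambda: {"WT_VEH": 1.19, "WT_LDOPA": 1.16, "HOM_VEH": 1.25, "HOM_LDOPA": 1.47}
    )
    growth_curves: Mapping[str, Sequence[float]] | None = None
    between_subject_cv: float = 0.15
    record_cv: float = 0.06
    growth_slope_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints_min, dtype=float)
        if tp.size < 2 or tp[0] != 0.0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints_min must be strictly increasing and start at 0")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError(f"group {g} needs n >= 2 (got {n})")
        if not self.n_per_group:
            raise ValueError("empty cohort: n_per_group has no groups")
        if not (0.0 < self.genotype_scale <= 1.0):
            raise ValueError("genotype_scale must be in (0, 1]")
        if self.growth_curves is not None:
            for g, curve in self.growth_curves.items():
                curve = np.asarray(curve, dtype=float)
                if curve.size != tp.size:
                    raise ValueError(f"growth curve for {g} must match timepoints length")
                if curve[0] != 1.0:
                    raise ValueError(f"growth curve for {g} must equal 1 at t=0")

    def growth(self, group: str, time_min: float) -> float:
        """Group growth factor at a timepoint (1 at baseline)."""
        tp = np.asarray(self.timepoints_min, dtype=float)
        if self.growth_curves is not None and group in self.growth_curves:
            return float(np.interp(time_min, tp, np.asarray(self.growth_curves[group], float)))
        end = self.growth_end.get(group, 1.0)
        return 1.0 + (end - 1.0) * float(time_min) / float(tp[-1])


def simulate_cohort_amplitudes(design: CohortDesign, base: WaveformModelParams | None = None) -> pd.DataFrame:
    """Ground-truth amplitude table for a cohort (no waveform synthesis).

    One row per subject x timepoint with the true per-record RmP3 and P2
    amplitudes, the subject scaler, realised growth and record jitter.
    """
    base = base or WaveformModelParams()
    rng = np.random.default_rng(design.seed)
    rows = []
    for group in GROUPS:
        if group not in design.n_per_group:
            continue
        genotype, treatment = group.split("_")
        scale = design.genotype_scale if genotype == "HOM" else 1.0
        for i in range(design.n_per_group[group]):
            subject = f"{group}_{i + 1:02d}"
            z = float(_lognormal_factor(rng, design.between_subject_cv))
            beta = 1.0 + design.growth_slope_sd * float(rng.standard_normal())
            for t in design.timepoints_min:
                g = design.growth(group, t)
                realized = max(1.0 + beta * (g - 1.0), 0.05)
                nu = float(_lognormal_factor(rng, design.record_cv))
                amp = scale * z * realized * nu
                rows.append(
                    {
                        "subject_id": subject,
                        "genotype": genotype,
                        "treatment": treatment,
                        "group": group,
                        "time_min": float(t),
                        "rm_p3_true_uV": base.p3.rm_p3_uV * amp,
                        "p2_amp_true_uV": base.p2_amp_uV * amp,
                        "subject_scaler": z,
                        "growth_factor": realized,
                        "record_jitter": nu,
                    }
                )
    return pd.DataFrame(rows)


def simulate_cohort(
    design: CohortDesign,
    base: WaveformModelParams | None = None,
    acq: AcquisitionSpec | None = None,
) -> tuple[list[ERGWaveform], pd.DataFrame]:
    """Generate one waveform per subject x timepoint plus the ground-truth table."""
    base = base or WaveformModelParams()
    acq = acq or AcquisitionSpec()
    truth = simulate_cohort_amplitudes(design, base)
    # Independent stream for waveform noise, decoupled from the amplitude draws.
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x5EED]))
    waves = []
    for row in truth.itertuples(index=False):
        params = replace(
            base,
            p3=replace(base.p3, rm_p3_uV=row.rm_p3_true_uV),
            p2_amp_uV=row.p2_amp_true_uV,
            op_atoms=tuple(
                (c, f, a * row.p2_amp_true_uV / base.p2_amp_uV if base.p2_amp_uV else a, w)
                for c, f, a, w in base.op_atoms
            ),
        )
        meta = {
            "subject": row.subject_id,
            "genotype": row.genotype,
            "treatment": row.treatment,
            "time_min": row.time_min,
            "eye": "OD",
        }
        waves.append(simulate_waveform(params, acq=acq, seed=rng, meta=meta))
    return waves, truth


# ---------------------------------------------------------------------------
# OCT cohort


@dataclass(frozen=True)
class OCTLayerSpec:
    """Per-layer generative settings (all in micrometres).

    ``hom_offset_um`` is a signed baseline offset applied to HOM animals
    (negative = congenitally thinner); ``thinning_um`` is the positive
    decrement every animal accrues between baseline and 30 min.
    """

    baseline_mean_um: float
    sd_um: float
    hom_offset_um: float = 0.0
    thinning_um: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_mean_um <= 0:
            raise ValueError("baseline_mean_um must be positive")
        if self.sd_um < 0:
            raise ValueError("sd_um must be non-negative")


_DEFAULT_OCT_LAYERS = {
    "RNFL": OCTLayerSpec(32.0, 2.0, 0.0, 1.2),
    "GCIPL": OCTLayerSpec(70.0, 3.0, 0.0, 1.8),
    "INL": OCTLayerSpec(25.0, 1.5, 0.0, 0.8),
    "OPL": OCTLayerSpec(18.0, 1.5, -2.0, 1.0),
    "ONL": OCTLayerSpec(60.0, 3.0, -5.0, 1.2),
}


@dataclass
class OCTCohortDesign:
    """Two-timepoint (baseline, 30 min) per-layer OCT thickness design.

    Total retinal thickness (TRT) is not drawn independently: every
    record's TRT is the sum of its component layers plus a constant
    ``remainder_um`` (photoreceptor segments / RPE complex), so the
    additivity invariant holds exactly.
    """

    layers: Mapping[str, OCTLayerSpec] = field(default_factory=lambda: dict(_DEFAULT_OCT_LAYERS))
    remainder_um: float = 30.0
    remeasure_sd_um: float = 0.8
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"WT_VEH": 11, "WT_LDOPA": 11, "HOM_VEH": 13, "HOM_LDOPA": 11}
    )
    followup_min: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if "TRT" in self.layers:
            raise ValueError("TRT is derived (sum of layers + remainder); do not configure it")
        for name, spec in self.layers.items():
            if not isinstance(spec, OCTLayerSpec):
                raise TypeError(f"layer {name} must be an OCTLayerSpec")
        if self.remainder_um < 0:
            raise ValueError("remainder_um must be non-negative")


def simulate_oct_cohort(design: OCTCohortDesign, n_per_group: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-subject per-layer thickness at baseline and follow-up (long table).

    Columns: subject_id, genotype, treatment, time_min, measure, value.
    Raises if any generated thickness would be negative (inconsistent
    parameters).
    """
    n_per_group = n_per_group or design.n_per_group
    rng = np.random.default_rng(design.seed)
    layer_names = list(design.layers)
    rows = []
    for group in GROUPS:
        if group not in n_per_group:
            continue
        genotype, treatment = group.split("_")
        for i in range(n_per_group[group]):
            subject = f"{group}_{i + 1:02d}"
            base_vals = {}
            late_vals = {}
            for name in layer_names:
                spec = design.layers[name]
                mean = spec.baseline_mean_um + (spec.hom_offset_um if genotype == "HOM" else 0.0)
                b = mean + spec.sd_um * float(rng.standard_normal())
                l = b - spec.thinning_um + design.remeasure_sd_um * float(rng.standard_normal())
                if b <= 0 or l <= 0:
                    raise ValueError(
                        f"generated non-positive thickness for layer {name} "
                        "(layer parameters inconsistent)"
                    )
                base_vals[name] = b
                late_vals[name] = l
            base_vals["TRT"] = sum(base_vals.values()) + design.remainder_um
            late_vals["TRT"] = sum(v for k, v in late_vals.items()) + design.remainder_um
            for t, vals in ((0.0, base_vals), (design.followup_min, late_vals)):
                for name in layer_names + ["TRT"]:
                    rows.append(
                        {
                            "subject_id": subject,
                            "genotype": genotype,
                            "treatment": treatment,
                            "time_min": t,
                            "measure": name,
                            "value": vals[name],
                        }
                    )
    return pd.DataFrame(rows)
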