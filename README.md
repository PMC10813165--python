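# retscreen

Retinal biomarker analysis for preclinical drug screening in rodent
models of Parkinson's disease.  The package turns dark-adapted
full-field electroretinogram (ERG) recordings and segmented OCT
thickness maps into the longitudinal statistics used to screen
candidate compounds (e.g. acute L-DOPA) for effects on retinal
function and structure — and ships a seeded synthetic-cohort generator
so that every stage of the pipeline can be exercised and validated
without animal data.

## What it computes

**ERG decomposition.**  The leading edge of the a-wave is modelled with
the delayed-Gaussian saturation function of rod phototransduction,

```
P3(t) = -RmP3 · (1 - exp(-E·S·(t - td)²))     for t > td,  else 0
```

with flash energy `E = 10^(log cd·s/m²)`, sensitivity `S` and short
delay `td`; the fit returns **RmP3**, the saturated photoreceptoral
amplitude in µV.  Subtracting the fitted P3 from the raw record leaves
the P2-OP complex; a zero-phase DFT low-pass (46.9 Hz, −3 dB) removes
the oscillatory potentials and isolates the ON-bipolar-cell-driven
**P2**, whose baseline-to-peak amplitude is measured.

**Longitudinal statistics.**  Per-subject normalisation to baseline
(100 × value/baseline), ROUT-style robust outlier screening (FDR level
Q = 1 %), classical two-way mixed-design repeated-measures ANOVA
(between-subjects group factor tested against subjects-within-groups;
time and group × time against the subject × time residual) and
Sidak-corrected pairwise contrasts at each timepoint, with mean ± SEM
group summaries.

**OCT ETDRS sectors.**  Quadrant means of the 3–6 mm ETDRS outer ring
centred on the optic nerve head, computed from per-pixel layer
thickness maps (NaN-aware, with coverage reporting), feeding the same
statistics.

**Synthetic cohorts.**  A generative model — delayed-Gaussian P3 +
gamma-kernel P2 + Gabor-burst oscillatory potentials + noise, passed
through the 0.3–1000 Hz acquisition band-pass — produces four-group
(WT/HOM × VEH/L-DOPA) repeated-measures cohorts with per-subject
scalers, drug-response heterogeneity and per-record jitter, plus
per-layer OCT thickness tables; ground truth is returned for every
record.

## Worked example

```python
import retscreen as rs

params = rs.WaveformModelParams()          # RmP3 400 µV, P2 600 µV
wave = rs.simulate_waveform(params, seed=7)
p3, p2 = rs.decompose(wave)
```

prints (via `examples/01_decompose_single_erg.py`):

```
true RmP3      :   400.0 uV
fitted RmP3    :   389.3 uV  (S=279, td=4.1 ms, SSE=1741)
true P2 peak   :   600.0 uV
fitted P2 peak :   589.4 uV  at 89.2 ms
```

The fitted RmP3 recovers the generating photoreceptoral amplitude to a
few percent in the presence of 10 µV recording noise and the overlying
b-wave/OP components; the P2 peak lands at the b-wave time (~90 ms).
`examples/02_cohort_drug_effect.py` runs the full cohort pipeline on a
12-animal HOM cohort and prints the ANOVA table — the time × treatment
interaction (F ≈ 10.5, p ≈ 1e-4) detects the faster amplitude growth of
the L-DOPA group, and the Sidak post hocs locate the separation at
20–30 min.  `examples/03_oct_etdrs_sectors.py` shows the ETDRS sector
computation.

A thin CLI wraps the same functions:

```bash
retscreen simulate  --config cohort.yaml --out data/
retscreen decompose --manifest data/waveforms/manifest.csv --out decomp.csv
retscreen analyze   --table measures.csv --dv p2_peak_uV --normalize --out analysis/
retscreen full-run  --config cohort.yaml --out run/
```

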