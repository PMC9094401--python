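# voxeldecode

Decoding continuous fMRI task states from a **single voxel's** BOLD
time-series.

Conventional task fMRI analysis needs repeated blocks or events to fit a
GLM. When a task is performed continuously for a whole run (a
"continuous-state" or naturalistic design), the only usable signal at a
voxel is the temporal dynamics of its series. `voxeldecode` implements a
hybrid decoding chain for exactly that setting — two motor states, a
self-initiated (SI) and a visually guided (VG) finger-tapping run per
subject — and a univariate baseline to beat:

1. **Wavelet scalogram.** Each series x(t) is projected onto 32 frequency
   bands (0.003–0.313 Hz, step 0.01 Hz) with the continuous wavelet
   transform, CWT(a, b) = |a|⁻¹ᐟ² ∫ x(t) ψ((t−b)/a) dt, using the
   Daubechies-2 wavelet ψ and the pseudo-frequency relation
   f = f_c / (a·TR).
2. **Per-band 1D-CNN.** One classifier per band (and one on the raw
   series): three conv blocks (32/64/128 filters, kernel 3, batch norm,
   LeakyReLU, max-pool 2) → dense(128) + dropout → sigmoid; Adam, binary
   cross-entropy, L1 1e-5, batch size 2; the mean test AUC over 10
   random restarts is the decoding score.
3. **Wavelet-ALFF baseline.** The time-mean |coefficient| per band is a
   univariate amplitude decoder and feeds paired t-tests across subjects.
4. **Evaluation.** AUC (Mann–Whitney with midrank ties); an OLS calibration
   |T| = slope·AUC + intercept maps a t-significance level (e.g. |T| = 4.08)
   to an AUC "efficiency" threshold (0.61 by default); comparison
   summaries count efficient models per method across a voxel × band design
   (25 voxels × 32 bands = 800 pairs, 825 models with the raw-series ones).

A built-in synthetic generator (42 subjects × 2 states × 230 time points at
TR = 2 s, 1/f background, band-limited amplitude effect between states)
stands in for subject data, and a 25-peak activation table from the
blocked-design SI-vs-VG contrast is packaged for coordinate-based voxel
extraction. The CNN engine is plain seeded numpy — no GPU, no deep-learning
framework.

## Worked example

`examples/02_decode_effect_band.py` simulates a 16-subject cohort with a
2× amplitude effect at 0.103 Hz, wavelet-transforms every series, and trains
the CNN on the effect band and on a distant low-frequency null band
(reduced scale: 25 epochs, 3 repetitions):

```text
24 train / 8 test series
band 10 (0.103 Hz, effect): CNN mean AUC = 0.917 (reps [0.875 1.    0.875]), wavelet-ALFF AUC = 0.875
band  0 (0.003 Hz, null): CNN mean AUC = 0.750 (reps [0.75  0.688 0.812]), wavelet-ALFF AUC = 0.562
AUC 0.5 = chance; the efficiency threshold used downstream is 0.61
```

The effect band decodes well for both methods (the synthetic effect is an
amplitude difference, which is what ALFF measures); the null band trails it.
The null-band CNN sits above chance because the default protocol keeps the
best epoch *on the test set* — an optimistic bias inherited from the
reference protocol; pass `monitor="validation"` for honest estimates (see
`docs/methods.md`).

Other examples: `01_simulate_and_transform.py` (generator + scalogram +
per-band amplitude), `03_calibration_and_comparison.py` (800-pair / 825-model
bookkeeping and the AUC↔|T| calibration on a 25-voxel run),
`04_extract_from_nifti.py` (peak-table extraction from a 4D volume).

There is also a thin CLI mirroring the pipeline stages:

```bash
voxeldecode simulate --n-subjects 6 --seed 1 --out series.tsv
voxeldecode alff --series series.tsv --out alff.tsv
voxeldecode decode --series series.tsv --band 10 --epochs 25 --seed 1 --out result.tsv
voxeldecode run-all --config run.toml --seed 1 --out rundir
```

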