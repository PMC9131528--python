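# anxnet

From regional brain atrophy to anxiety-related brain networks: a tested
Python implementation of the analysis chain used to link longitudinal
cortical thinning to symptom severity in multiple sclerosis and onward to
network-level mechanisms — atrophy network mapping against a normative
functional connectome, directed (effective) connectivity from source-space
EEG, path-model structural equation modelling, and task-EEG power
statistics. Every stage is exercisable on synthetic data with known ground
truth, so the whole pipeline is testable without any patient data or
downloads.

The package is aimed at researchers who want the *inferential machinery* of
such studies — the estimators, the permutation/bootstrap significance
procedures, and their calibration — as reusable, verifiable components.

## The analysis chain

1. **Morphometry** (`anxnet.morphometry`). Annualized atrophy per subject
   and region, `atrophy = (CT_followup − CT_baseline) / Δt` (mm/yr), is
   correlated with an anxiety score (HADS-A, 0–21) as a partial correlation
   given age and sex: both variables are residualized on `[1, age, sex]`,
   with `t = r·√((n−k−2)/(1−r²))`, k = 2. Family-wise error across regions
   is controlled by max-cluster-mass permutation of the symptom labels;
   surviving clusters become a binary seed mask.
2. **Atrophy network mapping** (`anxnet.netmap`). The seed's mean BOLD time
   course in each normative resting-state subject is correlated with every
   in-brain voxel; correlations are Fisher-transformed (`z = atanh r`), a
   one-sample group t map of z against 0 is formed, and voxels surviving a
   Bonferroni voxel-wise FWE threshold define the seed's functional network.
   Minimal preprocessing (6-mm FWHM smoothing, nuisance regression,
   0.01–0.08 Hz zero-phase bandpass) is included.
3. **Effective connectivity** (`anxnet.effconn`). Source signals (extracted
   with a DICS beamformer from supplied lead fields) are modelled as an
   MVAR process `x_t = Σ_k A_k x_{t−k} + e_t`; partial directed coherence
   `π_{i←j}(f) = |Ā_{ij}(f)| / √(Σ_m |Ā_{mj}(f)|²)` with
   `Ā(f) = I − Σ_k A_k e^{−i2πfk/fs}` is evaluated in sliding windows and
   averaged over time (TPDC) and over the theta (4–7 Hz) and gamma
   (30–70 Hz) bands. Significance combines a window-shuffle bootstrap
   threshold with a time-reversal direction check.
4. **SEM** (`anxnet.sem`). Observed-variable path models (e.g.
   `HADS ~ PFC + AMG + HIP`) are fitted by maximum likelihood on the sample
   covariance, minimizing `F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p`, with
   `χ² = (n−1)·F_min`, `RMSEA = √(max(χ²−df,0)/(df(n−1)))`,
   `AIC = χ² + 2·#free`, and standardized coefficients
   `s = b·sd(pred)/sd(out)` from the implied covariance.
5. **Task EEG** (`anxnet.eegtask`). Cue-locked epochs (−2 to +5 s), TMS
   artifact excision (−5 ms to +20 ms around the pulse), shock-trial
   removal, grand-average re-referencing, Hilbert-envelope band power, and
   cluster-based permutation statistics over channel × time maps.
6. **Synthetic data** (`anxnet.simulate`) generates every input with planted
   ground truth; `anxnet.validation` measures calibration (false-positive
   rates) and recovery (detection rates) of each stage on those inputs.

## Worked example

`examples/01_atrophy_to_seed.py` simulates a 92-subject, 68-region cohort
with one planted region (12) whose annualized thinning correlates with the
anxiety score at r = 0.6, then runs the morphometry chain:

```
 region        r   t_stat  p_uncorrected  p_corrected
     12 0.606820 7.161799   2.301720e-10     0.001998
     32 0.251948 2.442272   1.659484e-02     0.688312
     19 0.232391 2.241386   2.751678e-02     0.852148

seed mask regions: [12] (planted: 12)
```

The planted region carries the extreme adjusted correlation and is the only
region whose cluster survives the 1000-permutation max-mass correction
(p_corrected = 0.002 is the permutation resolution floor 2/1001); the two
runner-up regions are chance suprathreshold singletons that the correction
discards. `examples/03_effective_connectivity.py` does the same for directed
connectivity — three theta oscillators with a single planted 1→2 coupling:

```
target source  forward  threshold  net_forward  net_reversed  passes
   ch0    ch1    0.123      0.285       -0.817         0.494   False
   ch1    ch0    0.940      0.285        0.817        -0.494    True
   ...
```

Only the planted connection exceeds the bootstrap threshold *and* flips its
net direction under time reversal. The other examples cover network mapping
(Dice = 1.000 against the planted module), SEM recovery (s = 0.608 / 0.384 /
0.195 for true 0.6 / 0.4 / 0.2), the EEG cleaning chain, and the end-to-end
pipeline with its reproducibility manifest.

## Command line

A thin CLI wraps the same functions:

```bash
anxnet run --seed 7 --outdir out          # full synthetic workflow + manifest
anxnet atrophy --input ct.tsv --n-perm 1000 --seed 7
anxnet sem --model model.txt --data volumes.tsv
```

Exit codes: 0 success, 2 precondition failure, 3 numerical failure.

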