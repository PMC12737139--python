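# aldtf — adaptive layer-dependent wavelet denoising

`aldtf` denoises quasi-periodic physiological signals — ECG and fiber-optic
cardiorespiratory traces — without needing a clean reference signal.  It is
aimed at people processing single-channel recordings from wearables, bedside
monitors or optical-fiber sensors, where the noise mixture (baseline wander,
electrode motion, muscle artifact) varies from record to record and no ground
truth exists to tune against.

## Method

The noisy signal y_in(n) is decomposed with a discrete wavelet transform
(bior6.8 by default) into detail layers D_1..D_J and an approximation A_J.
Each detail layer j gets its own threshold function

    ŵ = sgn(w) · (|w| / 2) · [ tanh( α_j (|w| − λ_j) ) + 1 ]

where λ_j is the layer threshold and α_j a tuning factor that moves the rule
between gentle shrinkage (small α_j) and an effectively hard threshold
(large α_j).  The bracket lies in [0, 1], so the rule never grows a
coefficient, is continuous (no hard-threshold ringing), and fixes ŵ = w/2 at
|w| = λ_j.

Because no clean reference exists, each α_j (and optionally λ_j) is chosen
by maximizing the **non-zero periodic peak (NZOPP)** of the reconstruction's
normalized autocorrelation

    NACF(k) = Σ_{n=0}^{N−k−1} y(n) y(n+k)
              / ( √(Σ_{n=0}^{N−1} y²(n)) · √(Σ_{n=0}^{N−k−1} y²(n+k)) )

— a clean heartbeat-like signal has a large autocorrelation peak at its
fundamental period, broadband noise does not.  The maximization uses a
derivative-free five-point bracket search that halves the interval each
iteration down to a width of 1e-6.  Layers are tuned finest to coarsest;
the approximation layer passes through untouched.  Classical soft/hard DWT
baselines and the usual reference-based metrics (SNR, SINAD, RMSE, PRD) are
included for evaluation on synthetic data where the clean signal is known.

## Worked example

```python
import aldtf

# synthetic ECG (360 Hz, 10 s, 72 bpm) + white noise mixed at exactly 5 dB
pair = aldtf.synth_noisy_ecg("WHITE", 5.0, fs=360.0, duration_s=10.0,
                             heart_rate_bpm=72.0, seed=42)
res = aldtf.aldtf_denoise(pair.noisy)
rep = aldtf.delta_metrics(pair.clean, pair.noisy, res.output)
```

prints (via the fields of `rep` and `res`):

```
input SNR : 5.0 dB
output SNR: 10.8135 dB   (dSNR 5.8135 dB)
RMSE      : 0.0566
PRD       : 28.8 %
NZOPP     : 0.587 -> 0.8222
layer 1: lambda=0.4362  alpha=60.30
layer 2: lambda=0.4627  alpha=37.33
layer 3: lambda=0.5082  alpha=6.66
layer 4: lambda=0.5655  alpha=0.00
```

The denoiser raised the SNR by 5.8 dB and the periodicity score (NZOPP) from
0.59 to 0.82, using purely the noisy signal.  The learned tuning factors
fall from the finest layer (α=60, hard-like: keep sharp QRS coefficients,
zero the noise floor) to the coarsest (α=0, maximal smoothing of the layer),
i.e. the shape of the threshold function genuinely adapts per layer.

The same flow is available from the shell:

```sh
aldtf simulate --kind ecg --noise white --snr 5 --seed 42 --out /tmp/run
aldtf denoise  --input /tmp/run.noisy.csv --fs 360 --out /tmp/run.denoised
aldtf evaluate --clean /tmp/run.clean.csv --noisy /tmp/run.noisy.csv \
               --denoised /tmp/run.denoised.csv --fs 360
aldtf bench --seeds 10 --noise white --noise ma --snr 5
```

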