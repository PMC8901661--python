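# vocalence

Classification of pig vocalizations by emotional valence and recording
context, for computational bioacoustics and animal-welfare research.

Pigs vocalize constantly from birth to slaughter, and the acoustic
structure of their calls carries information about the emotional valence
(positive vs. negative) of the situation that produced them.  `vocalence`
implements the full analysis chain used to test whether that information
can be recovered automatically:

1. **Acoustic features** — ten parameters per cropped call: duration
   (Dur), amplitude variation (AmpVar), amplitude-modulation rate and
   extent (AmpModRate, AmpModExtent), spectral energy quartiles
   (Q25/Q50/Q75), peak frequency (FPeak), harmonic-to-noise ratio
   (Harmonicity) and Wiener entropy (WienEntropy, the log ratio of the
   power spectrum's geometric to arithmetic mean).  Calls are typed
   low-frequency (LF, grunts) vs high-frequency (HF, screams/squeals) by
   Q50 against age-class cutoffs (2414 / 2153 / 896 Hz for age classes
   1–3).
2. **Statistical screen** — per-call-type PCA picks one non-redundant
   parameter per category; Gaussian linear mixed models
   `y ~ valence + age_class + (1 | team/pig)` quantify valence effects
   with likelihood-ratio p-values and marginal R² (variance explained by
   fixed effects alone).
3. **Permuted discriminant function analysis (pDFA)** — linear DFA on
   balanced per-(pig × level) subsets with held-out cross-classification,
   a permutation null that shuffles labels only *within* pigs (pig
   identity is the control factor), empirical chance levels and exact
   permutation p-values.
4. **Spectrogram CNN** — fixed-size log spectrograms (central zero-padding
   to 3.595 s, 3 ms window, 99 % overlap, 512-point DFT) classified by a
   small convolutional network with the published training protocol
   (70/30 stratified splits, 20 epochs, batch 32, lr 0.001 with 10^-0.5
   drops, best-validation checkpoint, repeated trials).
5. **t-SNE maps** of the last fully connected layer's activations.
6. **Synthetic call generator** — harmonic stack + band noise with AM
   envelope, pigs nested in teams, 19 imbalanced contexts, three age
   classes, and valence contrasts built in so the whole pipeline is
   testable without any audio download.

## Worked example

```python
import numpy as np
from vocalence import synth, features, screening
from vocalence.pdfa import PdfaDesign, run_pdfa

spec = synth.default_spec(rng_seed=1, n_calls=400)
calls, meta = synth.synthesize_dataset(spec)
table = features.extract_table(calls)

sel = screening.select_parameters(table, "LF")
print(sel.selected)
# ['Dur', 'AmpModRate', 'Q25', 'WienEntropy']

res = screening.fit_valence_lmm(table[table.call_type == "LF"], "Dur")
print(round(res.marginal_r2, 2), res.p_value < 0.001)
# 0.19 True

r = run_pdfa(table[table.call_type == "LF"],
             PdfaDesign(n_permutations=100, rng_seed=1))
print(round(r.pct_cross_classified, 1), round(r.chance_cross_classified, 1), r.p_cross)
# 97.5 50.4 0.009900990099009901
```

The PCA recovers the four-parameter set (duration, AM rate, a spectral
quartile, a tonality measure); the mixed model attributes about a fifth
of LF duration variance to valence alone at this sample size; and the pDFA cross-classifies
synthetic calls far above its permutation chance level with the smallest
attainable p-value (1/101 at 100 permutations).

The same stages are scriptable from a shell:

```bash
vocalence synth --out calls/ --seed 1 --n-calls 400
vocalence extract --calls calls/ --meta calls/meta.csv --out features.csv
vocalence stats --features features.csv --factor valence --out stats.json
vocalence pdfa --features features.csv --call-type LF --perms 1000 --seed 1
vocalence run --out run/ --seed 1        # end-to-end with a JSON report
```

## Layout

```
src/vocalence/
  synth.py        synthetic call generator (WAV + metadata CSV)
  features.py     10 acoustic parameters + LF/HF typing
  screening.py    PCA selection, mixed models, marginal R2
  pdfa.py         permuted DFA with control factor
  classifier.py   spectrograms + CNN training protocol
  _nn.py          numpy CNN engine
  embedding.py    t-SNE of last-layer activations
  pipeline.py     aggregation ops + end-to-end runner
  cli.py          `vocalence` command group
docs/methods.md   model, parameter and design notes
```
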