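# edafuse

Binary valence/arousal classification from electrodermal activity (EDA/GSR),
fusing per-trial statistical signal features with knowledge-graph embeddings
of subject gender and age.

## The problem

Skin conductance is a workhorse signal in affective computing: phasic
skin-conductance responses (SCRs) track sympathetic arousal, and tonic level
shifts accompany changes in affective state. Classifiers built on per-trial
EDA statistics alone, however, ignore stable subject covariates — gender and
age — that shift the base rates of emotional responding. `edafuse`
implements a pipeline that injects those covariates through a learned
graph-embedding channel:

1. **Gender-age relation graph.** Participants, integer ages and gender
   tokens are entities; observed facts are triples such as
   `(participant, AgeIs, 28)` and `(participant, GenderIs, F)`. Each entity
   and relation gets a complex embedding of dimension K, and a triple
   (s, r, o) is scored

   `f(s, r, o) = Re(⟨w_r, e_s, ē_o⟩)
              = ⟨Re w, Re s, Re o⟩ + ⟨Re w, Im s, Im o⟩ + ⟨Im w, Re s, Im o⟩ − ⟨Im w, Im s, Re o⟩`.

   Embeddings are trained by maximizing the softmax likelihood of each
   observed triple against sampled filtered corruptions of its object and
   subject (negatives that would themselves be observed positives are
   excluded), with an L2 penalty λ·ΘᵀΘ. Quality is measured by filtered
   ranking (MRR, Hits@1/3). The real parts of participant embeddings form
   the covariate feature matrix **G**.

2. **Statistical features.** Each preprocessed trial (per-participant
   min-max normalization, 11-point median filter at 4 Hz; resample/segment/
   baseline-removal for 128 Hz data) yields the feature vector **S**: seven
   basic moments, four first/second-difference statistics (or SCR-event
   features — peak count, amplitude, rise time, local minima — for the
   128 Hz style).

3. **Weighted fusion and classification.** PCA reduces **G** to the feature
   dimension d, and a learnable d×d matrix **P** turns each subject's
   reduced embedding row ĝ into multiplicative feature weights:

   `F = S ⊗ (P ĝ)` (elementwise).

   F feeds an MLP with hidden widths 64–128–64 (batch norm, ReLU, dropout
   0.2 after each hidden layer) and a 2-unit softmax output, trained with
   the MSE criterion against one-hot targets by Adam; **P** is learned
   jointly with the network.

4. **Evaluation.** Leave-one-subject-out (LOSO) cross-validation with
   recall, precision, accuracy and F1 per fold; the Friedman rank test and
   the Nemenyi post-hoc critical distance `CD = q_α √(k(k+1)/6N)` compare
   methods across folds.

Because the benchmark wristband/video EDA corpora are access-controlled, the
package ships a first-class synthetic generator: tonic-plus-phasic signals
at 4 or 128 Hz whose SCR rate depends on the arousal class, whose tonic
level depends on the valence class, and whose label odds depend on gender
and age by a controllable amount. Every stage of the pipeline — and the
claim that covariate fusion beats signal-only classification — is testable
end to end without any download.

## Worked example

```bash
edafuse simulate --seed 7 --out demo/bundle
# wrote 320 trials from 40 subjects to demo/bundle

edafuse embed --data demo/bundle --out demo/G.csv --dim 16 --seed 7
# MRR=1.000  Hits@1=1.000  Hits@3=1.000  (n=160 ranked completions)

edafuse evaluate --data demo/bundle --out demo/sf  --features sf      --epochs 150 --seed 0
# sf arousal: accuracy 0.572 ± 0.209, F1 0.476

edafuse evaluate --data demo/bundle --out demo/sfg --features sf-garg --epochs 150 --seed 0
# sf-garg arousal: accuracy 0.622 ± 0.201, F1 0.473
```

The first command writes a 40-subject synthetic bundle (8 trials each,
4 Hz, 60 s). `embed` trains the gender-age graph embedding and reports
filtered-ranking quality: MRR 1.0 means every held-out completion (each
subject's true age and gender) outranks all of its filtered corruptions.
The two `evaluate` runs score the signal-only model (SF) and the fusion
model (SF-GARG) under LOSO: mean fold accuracy ± its standard deviation
across folds. On this bundle fusion lifts arousal accuracy from 0.572 to
0.622 — the covariate channel supplies label information the signal alone
does not carry. Single-seed differences fluctuate; the multi-seed
experiment below is the reliable comparison.

The same computations are available as a library:

```python
from edafuse import SimConfig, generate_dataset, run_loso
bundle = generate_dataset(SimConfig(seed=7))
report = run_loso(bundle, task="arousal", mode="sf-garg", seed=0)
print(report.aggregate())
```

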