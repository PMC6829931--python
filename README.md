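# seatsense

Detection and classification of compensatory trunk movements during seated
reaching, from the pressure distribution on a sensing seat mat.

After a stroke, people with upper-limb impairment often substitute trunk
motion for arm motion when reaching: leaning the trunk forward (TLF),
rotating it (TR), or elevating the shoulder girdle (SE). These
compensations are hard to monitor outside the clinic, but they leave clear
traces in the seat-pressure distribution. `seatsense` implements the full
analysis chain for a body-pressure measurement mat (32 × 32 piezoresistive
sensors sampled at 50 Hz): per-trial feature extraction, k-NN and linear
SVM classification with subject-grouped cross-validation, evaluation
metrics, a surface-EMG verification chain, and a synthetic trial generator
that stands in for clinical recordings, which are not publicly available.

## Model

Sensor *i* at lateral coordinate *x*ᵢ (column) and longitudinal coordinate
*y*ᵢ (row) reads pressure *p*ᵢ(*t*). With frame total
SSV(*t*) = Σᵢ *p*ᵢ(*t*), each motion trial of *T* frames is summarised by
five features:

- **ASV** = (1/*T*) Σₜ SSV(*t*) — average sensor value;
- **SD_LatCOP**, **SD_LonCOP** — standard deviations of the centre of
  pressure, LatCOP(*t*) = Σᵢ *x*ᵢ *p*ᵢ(*t*) / SSV(*t*) and the analogous
  LonCOP(*t*) over *y*ᵢ;
- **SD_LRratio**, **SD_FBratio** — standard deviations of the left/right
  and front/back half-pressure ratios.

The SD features capture the volatility of the seated posture during a
reach; compensation patterns redistribute pressure in characteristic
directions, so the five numbers separate NC (no compensation) from TLF,
TR and SE. Classification uses Euclidean k-NN (k selected by an inner
subject-grouped sweep) and a linear soft-margin SVM
(min ½‖**w**‖² s.t. *y*ᵢ(**w**ᵀ**x**ᵢ + b) ≥ 1) on features standardised
to zero mean and unit variance using training folds only. Cross-validation
folds partition *subjects* — four folds of two test subjects for the
8-subject design — so every reported score estimates generalisation to
unseen people.

## Worked example

```sh
python examples/cross_validation.py
```

```
binary compensation detection (positive class = compensation):
classifier           task  precision  recall    f1
       knn back-and-forth        1.0   0.988 0.994
       knn   side-to-side        1.0   1.000 1.000
       knn    up-and-down        1.0   0.988 0.994
       svm back-and-forth        1.0   1.000 1.000
       svm   side-to-side        1.0   1.000 1.000
       svm    up-and-down        1.0   0.988 0.994

4-class macro F1:  knn 0.950   svm 0.988
```

Eight synthetic subjects, ten repetitions per task per side. Each binary
row is the detection quality of "any compensation vs none" for one
reaching task, pooled over the four subject folds; the macro F1 averages
the per-class F1 of the 4-class pattern recognition. `examples/` also
contains narrative scripts for feature extraction
(`simulate_and_extract.py`) and the sEMG RMS chain (`semg_summaries.py`).

A shell interface wraps the same library:

```sh
seatsense run --out results/run --seed 42          # end-to-end pipeline
seatsense simulate --out data/synthetic --seed 42  # dataset only
seatsense semg --data data/emg --out results/semg  # RMS summaries
```

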