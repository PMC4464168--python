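# b2t — decoding spoken phrases from intracranial neural recordings

`b2t` reconstructs continuously spoken word sequences from multichannel
electrocorticographic (ECoG) recordings made while a subject reads text
aloud.  It is written for researchers working on speech neuroprostheses
and brain-computer interfaces who want a complete, inspectable reference
pipeline — from raw electrical potentials to decoded text — together
with a synthetic-session generator that makes every stage testable
without access to clinical recordings.

## The model

Speech is treated the way an automatic speech recognizer treats audio,
with broadband gamma power standing in for the acoustic signal:

1. **Features.** Each channel is detrended, downsampled to 600 Hz,
   screened for line noise (channels whose 58–62 Hz energy exceeds
   Q3 + 2·IQR across channels are dropped), re-referenced to the common
   average, and band-filtered to 70–170 Hz with a 118–122 Hz notch
   (elliptic IIR, applied causally).  Log mean-square energy
   `E_{i,c} = log((1/n) Σ_t X_{i,c}(t)²)` is computed on 50 ms windows
   every 25 ms, and each frame is stacked with its ±4 neighbours:
   `F_i = [E_{i−4}, …, E_i, …, E_{i+4}]`, 450 ms of context.
2. **Discriminability and reduction.** Each stacked column (one channel
   at one temporal offset) gets a score `d_k`: the mean Kullback–Leibler
   divergence between the per-phone Gaussians fitted on that column,
   averaged over all ordered phone pairs (which symmetrizes it).  Scores
   are normalized by their mean, sorted, and features are kept up to the
   last decline steeper than `t = −0.05`; the kept columns are projected
   to at most (#classes − 1) dimensions by LDA.
3. **Phone models.** Every grouped phone `j` (20 classes plus silence;
   similar phones share a class, diphthongs split into two) is a
   diagonal-covariance Gaussian `p(F_i | λ_j) = N(μ_j, Σ_j)` fitted by
   sample moments.
4. **Decoding.** The word sequence is
   `Ŵ = argmax_W p(X|W) P(W)`, computed by exact Viterbi search over a
   determinized phone-prefix tree of the pronunciation lexicon, with a
   Witten–Bell-smoothed bigram language model estimated from the read
   texts (ARPA import/export supported).
5. **Evaluation.** Leave-one-phrase-out: feature selection, LDA, phone
   models and the LM are refitted with each phrase held out.  Chance
   level comes from retraining on features circularly shifted by half
   the training length with labels fixed.  Metrics: word error rate
   (WER = (S+D+I)/N), single-frame phone accuracy, confusion matrices,
   and WER as a function of dictionary size.

## Worked example

Generate a synthetic session (12 channels, 6 phone-informative, 2
line-noise-dominated, 14 phrases) and evaluate it end to end:

```bash
python - <<'EOF'
from b2t.synthetic_data import SimulationConfig
from pathlib import Path
cfg = SimulationConfig(n_phrases=14, n_channels=12, n_informative=6, n_bad=2,
                       words_per_phrase=(4, 6), pause_mean_s=0.6, seed=11)
Path("sim.json").write_text(cfg.to_json())
EOF
b2t simulate --config sim.json --out session
b2t evaluate --session-dir session --sizes 10,20 --seed 1 --out report
```

which prints

```
mean WER 0.221 (random 0.933), frame accuracy 0.754 (random 0.045)
```

and writes `report/report.json`, `confusion.csv` and `wer_by_size.csv`.
The first number is the mean word error rate over the 14 held-out
phrases with 10-word dictionaries (the spoken words plus random
distractors); `random` is the same decode with models trained on
half-shifted features — the chance level.  Frame accuracy is the
fraction of 25 ms frames whose decoded phone (of 20 classes + silence)
matches the ground-truth alignment.  Individual folds look like:

```
ref: can seven little never      | decoded: can seven little never     | WER 0.00
ref: power all liberty come great| decoded: our our liberty come great | WER 0.40
```

The other stages are available individually (`b2t features`,
`b2t klmap`, `b2t train`, `b2t decode`) and as library functions
(`b2t.extract_features`, `b2t.compute_klmap`, `b2t.leave_one_phrase_out`,
…).

## Layout

```
src/b2t/io_session.py       file formats, containers, configuration
src/b2t/phones.py           grouped phone inventory
src/b2t/preprocess.py       filtering, framing, stacking, label alignment
src/b2t/discriminability.py KL scores, feature selection, LDA
src/b2t/phone_models.py     Gaussian phone models, speech-activity screen
src/b2t/decoder.py          bigram LM, search graph, Viterbi
src/b2t/evaluation.py       leave-one-phrase-out, baselines, metrics
src/b2t/synthetic_data.py   session generator
src/b2t/cli.py              the b2t command
```

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
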