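# callsig

Vocal-signature analysis for bat contact calls: synthetic call simulation,
spectrogram measurement extraction, signature information capacity in bits,
and conventional + permuted discriminant function analysis.

## The problem

Many group-living bats exchange short, downward frequency-modulated
"contact calls" that carry individual signatures — acoustic variation that
lets colony mates recognize who is calling. Quantifying that signature
requires answering three linked questions from a table of per-note acoustic
measurements:

1. **How much identity information does a call carry?** Beecher's
   information capacity sums, over statistically independent principal
   components of the measurements, the bits contributed by each component:

   *H*<sub>i</sub> = log₂(*S*<sub>T</sub>/*S*<sub>w</sub>) = ½ log₂(*S*²<sub>T</sub>/*S*²<sub>w</sub>),  *H*<sub>s</sub> = Σ *H*<sub>i</sub>

   where *S*²<sub>w</sub> is the within-individual variance of a component,
   *S*²<sub>B</sub> the variance between signalers (here: colony +
   individual variance components, estimated by REML), and
   *S*²<sub>T</sub> = *S*²<sub>B</sub> + *S*²<sub>w</sub>. Per-component
   repeatability is the intraclass correlation
   *r*<sub>i</sub> = *S*²<sub>B</sub>/(*S*²<sub>B</sub> + *S*²<sub>w</sub>).
   Components are retained by parallel analysis, varimax-rotated, and
   scored by the Bartlett method.

2. **Can new notes actually be classified?** Linear discriminant analysis
   with leave-one-out cross-validation gives an empirical correct-
   classification rate, with Wilks' Λ and Bartlett's χ² approximation
   testing equality of class mean vectors.

3. **Is a higher-level factor (species, population, colony, sex)
   significant when notes are nested within individuals?** The permuted
   DFA (pDFA) trains on a balanced random subset of each subject's notes,
   classifies the rest, and compares the mean rate against a permutation
   null in which test-factor labels are reshuffled across subjects while
   each subject's notes stay together. The one-tailed p is the share of
   permuted datasets classifying at least as well as the observed one.

Because real recordings of this kind are rarely public, the package ships a
first-class synthetic-call generator: hierarchically structured populations
(species → colony → individual → note) of FM-sweep notes with up to three
harmonics, rendered to 250 kHz 16-bit WAV with ground-truth annotations, so
every stage of the analysis is testable end to end.

## Worked example

```python
import callsig as cs

# 1. simulate a two-colony population of white-winged vampire bats
profile = cs.DIAEMUS
hierarchy = cs.HierarchyConfig(
    n_colonies=2, individuals_per_colony=4, notes_per_individual=60,
    snr_db=30.0, seed=1, **cs.realistic_sds(profile))
specs = cs.sample_population(profile, hierarchy)
annotations = cs.write_dataset(specs, "demo", seed=1)

# 2. extract the 36 measurements per annotated note
features = cs.extract_table(annotations, "demo")

# 3. keep well-separated first notes from well-sampled individuals
first = cs.select_first_notes(features)
kept, dropped = cs.min_notes_filter(first, threshold=45)

# 4. signature information capacity
feats = kept[cs.FEATURE_COLUMNS].dropna(axis=1)
n_pc = cs.parallel_analysis(feats, n_iterations=1000, seed=1)
model = cs.pca_varimax(feats, n_pc)
vce = cs.estimate_vce(model.transform(feats), kept,
                      ["colony", "individual"])
sig = cs.signature_information(vce)

# 5. individual classification
res = cs.lda_fit(feats, kept["individual"])
```

Output:

```
1002 notes extracted, 480 first notes retained
8 components retained (86% of variance)
signature information H_s = 1.22 bits, mean repeatability 0.18
individual assignment: 57% correct (leave-one-out), chance 12%
Wilks lambda 0.043, chi2 1436, df 252, p 1.1e-164
```

Reading: the simulated calls carry about 1.2 bits of colony + individual
signature per note — individual components are repeatable but far from
stereotyped (repeatability 0.18), as in real contact calls — yet a
discriminant classifier still assigns 57% of held-out notes to the correct
one of 8 bats against a 12% chance rate.

The same pipeline runs from the shell:

```bash
callsig generate --profile Diaemus --out demo --seed 1
callsig extract --wav-dir demo --annotations demo/annotations.csv --out feats.csv
callsig info --features feats.csv --factors colony,individual --seed 1
callsig dfa --features feats.csv --test-factor individual --seed 1
callsig run --config study.yaml       # full generate→extract→info→DFA run
callsig presets                       # the nine named test designs
```

## Layout

| Module | Contents |
| --- | --- |
| `callsig.profiles` | species-typical call parameter profiles |
| `callsig.synth` | hierarchical population sampling, waveform synthesis, WAV/CSV output |
| `callsig.spectro` | spectrograms, fundamental tracking, the 36 measurements |
| `callsig.selection` | first-note, minimum-notes, and double-note filters |
| `callsig.info` | parallel analysis, `VarimaxPCA`, REML variance components, bits |
| `callsig.dfa` | `LinearDFA`, `PermutedDFA`, Holm correction, rate comparisons |
| `callsig.pipeline` | `RunConfig`, end-to-end `run()`, the nine test presets |
| `callsig.cli` | `callsig` command-line interface |

`VarimaxPCA`, `LinearDFA` and `PermutedDFA` follow scikit-learn estimator
conventions (`fit`/`transform`/`predict`, `get_params`, fitted attributes
with trailing underscores) and compose with sklearn tooling.

See `docs/methods.md` for the model, its assumptions, parameter defaults,
and known limitations.
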