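# zfpwm

De novo prediction of DNA-binding specificities for Cys2His2 zinc-finger
(C2H2-ZF) proteins, directly from protein sequence.

C2H2-ZF proteins are the largest family of sequence-specific DNA binders in
metazoans, yet experimentally determined binding motifs exist for only a
small fraction of them. `zfpwm` predicts a position weight matrix (PWM) for
any protein carrying C2H2-ZF domains: it is aimed at regulatory-genomics
researchers who need candidate motifs for uncharacterized zinc-finger
transcription factors, and at protein engineers matching finger arrays to
target sites.

## The model

Each finger contacts a 4-bp DNA subsite through a small set of residue–base
contacts between recognition-helix positions (−1, 2, 3, 6) and bases
b1..b4. Two contact maps are supported: the **canonical** model
(a6b1, a3b2, a−1b3, a2b4) and an **expanded** model adding a2b3, a−1b4 and
a6b2. An interface is encoded as a sparse indicator vector **x** (320 or
560 dimensions: contacts × 4 bases × 20 amino acids), and a max-margin
model trained on bind/no-bind examples supplies an empirical energy score
y = **w**·**x** (a degree-2 polynomial kernel variant is also available).
There is no intercept: an empty interface scores exactly zero.

The 256 possible subsites are treated as states of a Boltzmann ensemble,

    P_i = bg(i) · exp(λ·y_i) / Z,       λ = 4 by default,

and the PWM columns are the per-position marginals of this distribution
(computed position-by-position for linear scorers, by full enumeration
otherwise). Fingers separated by at most 12 residues (last His to next
Cys) act as one array; adjacent subsites overlap by one base, whose column
is a weighted geometric mean of the two per-finger predictions,
p ∝ p_prev^α · p_next^(1−α) with α = 0.75 on the N-adjacent finger's b1
column. An n-finger array yields a 3n+1-column PWM.

For evaluation, predicted and experimental PWMs are compared by ungapped
local alignment under an IC-weighted Pearson column score,
PCC(n, m) · IC(m)/2, with the reverse complement of the experimental
matrix also considered; significance comes from an empirical p-value
against matrices of random background columns.

## Worked example

Train a scorer on synthetic bind/no-bind data from a planted contact-energy
model, predict a PWM for a two-finger protein from its raw sequence, and
compare it to a noisy "experimental" motif:

```python
import zfpwm as z
from zfpwm.synth import PlantedScenario, generate_background_columns
from zfpwm.scoring import train_linear
from zfpwm.alignment import NullModel

scenario = PlantedScenario(contact_model=z.CANONICAL, seed=3, n_fingers=2)
examples = scenario.training_set(n_pos=2000, n_neg=2000, margin=0.1)
model = scenario.standardize(train_linear(examples, model=z.CANONICAL,
                                          regularization=100.0))

protein = scenario.protein()                      # synthetic 2-finger protein
fingers = z.find_c2h2_domains(protein)
array = z.build_arrays(fingers, max_linker=12)[0]
pwm = z.array_pwm(model, array, alpha=0.75)
print("fingers detected:", len(fingers))          # 2
print("array PWM columns:", len(pwm))             # 7
print("consensus:", pwm.consensus())              # CTGACCC

exp = z.trim_pwm(scenario.experimental_pwm())
res = z.align_pwms(pwm, exp)
null = NullModel(generate_background_columns(500, 1.0, seed=5),
                 n_random=9999, seed=17)
p = z.empirical_pvalue(pwm, exp, null, observed=res.total_score)
print(f"alignment: {res.orientation}, span {res.pred_span}, "
      f"total score {res.total_score:.3f}")
print(f"empirical p-value: {p:.4g}")
print(f"fraction of columns correct: {z.fraction_correct_columns(res):.3f}")
```

Output:

```
fingers detected: 2
array PWM columns: 7
consensus: CTGACCC
alignment: forward, span (1, 7), total score 3.183
empirical p-value: 0.0001
fraction of columns correct: 1.000
```

The seven columns are the 3·2+1 bases covered by a two-finger array. The
alignment score sums IC-weighted Pearson correlations over the aligned
window; p = 1/10000 means no random-column matrix of the same width scored
as high, and every experimental column reached the 0.25 correctness bar.

The same pipeline is available from the shell:

```
zfpwm synth --seed 7 --out fixtures/
zfpwm train --train fixtures/training.tsv --model-kind canonical --out model.txt
zfpwm predict --fasta fixtures/proteins.fa --model model.txt --out-dir pwms/
zfpwm evaluate --pred pwms/ --exp fixtures/experimental/ \
    --background fixtures/background_columns.tsv --report report.tsv
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the defaults and
the synthetic-data generators in detail.
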