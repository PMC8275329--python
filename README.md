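# exomodes

Joint discovery of DNA motifs and exonuclease read footprints — "binding
modes" — from ChIP-exo / ChIP-nexus data.

ChIP-exo and ChIP-nexus trim immunoprecipitated DNA with lambda
exonuclease up to the protein–DNA crosslink, so read 5′ ends accumulate in
narrow strand-specific borders around bound sites. The *shape* of that
footprint carries information beyond the motif: different binding
configurations of the same factor, cofactor co-binding, or indirect
binding all leave different exonuclease stop patterns. `exomodes` is for
regulatory genomicists who have summit-centered bound regions plus
strand-specific 5′-end count tracks and want to partition those regions
into modes defined *jointly* by sequence and footprint, without a motif
database.

## Model

Each of n regions (sequence X_i with binarized strand read vectors R_i⁺,
R_i⁻) belongs to one of m modes. Mode k is parameterized by a PWM φ_k of
width w_k, two Bernoulli read windows φ_k⁺, φ_k⁻ (width 5 by default) at
signed offsets τ_k⁺, τ_k⁻ from the motif start Z_i, and a mixture weight
γ_k:

    P(X_i, R_i⁺, R_i⁻ | mode k, Z_i) =
        P(X_i | φ_k, Z_i) · P(R_i⁺ | φ_k⁺, Z_i + τ_k⁺) · P(R_i⁻ | φ_k⁻, Z_i + τ_k⁻)

with a 2nd-order Markov sequence background and 0th-order Bernoulli read
backgrounds everywhere outside the site and windows. PWM columns, window
Bernoullis and γ are integrated out under conjugate Dirichlet/Beta priors;
a collapsed Gibbs sampler moves the per-region site assignments
(orientation, mode, position) and the per-mode structural variables
(offsets, motif widths), a hill-climbing pass yields the MAP state, and
the number of modes is chosen by minimum BIC = K ln(n) − 2 ln P̂ with
K = Σ_k (3w_k + w_k⁺ + w_k⁻ + 2). Fitted models score new regions by
position-marginalized likelihood, giving per-mode posteriors, confusion
matrices, and two-model log-odds classification. See `docs/methods.md`
for the full account.

## Worked example

Plant three binding modes (distinct 9–10 bp motifs, strong 5 bp footprints
at offsets τ⁺ = −10, −6, +8) in 200 synthetic regions of 240 bp, fit with
a BIC sweep, and compare to the planted truth:

```python
import exomodes as xm
from exomodes.model import Priors
from exomodes.sampler import SamplerConfig
from exomodes.selection import model_sweep
from exomodes.synthetic import default_three_mode_specs, evaluate_recovery

specs = default_three_mode_specs()
ds, truth = xm.generate_dataset(specs, n=200, L=240, seed=7)
ds = xm.augment_revcomp(ds)
cache = xm.build_cache(ds)
cfg = SamplerConfig(restarts=2, init_width=12, max_sweeps=60)
sweep = model_sweep(cache, range(1, 5), Priors(), cfg, seed=7)
print(sweep.table[["m", "K", "log_posterior", "bic", "chosen"]].round(1))

fitted = sweep.best
assign = xm.assign_regions(ds, fitted)
mask = (truth["mode"] != "background").to_numpy()
agree = xm.label_agreement(assign["mode"].to_numpy()[mask],
                           truth["mode"].to_numpy()[mask])
print(f"label agreement vs planted truth: {agree:.3f}")
print(evaluate_recovery(fitted, specs).round(3))
```

Output:

```
 m   K  log_posterior      bic  chosen
 1  42      -173733.7 347719.0   False
 2  93      -172129.0 344815.2   False
 3 123      -171036.5 342810.0    True
 4 168      -171043.2 343092.9   False
label agreement vs planted truth: 1.000
 mode  gamma matched_spec orientation  shift  mean_pwm_tv  err_tau_pos  err_tau_neg
    1  0.374        modeC           -      0        0.041            0            0
    2  0.345        modeB           +      0        0.034            0            0
    3  0.281        modeA           -      0        0.040            0            0
```

BIC bottoms out at the true m = 3 (the collapsed posterior flattens beyond
it, so the K ln n penalty decides); every region lands in its planted mode
after Hungarian matching; each learned mode matches one planted spec —
possibly in the mirrored orientation, which is parameter-equivalent — with
mean per-column PWM total variation ≈ 0.04 and both window offsets exact.

## Command line

```bash
exomodes simulate --spec specs.json --n 200 --out sim/    # fixture files
exomodes fit --peaks peaks.bed --genome genome.fa \
    --pos reads_pos.bedGraph --neg reads_neg.bedGraph --out run/
exomodes predict --model run/model.json --model-b other/model.json \
    --peaks new.bed --genome genome.fa --pos p.bedGraph --neg n.bedGraph \
    --component seq --out scores.tsv
exomodes confusion --model run/model.json --assignments run/assignments.tsv \
    --peaks peaks.bed --genome genome.fa --pos p.bedGraph --neg n.bedGraph \
    --out confusion.tsv
```

`fit` writes the sweep table, per-region assignments (mode, strand-mapped
site coordinates, posterior), MEME-format motifs, footprint table, BED of
sites, and a model JSON that `predict`/`confusion` reuse. Inputs are BED
peaks (summit = interval midpoint or a designated column), a soft-masked
FASTA (repeats become N; regions need ≥ 100 informative bases), and
per-strand bedGraph/bigWig 5′-end counts, with optional scaled control
subtraction.

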