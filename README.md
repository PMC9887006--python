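# acidbase

**Dual-rail acid-base molecular computing: simulator and liquid-handler
compiler.**

Strong acids and bases are cheap, complementary, and react to
completion: mixing them computes. `acidbase` is a Python package for
scientists exploring chemistry-based information processing. It
implements computation encoded in pH:

* a signed value is a **dual-rail pair** of solutions — (acid, base)
  means +1/TRUE, (base, acid) means −1/FALSE, and negation is a free
  rail swap;
* mixing an odd number of droplets computes the **majority function**
  (neutralization H₃O⁺ + OH⁻ → 2 H₂O leaves the more abundant
  species), and majority + inversion is a functionally complete basis
  for digital logic;
* a **binary neural network** (weights ±1) classifies an image by
  pooling one small aliquot from every encoded pixel per neuron: the
  pooled proton excess is exactly proportional to Σᵢ wᵢxᵢ / L, so the
  output pair's sign is the neuron's decision.

The package provides the exact pH model, the logic layer, in-silico
and chemical network inference, straight-through-estimator training of
the binary weights, a synthetic image generator for testing everything
offline, and a compiler/simulator/validator for Echo-style acoustic
liquid-handler picklists over 384- and 1536-well plates.

## The model in brief

For a mixture with proton excess concentration
`D = (n_acid − n_base) / V` (mol/L), charge balance with water
autoionization `Kw = 10⁻¹⁴` gives

    [H⁺]² − D·[H⁺] − Kw = 0,    pH = −log₁₀ [H⁺],

solved in closed form (numerically stable on both sides of
neutrality). A level `v ∈ {−L, …, −1, 1, …, L}` is encoded by diluting
both rails to concentration `c₀·|v|/L`; the 3-bit scheme (L = 4) maps
8-bit intensities through eight fixed ranges to {−4…−1, 1…4}, and
binary images threshold at 128. Logic gates AND/OR add a fresh −1/+1
bias droplet as the third input of a 3-way majority; NAND/NOR swap the
output rails. Deep circuits attenuate toward pH 7, so evaluation
defaults to replacing every gate output with fresh stock of the same
sign (signal restoration). See `docs/methods.md` for the full account.

## Worked example

Evaluate a gate chemically:

```python
from acidbase import chem, dualrail
from acidbase.logic import gate_eval

a = dualrail.encode_level(+1)        # 2.4 µL acid / 2.4 µL base pair
b = dualrail.encode_level(-1)
out = gate_eval("OR", a, b)          # majority(a, b, fresh +1 bias)
print(round(chem.ph(out.ph_rail), 4), dualrail.decode(out))
```

prints `1.4771 1`: two acid droplets against one base droplet leave an
excess of 0.1/3 mol/L — pH −log₁₀(0.1/3) ≈ 1.4771, an acidic pH rail,
so OR(+1, −1) decodes to +1.

Run the built-in 2-bit decoder demo from the shell:

```console
$ acidbase circuit --decoder --all
a	b	y0	y1	y2	y3
-1	-1	+1	-1	-1	-1
-1	+1	-1	+1	-1	-1
+1	-1	-1	-1	+1	-1
+1	+1	-1	-1	-1	+1
```

Each input pair activates exactly one output — the one-hot pattern a
decoder must produce.

Classify synthetic digit images through the full chemistry with a
planted weight table:

```console
$ acidbase classify --synthetic 3 --scale 8 --weights weights.txt --seed 0
sample 0	true=0	in_silico=0	chemical=0	match=yes
...
summary	n=6	accuracy=100.00%	match_rate=100.00%
```

`accuracy` is the in-silico argmax against the true labels;
`match_rate` is the fraction of samples where the chemical indicator
readout (one unique acidic output pair) agrees with the in-silico
network. `acidbase train`, `acidbase encode`, and
`acidbase picklist compile|simulate|validate` cover the remaining
workflows (`--help` on any command).

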