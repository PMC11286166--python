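# congalines

Are linear arrangements of fossils more than chance?

Closely spaced, nearly collinear chains of three or more frond specimens —
"conga lines" — occur on late Ediacaran bedding-plane assemblages from
Newfoundland. Whether such chains are a biological signal (stoloniferous or
philopatric reproduction) or an accident of where specimens happen to sit
depends entirely on the surface's background spatial structure: a dense or
clustered population produces many chance alignments, a sparse random one
almost none.

`congalines` implements that inference for mapped point patterns
(per-specimen x, y coordinates in a polygonal window, in metres):

1. **Detection** — count every three-point alignment: a triple
   (p₁, p₂, p₃) with consecutive spacings ≤ r and bearing change
   |b′ − b| < θ; assemble overlapping triples into maximal chains.
2. **Background characterisation** — fit a homogeneous Poisson model
   (complete spatial randomness, intensity λ) by maximum likelihood and a
   Thomas cluster model (parents κ, mean offspring μ, dispersal σ) by
   minimum contrast against the pair correlation function; keep whichever
   survives Diggle's Monte-Carlo goodness-of-fit test better.
3. **Chance expectation** — evaluate the analytic expected number of chance
   alignments under the selected background,

       E_pois = θ π² r⁴ λ³ A / 360,
       E_TC   = (θ A κ³ μ³ / 360) · [π r² + (1 − e^{−r²/4σ²}) / κ]²,

   with A the mapped area and θ in degrees (both derive from
   E = (θ/360) · A · λ³ · K(r)², with K the Ripley K-function of the
   background).
4. **Significance scan** — for r from 5 to 50 mm at 1 mm steps, compare the
   observed count with its Poisson tail probability given E, and report the
   contiguous ranges of r with significantly *more* (or *fewer*) alignments
   than chance predicts (α = 0.05).

A seeded synthetic-surface generator (CSR or Thomas backgrounds with planted
conga chains and full ground truth) makes every stage testable without the
deposited field maps. Preprocessing utilities cover retrodeformation
(removing tectonic strain recorded by ovate holdfast discs) and masking of
eroded patches.

## Worked example

`examples/04_significance_scan.py` plants 10 chains (12 mm spacing, 5°
bearing jitter) on a Thomas background fitted to the densest studied surface
(κ = 18 m⁻², μ = 6, σ = 72.63 mm, 2 × 2 m window) and runs the full scan:

```
585 points, 25 planted triples
selected background: thomas
 r(mm)  observed  expected   p(more)
     5         0      0.02   1.00e+00
    10         1      0.31   2.68e-01
    12         6      0.65   5.82e-05
    15        29      1.57   1.29e-26
    20        35      4.96   1.74e-18
    30       115     24.89   2.35e-39
    40       195     77.69   4.86e-29
    50       309    186.72   1.81e-16

significantly MORE than predicted (r in mm): 12-50
significantly FEWER than predicted:           N/A
```

The "more" range begins exactly at the planted spacing: below 12 mm the
chains are invisible to the detector; above it they overwhelm the chance
expectation. The other examples each demonstrate one capability (detection,
analytic expectations, background fitting, analytic-vs-numeric validation)
and print a line explaining their numbers.

The same pipeline is scriptable from the shell:

```sh
congalines synth --kappa 18 --mu 6 --sigma-mm 72.63 --n-chains 10 \
    --out surface.csv --truth truth.json --seed 11
congalines scan --points surface.csv --window window.geojson --seed 12
```

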