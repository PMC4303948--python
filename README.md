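# gapcircuit

A sequence-based dynamical model of the *Drosophila* gap gene network.

The gap genes (*hb*, *Kr*, *gt*, *kni*) form the first zygotic tier of
the segmentation cascade: they read maternal protein gradients (Bcd,
Cad) and terminal inputs (Tll, Hkb) and partition the
anterior–posterior axis into broad expression domains during cleavage
cycles 13–14A. `gapcircuit` implements a two-layer model that connects
the DNA sequence of the gap regulatory regions to these spatiotemporal
protein patterns:

1. **Thermodynamic layer.** Binding sites are predicted from position
   weight matrices (log-odds scores, DNase-accessibility filtered). The
   probability that the basal transcriptional machinery (BTM) is
   recruited is computed from the configuration partition function

   E = Σ<sub>σ</sub> W(σ)Q(σ) / (Σ<sub>σ</sub> W(σ)Q(σ) + Σ<sub>σ</sub> W(σ)),

   where a configuration σ is a non-overlapping set of bound sites,
   W(σ) = Π q(S<sub>i</sub>) · Π ω (homotypic cooperativity for
   adjacent same-TF pairs) · Π β<sub>R</sub> (effective repressors),
   with site strength q(S) = K(S<sub>max</sub>) · v<sub>TF</sub> ·
   exp[LLR(S) − LLR(S<sub>max</sub>)], and Q(σ) = q<sub>btm</sub> ·
   Π T<sup>ab</sup> over bound activators. The signed interconnectivity
   matrix T<sup>ab</sup> encodes the action of TF *b* on gene *a*:
   positive entries are activator weights α, negative magnitudes are
   short-range repressor strengths β (a bound effective repressor makes
   DNA within d<sub>R</sub> of its site inaccessible).

2. **Dynamical layer.** The activation level drives delay
   reaction–diffusion equations for mRNA u and protein v per nucleus:

   du/dt = R<sub>u</sub>·E(t) + D<sub>u</sub>(n)·[(u<sub>i−1</sub>−u<sub>i</sub>) + (u<sub>i+1</sub>−u<sub>i</sub>)] − λ<sub>u</sub>·u

   dv/dt = R<sub>v</sub>·u(t−τ<sub>v</sub>) + D<sub>v</sub>(n)·[…] − λ<sub>v</sub>·v

   over cycles 13 and 14A (eight 6.5-minute classes, nuclei doubling at
   the cycle boundary), with gap proteins feeding back into E and
   maternal/terminal TFs interpolated from data.

The free parameter vector (68 entries in the default 4-gene/8-TF
configuration: 32 T entries, 4 basal constants, 8 affinities, 8
cooperativities, 4 repression ranges, 4 delays, 8 decay rates) is
fitted by differential evolution against the combined objective
`Error = RSS + 5·10⁴·wPGP + 10⁻³·Σ(T^ab)²`. The package also provides
four-fold cross-validation, a label-shuffled negative control,
asymptotic confidence intervals and collinearity-index subset scans on
the sensitivity matrix, and in-silico experiments: null mutants,
CRE-restricted reporter constructs, per-site regulatory weights
w<sub>r</sub> = (RSS<sub>ref</sub> − RSS<sub>mut</sub>)/RSS<sub>ref</sub>
and ranked site-removal curves.

No external data are required: `gapcircuit.synth` generates complete
synthetic studies (PWMs, regions with planted sites, FlyEx-like
gradient profiles, and a two-gene toy circuit forward-simulated from
known parameters) against which every layer is tested.

## Worked example

```python
import numpy as np
from gapcircuit.protocols import run_parameter_recovery
from gapcircuit.synth import FixtureSpec, synth_ground_truth

toy = synth_ground_truth(FixtureSpec(seed=0))   # 2 genes, 3 TFs, 5% noise
print(toy.config.n_free)                        # 22 free parameters

out = run_parameter_recovery(seed=1, toy=toy)   # best of 3 DE fits
print(round(out["fit_rms"], 2))
print(np.sign(out["params"].t_matrix).astype(int))
print(out["n_identified"])
```

Output:

```
22
5.16
[[ 1  1 -1]
 [-1 -1  1]]
0
```

`5.16` is the root-mean-square residual of the refitted model against
the noisy data — at the generating noise floor (≈ 5.4 fluorescence
units) — and the sign matrix reproduces the generating network
topology exactly: gA is autoactivating, activated by the anterior
gradient M1 and quenched by the posterior input M2; gB is the
complement. The final `0` is the number of T entries whose 95%
confidence interval excludes zero at this optimum: regulatory
strengths ride a strong affinity–strength (K·T) ridge at this data
size, so their individual magnitudes are not certified even though
the recovered regulatory logic is correct (see `docs/methods.md`).

A command-line interface mirrors the library
(`gapcircuit synth | scan | activation | simulate | score | fit |
crossval | negcontrol | identify | weights | mutant | reporter |
topology`); `gapcircuit synth --out fx/` writes a self-contained
fixture directory (FASTA, PWM, BED, TSV, JSON) that the other
subcommands consume.

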