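# rflpdelta

Quantifying the loss of OTU detectability in 16S rDNA PCR-RFLP
(ARDRA/CAPS) fingerprinting of bacterial communities, by a
**theoretical-to-actual delta** analysis on mock bacterial communities
(MBCs).

## The problem

Restriction fingerprinting estimates community richness by counting the
bands that AluI digestion of a 799F/U1492R 16S rDNA amplicon pool leaves
on a high-resolution polyacrylamide gradient gel. Two very different
numbers hide behind "how many bands":

* the **theoretical (pre-assembly) count** — digest every community
  member's amplicon *individually*, pool the fragment lists, and merge
  fragments closer than the gel resolution (5 bp) into single bands.
  This is the maximum the fingerprint could reveal;
* the **actual (post-assembly) count** — pool the *templates* first,
  amplify the mixture, then digest. Primer binding preferences,
  competitor templates (plant chloroplast 16S in endophyte work), and
  the detection threshold of gel staining suppress most members.

The ratio of the two — the fold-loss `Δ(g) = N_theoretical(g) /
N_actual(g)` per community size `g` — measures how much diversity a
fingerprint silently discards. `rflpdelta` implements the full pipeline
on synthetic OTU pools with planted ground truth: in silico degenerate
primer matching (IUPAC set-intersection), AluI digestion, gel
resolution/window emulation, randomized (3000-replicate,
multiple-of-five) and stepwise-nested (five composition types) community
assembly, a parametric amplification-bias simulator standing in for the
wet lab, and the comparison layer (four regression families, unbalanced
one-way ANOVA with Tukey-Kramer contrasts, Lilliefors normality
screening).

## The model in brief

For a community with members *i*, equimolar template fractions
`c_i = 1/g` and competitor fraction `f_cp`, the simulator assigns
end-point amplified mass

```
a_i ∝ (w_i · c_i · (1 − f_cp))^γ ,      a_cp ∝ (w_cp · f_cp)^γ ,
```

normalized to Σ = 1. Affinities `w_i` are drawn once per OTU from a
heavy-tailed (Pareto, tail index 0.15) distribution — primer preference
spanning orders of magnitude — and every fragment inherits its OTU's
mass. After merging at gel resolution inside the 50–500 bp window, a
band is visible iff its pooled mass reaches the detection threshold
`τ = 0.02` of the lane. `γ = 0, τ = 0` recovers the theoretical count
exactly; the defaults reproduce the characteristic phenomenology:
observed band counts plateau from ~10 OTUs upward while theoretical
counts keep growing logarithmically, giving fold-losses of roughly 2–7×.

## Worked example

```python
from rflpdelta import (PRIMER_799F, PoolSpec, generate_pool, profile_otu,
                       GelModel, MockCommunity, theoretical_count,
                       BiasModel, simulate_post_assembly)

pool = generate_pool(PoolSpec(n_otus=10, seed=4))
profiles = {r.otu_id: profile_otu(r, PRIMER_799F) for r in pool.records}
print("OTU01 fragments:", sorted(profiles["OTU01"].fragments))

gel = GelModel()                       # 5 bp resolution, 50-500 bp window
community = MockCommunity("demo", tuple(sorted(profiles)), 10)
theo = theoretical_count(community, profiles, gel)
out = simulate_post_assembly(community, profiles, BiasModel(seed=0), gel)
print("theoretical bands:", theo.n_bands)
print("observed bands:", out.n_bands)
print("fold-loss:", round(theo.n_bands / out.n_bands, 2))
```

prints

```
OTU01 fragments: [139, 233, 328]
theoretical bands: 30
observed bands: 4
fold-loss: 7.5
```

The ten OTUs could show 30 distinguishable bands, but under the default
bias model only the fragments of the few dominantly amplified members
stay visible — a 7.5× loss for this community and affinity draw.

The same experiment end to end, at full scale, from the shell:

```sh
rflpdelta run-all --seed 1 --out-dir runs/demo
# seed 1: fold-loss 2.45-7.22, plateau slope -0.112 bands/5 OTUs,
# ANOVA p = 2.53e-05; outputs in runs/demo
```

`runs/demo/` then holds the per-set summary TSVs, the fold-loss table,
the competitor-titration scenarios and a JSON stats report (regression
fits, ANOVA + Tukey-Kramer, Lilliefors). Individual stages are exposed
as `rflpdelta generate | digest | assemble | simulate | stats`.

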