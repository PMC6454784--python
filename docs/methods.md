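# Methods

This note documents the models, conventions and numerical choices behind
`rflpdelta`, in the order the pipeline applies them.

## In silico PCR (module `primers`)

Primer annealing is modelled as exact-or-near-exact string compatibility:
a primer symbol matches a template symbol iff their IUPAC base sets
intersect. This treats template ambiguity codes permissively (an `N` in a
database entry matches any primer base), which is the right bias for
"would this primer bind here" questions; it deliberately ignores
thermodynamics, melting temperature and 3'-end effects. `max_mismatch`
defaults to 0 (a tolerance is not part of the protocol being emulated)
and is configurable.

Amplicons retain the primer footprints at both ends, because physical
amplicons contain primer sequence and gel sizes include it. When several
forward sites exist the 5'-most is used — deterministic, and consistent
with single clean expected-size amplicons. Two extraction modes exist
because the historical in silico step only anchored the forward (799F)
site: `to_end` (default; digest from the forward site to the database
entry's end) and `to_reverse_primer` (end at the nearest downstream
reverse footprint). On generated pools both modes agree by construction
(a reverse footprint is planted at the amplicon 3' end).

Coordinates are 0-based half-open in memory and 1-based inclusive in all
tabular reports.

## Digestion and the gel (module `digestion`)

Digestion is complete: every occurrence of the recognition site
(AluI: `AGCT`, cut between G and C) cuts, overlapping occurrences
included; ambiguous template bases are never cut. Fragment lengths always
sum to the amplicon length.

The 5–11% polyacrylamide gradient gel is reduced to three parameters:

* `resolution_bp` (default 5) — fragments closer than this co-migrate;
* a detection window (default 50–500 bp, the gel's efficient sizing
  range), applied in gel-emulation contexts (pre- and post-assembly
  *in vitro* style counting) and disabled for pure in silico theoretical
  counting;
* `merge_rule` — the instrument specification "a 5 bp difference is
  resolvable" and the counting convention "≤ 5 bp counted once" disagree
  at exactly 5 bp, so both are implemented: `strict` (default; a
  difference ≥ resolution separates bands) and `inclusive` (> resolution
  separates).

Merging is anchor-based greedy clustering on ascending lengths: a band's
representative is its smallest member and a new band opens at the first
length that no longer co-migrates with the anchor. Unlike mean-linkage
chaining this is deterministic, order-invariant and cheap, and it has a
one-line brute-force oracle, which the tests exploit. Band intensity is
not modelled here; abundance-based visibility lives in the bias
simulator.

## Community assembly (module `communities`)

*Randomized design.* Groups of 5, 10, … OTUs drawn uniformly without
replacement within a community; compositions may repeat across the 3000
replicates (with C(50, 5)-scale spaces this is unavoidable and harmless).
A group size equal to the pool size yields exactly one community, hence
the characteristic totals 3000 × 9 + 1 = 27,001 (50-OTU pool) and
3000 × 6 + 1 = 18,001 (35-OTU pool). Every (group size, replicate) pair
consumes its own `SeedSequence` sub-stream, so enlarging the design never
perturbs existing draws.

*Nested design.* Five composition types (I unconstrained, II no focal
members, III/IV 20% focal with independent draws, V all focal) built by
stepwise addition of five members, each community a strict superset of
its predecessor. When a criterion becomes infeasible (a no-focal chain
outgrowing a 27-member non-focal pool at size 30) the shortfall is
topped up from the other stratum and logged, reproducing how a real
collection is forced to compromise.

*Theoretical counting* pools the members' individual fragment multisets
and merges once. It is subadditive (shared bands count once) and, for
nested chains, monotone in community size.

## Amplification-bias simulator (module `bias`)

End-point amplified mass is a one-step power law,
`a_i ∝ (w_i c_i (1 − f_cp))^γ`, rather than a cycle-by-cycle kinetic
model: no kinetic data exist to calibrate per-cycle efficiencies, and the
gel only sees the final mass ranking. A cycle-wise mode
(`mode="cyclewise"`: mass × (1 + efficiency)^30, efficiency
`w/(1+w)`) is provided for sensitivity analysis. Zero template stays
zero at every γ (no `0^0` resurrection), so `f_cp = 1` leaves only the
competitor and `γ = 0, τ = 0, f_cp = 0` is an exact identity with
theoretical counting — the simulator's primary self-check.

**Affinity distribution.** Affinities are drawn once per OTU (keyed by
seed and OTU id, so an OTU keeps its affinity across every community in
a nested chain). The default family is Pareto with tail index 0.15
(log-affinity exponential with ≈ 2.9-decade scale). The choice is
deliberate: the defining observation to emulate is that observed band
counts are already flat at ~10 OTUs while theoretical counts keep
growing. With lognormal affinities that plateau cannot occur — a
lognormal maximum lies in the Gumbel domain, where the gap between the
top order statistics shrinks like 1/√(2 ln n), so the number of members
within the visibility range of the dominant template creeps upward with
community size (empirically the fitted slope never falls below ≈ 0.23
bands per 5-OTU step at any lognormal spread). A regularly varying
(Fréchet-domain) tail keeps the expected number of near-dominant members
constant in n, which is exactly a plateau. Lognormal affinities remain
available (`affinity_distribution="lognormal"`, `sigma_bias`).

**Detection threshold.** A band is visible iff its pooled relative mass
reaches `τ` (default 0.02 of the lane). The value is invented — some
visibility threshold must exist for loss to occur, its magnitude is not
measurable from gel photographs — and configurable. Per-band mass sums
the amplified mass of every contributing fragment (an OTU with two
co-migrating fragments contributes twice, as it would in stain
intensity).

**Competitor.** The chloroplast-like competitor is a single ~1,100 bp
amplicon outside the 50–500 bp window, so it is reported as a separate
`competitor_band_present` flag rather than through the band set.
Competitor titrations (0/35/65/100% of template mass) hold affinities
fixed so the sweep isolates the competitor effect; bacterial band counts
are provably non-increasing in the competitor fraction. Direct vs nested
PCR are represented only as two bias parameterizations, not
mechanistically.

**Default protocol.** The "actual" arm averages over 50 affinity
realizations (seeded sub-streams). A single realization's plateau slope
carries ~0.2 bands/5-OTU sampling noise; with 50 realizations the
fitted slope of the default configuration lies between −0.12 and +0.14
across pool seeds, and the fold-loss range spans roughly 2.3–7×.

## Statistics (module `stats`)

* Four regression families; exponential and geometric (power-law
  `y = a·x^b`) fits use log-linearization, matching the desktop
  statistics packages of the era this analysis style comes from, with
  nonlinear least squares behind a flag. R² is reported on both the
  original scale and the linearized scale because conventions differ;
  the linearized value equals the squared Pearson correlation of the
  transformed variables. "Regression coefficient" means the slope-like
  coefficient `a`.
* One-way ANOVA tolerates unequal group sizes; the pairwise procedure is
  therefore Tukey-Kramer (`SE = sqrt(MSW/2 · (1/n_i + 1/n_j))`, q from
  the studentized range distribution).
* Lilliefors p-values come from a seeded Monte Carlo null (default
  10,000 draws, cached per sample size) — reproducible and calibrated
  (empirical level 0.045–0.054 at n ∈ {30, 100}); published-table
  interpolation is available as `mode="table"`.
* The delta report never divides by zero: groups with zero actual bands
  are flagged instead.

The full experiment treats the per-group-size plotted means of each of
the five data sets (three randomized in silico pools of 50/50/35 OTUs,
nested pre-assembly, nested post-assembly) as experimental units — group
sizes 10/10/7/6/6 — mirroring the unbalanced layout the analysis style
is designed for.

## Synthetic pools (module `synth`)

The generator emulates the statistical structure of real inputs: ~700 bp
amplicons carrying an exact expansion of the degenerate forward primer,
3–5 planted AluI fragments per amplicon (uniform), a 20% minority of
multi-operon OTUs pooling 6–11 fragments (intragenomic 16S
heterogeneity), 45/72 focal-tagged members, and a ~1,100 bp competitor.
Within an OTU, fragment lengths are pairwise ≥ resolution apart, and
accidental restriction sites or stray primer matches are removed by
local resampling (O(length), no whole-sequence rejection), so digesting
the emitted FASTA reproduces the planted ground truth exactly — the
round-trip that anchors the whole test suite. Min/max fragment bounds
default to the 50–500 bp window so theoretical in-window and windowless
counts coincide on default pools.

What the generator does **not** emulate: phylogenetically realistic 16S
evolution, realistic taxonomic composition, sub-50 bp fragments,
chimeras, heteroduplexes, or polymerase error. Passing tests therefore
demonstrate the correctness of the counting and comparison machinery and
the qualitative behaviour of the bias model — not quantitative
predictions for any real community.

An optional `distinct_across_otus` mode allocates lengths from a
pool-wide grid (2 × resolution spacing inside the window) so no two OTUs
share a band; it exists for small fixtures where exact band arithmetic
(union deficits of planted collisions, 4-bands-per-OTU counts) is
asserted, and it errors out when the grid is exhausted rather than
silently relaxing the guarantee.

## Scales and seeds

Default problem sizes — 3000 replicates per randomized group (72,003
communities over three pools), 30 nested communities, 50 bias
realizations, 10,000-draw Lilliefors nulls — run in a few seconds on one
CPU; the test suite uses the same sizes where a count is the claim
(27,001/18,001) and smaller, structurally identical configurations
elsewhere. All randomness flows from one master seed through named
`SeedSequence` sub-streams (`pool:<name>`, `random:<name>`, `nested`,
`bias:<i>`, `lilliefors:<set>`); two runs with the same configuration
are byte-identical in every output file.

## Known limitations

* The bias model's free parameters (γ, tail index, τ) are not
  identifiable from band counts alone; the defaults are a
  parameterization of the observed regime (strong preference, early
  plateau), not estimates. Quantitative fold-loss values for real
  communities are out of scope.
* The gel model has no band-intensity output, no smearing, and no
  partial digestion.
* The ANOVA treats plotted group means as independent units, as the
  original analysis style does; nested-design means at different sizes
  share members, so the independence assumption is inherited, not
  endorsed.
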