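# Methods

This note documents the models, parameter choices and numerical
conventions behind each module, what the synthetic generator does and
does not emulate, and the known limitations.

## Amino-acid scoring

**Units and basis.** Profiles store g per 100 g sample; scoring against
a reference pattern needs mg per g protein, obtained as
`g/100g × 1000 / protein_pct`. The conversion basis (`protein_pct`,
total protein by mass) is a profile field because fermented samples
differ widely in it. Default bundled patterns (editable TSVs under
`maotofu/data/`):

| pattern | values (mg/g protein) |
|---|---|
| WHO/FAO (1973) | Ile 40, Leu 70, Lys 55, Met+Cys 35, Phe+Tyr 60, Thr 40, Val 50 |
| whole egg | Ile 54, Leu 86, Lys 70, Met+Cys 57, Phe+Tyr 93, Thr 47, Val 66 |

Trp is excluded throughout: 24 h HCl hydrolysis at 110 °C destroys it,
leaving the 17 measurable acids. The sulfur (Met+Cys) and aromatic
(Phe+Tyr) pairs are summed before division wherever the reference uses
combined entries.

**RC/SRC.** `RC_k = RAA_k / mean(RAA)`, so mean(RC) ≡ 1 — asserted to
1e-9 in tests as an algebraic identity. `SRC = 100 − 100·CV` with CV the
coefficient of variation of RC. CV uses the **population** standard
deviation (n divisor) by default: the defining formula is "sd/mean"
without qualification, and the population form makes SRC exactly 100 for
a uniform profile at any n; `sample_sd=True` switches to the n−1
divisor. The limiting amino acid is the argmin of RC with alphabetical
tie-break for deterministic reporting.

**Fuzzy closeness.** μ = 1 − c·Σₖ|αₖ−uₖ|/(αₖ+uₖ) over the 7 non-Trp EAA
terms, c = 0.09. Each term lies in [0, 1], so μ ∈ [1 − 7c, 1] = [0.37, 1];
the lower bound is attained by an all-zero profile, the upper by an
egg-identical one. μ is symmetric in (α, u) and invariant under joint
rescaling of a term's pair. An alternative reading — choose c per-profile
so the result spans [0, 1] exactly — was considered and rejected: it
makes μ incomparable across samples.

**TAV.** TAV = content / threshold (both mg/100 g), contributing iff
TAV > 1 strictly. The reciprocal convention circulates in parts of the
literature; it is available via `invert=True` but the default is the
direction in which "greater than 1" means a taste contribution. The
bundled thresholds (Asp 100, Glu 30, Ala 60, Gly 130, Ser 150, Thr 260,
Pro 300, Arg 50, His 20, Ile 90, Leu 190, Lys 50, Met 30, Phe 90,
Val 40 mg/100 g) are the values standardly used in food-taste work;
Cys and Tyr have no established threshold and scoring them raises a
named error rather than inventing one.

## Volatile semi-quantification

Single-point internal-standard model `C = (Ac/Ais)·Cis`, assuming unit
relative response factors — semi-quantitative by construction. The
default in-matrix IS concentration, 0.14 μg / 5.1 mL ≈ 0.0275 μg/mL,
is the naive dilution of a 100 μL spike of 1.4 mg/L 2-octanol into
~5 mL of extract; it is a documented assumption and every API takes
`cis` explicitly. Relative percentages close to 100 within each sample
before filtering; the ≥1 % report uses a strict inequality
("surpassing"). Compound identity across samples is exact name match
after case-folding and whitespace collapse — no spectral matching.

## Community profiling

**Demultiplexing** is exact-match on the 5′ 16-mer, no mismatch
tolerance (deterministic; at CCS accuracies ≥ 0.90 barcode errors are
rare and the cost is a slightly higher unassigned count). The barcode's
reverse complement at the 3′ end is stripped when present.

**QC** keeps reads with length in [1400, 1800] inclusive and predicted
accuracy ≥ 0.90 (both bounds inclusive); failures are tallied by first
reason (length before accuracy).

**OTU clustering** is an abundance-sorted greedy centroid scheme
re-implemented from first principles in the UCLUST style (the original
tool chain — UCLUST/Vsearch/PyNAST/QIIME — is out of scope). Queries in
decreasing size (ties by sequence) join the first centroid, in founding
order, with identity ≥ 0.97, else found a new centroid. Identity is
matches / alignment columns under global alignment with match +1,
mismatch −1, linear gap −2, terminal gaps penalized — stated explicitly
because "97 % similarity" admits several definitions. The clusterer is
validated against an exhaustive pairwise-matrix reference on random
instances of ≤ 20 sequences. Greedy centroid assignment is
order-dependent by nature; the fixed ordering makes it reproducible.
Chimera removal is a no-op hook.

**Diversity.** Shannon H = −Σ pᵢ ln pᵢ (natural log, zero-count OTUs
dropped). Rarefaction subsamples without replacement at each depth with
a seeded generator; means are checked against the multivariate
hypergeometric closed form E[S_obs] = Σᵢ (1 − C(N−nᵢ, d)/C(N, d)).

**Reporting.** Dominance threshold is strict (> 1 %); cumulative
percentages accompany the ordered list. Taxon labels come from synthetic
truth or user annotation — database taxonomy assignment is out of scope.

## Correlation and networks

Spearman by default (robust to monotone transforms, standard for
compositional microbiome–metabolite panels); Pearson by flag. Two-sided
p-values: exact permutation distribution (all n! pairings, enumerated)
for n ≤ 8, t approximation otherwise — at n = 30 the empirical type-I
error of the 0.05 test sits within the binomial band (measured ≈ 0.044).
Stars: *** p < 0.001, ** p < 0.01, * p < 0.05 on raw p-values;
Benjamini–Hochberg `p_adj` is computed on request but off by default to
mirror common heatmap practice. Constant vectors are reported as missing
with a reason, not silently dropped.

Network edges require |rho| ≥ 0.6 **and** p < 0.05 — invented defaults,
both configurable. Relative abundances are compositional; correlations
on them can be spurious (closure effect). A CLR transform
(`clr_transform`, pseudocount 0.5) is provided but off by default; the
synthetic planted-link checks therefore run on raw abundances.

## Synthetic data: what it emulates, what it does not

* **Profiles**: log-normal noise (positivity) with exact mean and
  target CV around class means; defaults anchor to reported
  compositions of the three product classes (e.g. Lys 7.35 g/100 g in
  the inoculated class, Pro 5.29 g/100 g in the naturally fermented
  class, totals ≈ 54.7 / 78.1 / 76.3 g/100 g, protein 18.4 / 25.1 /
  22.1 %), with the remaining acids set to realistic soy-hydrolysate
  levels. Default CV 0.05 ≈ triplicate analyzer repeatability; 3
  samples per class matches triplicate determination.
* **Volatiles**: areas constructed as the exact inverse of the
  quantification formula, so round-trip recovery is a machine-precision
  check of the algebra, not of chromatography. No co-elution, drift or
  response-factor realism.
* **Reads**: independent random templates per taxon (pairwise
  divergence ≫ 3 %, so 97 % clustering must separate them), point
  mutations at 0.5 % per base (below half the 3 % radius), lengths in
  [1400, 1800], accuracy N(0.97, 0.02) floored at 0.90 for non-decoys.
  Decoys violate exactly one QC criterion each. No chimeras, no
  per-base quality profile, no homopolymer error structure —
  passing tests show the pipeline logic is right, not that it is robust
  to real PacBio error modes.
* **Taxa–metabolite matrices**: Gaussian copula; a link of strength s
  uses latent correlation s, giving Spearman ρ = (6/π)·asin(s/2) in
  expectation, monotone in s and exactly ±1 at s = 1 since observed
  values are strictly monotone transforms of the latents. The taxa
  matrix is returned unclosed (raw abundances) so planted links are
  exact; `to_relative_pct` applies the closure separately. Defaults
  n = 30 samples, 5 taxa, 8 metabolites.

All generators draw from per-stage child streams of the config seed:
identical configs give byte-identical outputs, and the amino-acid
draw never perturbs the read draw.

## Problem sizes

The test suite and the acceptance script run at desk scale as a design
choice: 50 random clustering instances of ≤ 20 sequences of 70 bp
(the identity definition is length-free, so short sequences exercise the
same code paths), 20 seeds × 2 planted links for recovery, 900 null
pairs for type-I calibration, 1000 replicates for rarefaction and
zero-strength checks. Dataset-scale quantities from sequencing studies
of this kind (10⁵ reads, 10⁴–10⁵ OTUs, network degrees over hundreds of
taxa) require the raw reads and are outside what a synthetic desk run
can or should reproduce.

## Known limitations

* Semi-quantification ignores response factors; concentrations are
  relative to 2-octanol, not absolute.
* Greedy OTU clustering is a stand-in for the full UCLUST/Vsearch
  behavior (no banded heuristics, no chimera detection).
* Exact permutation p-values are enumerated only up to n = 8 (8! =
  40,320 pairings); beyond that the t approximation is used.
* No compositional correction by default in correlation; enable
  `clr_transform` when analyzing closed data.
* The bundled reference patterns and taste thresholds are editable data,
  not fitted quantities; swap in study-specific tables as needed.
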