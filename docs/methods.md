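# Methods

## The scientific setting

A stress stimulus (heat, or arsenite at ambient temperature) activates the
transcription factor HSF1, which binds Heat Shock Elements (HSEs) across
the genome. Two competing pictures of how the stimulated binding landscape
arises from the ground state are: (i) HSF1 occupies different sites before
and during the response; (ii) HSF1 occupies the *same* sites throughout,
and stimulation amplifies low-level basal binding past the peak-calling
detection threshold. The package's analyses discriminate between these:
under (ii), untreated-condition signal at the locations of peaks "acquired"
only after stimulation must exceed matched random background, and must
rank-correlate with the stimulated signal.

## Generative model of the synthetic data

The generator (`peakamp.synth`) encodes hypothesis (ii) explicitly, so that
the analyses have known structure to recover.

**Site catalog.** Each cell line carries `n_sites` (default 3000) binding
sites; a configured fraction (default 0.5) of each catalog is shared
between the two cell lines. Site centers are uniform over the genome
conditional on a minimum separation (default 1000 bp), sampled exactly via
the order-statistics construction (sorted uniforms on a shortened axis,
re-inflated by the separation). Basal intensity b_i — the expected read
count contributed by the site in the untreated condition — is log-normal
(default log-mean ln 12, log-sd 1.0) and drawn **independently per cell
line** even at shared sites: basal binding patterns are cell-line-specific,
which is what makes untreated samples cluster by cell line.

With the default background of 0.02 reads/bp and 300-bp peaks, median
basal per-base signal at a site is (12/300 + 0.02)/0.02 = 3× background.

**Amplification.** A stimulus t multiplies each active site's intensity by
`A_t · exp(δ_it)` with δ ~ N(0, σ_δ²), σ_δ = 0.3. Defaults A_HS = 20 and
A_As = 15 give the heat stimulus the modestly stronger response; the
absolute values are test-facing choices (no empirical amplification factor
is available), chosen so that detection rates change qualitatively between
basal and stimulated samples. A small fraction of sites (default 5% per
stimulus) is truly stimulus-exclusive: amplified only under that stimulus,
but still carrying basal intensity always — basal binding anticipates both
responses. Everything else is constitutive (amplified under both).

**Coverage.** Per-base rates are background λ0 plus each site's intensity
spread by a discretized Gaussian kernel (sd 75 bp, the ChIP fragment
scale, truncated at ±4 sd and normalized to sum 1); counts are Poisson and
scaled by a per-replicate depth multiplier (defaults 1.0 and 0.6) so that
depth normalization has something to undo. Poisson (rather than negative
binomial) suffices because every downstream test is rank-based.

**Peak detection.** A site is emitted as a called peak (center ± 150 bp)
with probability `1/(1 + exp(-(log I - θ)/s))`, θ = 4, s = 0.5, on the
depth-scaled intensity I. At the defaults this detects ~5–10% of sites in
untreated samples and >90% after 20× amplification — treatment- and
condition-exclusive peak *sets* therefore arise mostly from the detection
threshold, not from distinct site catalogs, mirroring the amplification
hypothesis. Setting `plant_sites=False` yields pure-background null tracks
(used for p-value calibration).

**PRO-seq.** Stranded gene-body pileups: genes are placed sequentially per
chromosome with random gaps, uniform body rate per gene (log-normal across
genes, default median 0.05 reads/bp). An activated subset (default 15% of
genes, half shared between stimuli) is multiplied by a per-gene fold
(default means 8× for heat and 5× for arsenite, log-normal scatter 0.2).

**ATAC.** Class-dependent baselines (promoter 0.2, dTRE/enhancer 0.1,
remote site 0.02 reads/bp over the element) on a 0.005 background, plus a
stimulus increase of 0.1 reads/bp confined to ±250 bp of remote site
centers under heat — accessibility gain localized exactly at remote
binding sites, invisible in flanking bins.

**What the generator does not emulate.** Read-level artifacts (duplicates,
mappability, GC bias), fragment-length variation, copy-number effects,
peak-width variation, and correlated biological replicate noise. Passing
tests demonstrate that the *analyses* recover designed structure from
Poisson-noisy multi-assay data; they do not validate robustness to
alignment artifacts in real libraries.

## Analysis conventions

- **Coordinates** are 0-based half-open throughout (BED convention); the
  ±1 kb promoter is the 2000-bp window `[tss-1000, tss+1000)`, strand-
  symmetric. Overlap means ≥ 1 shared base (configurable `min_overlap_bp`);
  strand is ignored for overlap. Merging never coalesces merely touching
  intervals. Peaks spanning a promoter boundary are attributed whole by
  ≥ 1-bp overlap; no fractional attribution is attempted.
- **Subtraction** is whole-interval exclusion (blacklist semantics): an
  interval touching the exclusion set anywhere is dropped, never trimmed.
- **Venn counting** is per merged locus of the union, so
  `only_a + only_b + common` is a well-defined percentage denominator; how
  one peak overlapping two peaks of the other set should be counted is
  otherwise ambiguous.
- **Background sampling** draws chromosomes proportional to length and
  starts uniformly, then filters against exclusions without topping up, so
  the retained count is ≤ requested and is always reported. Collisions
  between draws are allowed (uniform semantics) and logged.
- **Mann–Whitney**: two-tailed; exact enumeration of the permutation
  distribution of U (midranks, tie-aware) whenever combined n ≤ 16, else
  normal approximation with tie correction and continuity correction. The
  exact branch covers ties too because the approximation is unreliable at
  tiny n. Degenerate all-equal data returns p = 1 with a warning. No
  multiple-testing correction is applied inside operations; reported
  p-values are raw.
- **Spearman**: midrank rho; exact permutation p for n ≤ 8 (8! = 40,320
  permutations enumerated), t approximation above. The exact cutoff stops
  at 8 because 10! permutations buys no practical accuracy for its cost.
- **Affinity matrix**: rows are the union-merge of all samples' peaks;
  values are depth-scaled read counts summed per interval, log2(x+1)-
  transformed before correlation, clustering, and PCA. The transform is an
  explicit, documented choice.
- **PCA**: samples are observations; each peak is centered across samples
  before the SVD, so identical samples coincide and the trivial depth
  component is removed. Sign convention: largest-magnitude sample score
  per component is positive. Clustering uses average linkage on
  1 − Spearman rho with columns pre-sorted by sample id for deterministic
  leaf order.
- **PRO-seq 3' normalization**: factors are medians over genes ≥ 60 kb of
  reference/sample density in the last 20 kb of the gene body excluding
  the final 500 bp, on the sense strand. Rationale: minutes after a
  stimulus the polymerase wave has not reached distal gene bodies, so
  these windows act as an internal standard; the exact window is
  configurable because no canonical choice exists.
- **Gene bodies** are `[TSS+500, TES)` (sense strand) to exclude the
  promoter-proximal pause; folds use pseudocount ε = 0.5 so silent genes
  yield bounded values. Fold activation is reported relative to the
  not-activated genes' mean fold, cancelling global drift.
- **HSE model**: exact consensus (runs of ≥ 3 alternating GAA/TTC cores at
  pentamer spacing, either phase, maximal), not a position-weight matrix —
  an explicit consensus is exactly reproducible and admits an exhaustive
  oracle. A per-unit core mismatch budget exists (default 0). N never
  matches. Density nulls assign features to regions by midpoint so
  inside + outside = total exactly; regions are merged before length
  computation, making the ratio invariant to region splitting.
- **Determinism**: every random draw flows from one seed through named
  substreams (`rng(seed, crc32(stage_name))`), so stage insertion does not
  perturb other stages and identical configs give byte-identical outputs.

## Problem sizes

The default toy genome is 4 chromosomes × 5 Mb with 3000 sites per cell
line, which keeps a full simulation in seconds of CPU time; this default
is used for the headline amplification analysis. Multi-assay end-to-end
runs, correlation-structure and separation analyses use 0.4–1 Mb
chromosomes with 100–600 sites and proportionally fewer genes/elements —
sizes at which every targeted effect is still decisively detectable, as
the acceptance script's output shows. Null calibrations use 200-kb
single-chromosome genomes across 100–200 seeds.

## Known limitations

- The accessibility-peak universe at desk scale is the annotated open
  elements (promoters, dTREs, enhancers); no ATAC peak caller is included.
- Activation labels are generator truth (or user input); the package does
  not fit a differential-expression model.
- Peak calling itself is out of scope: called peaks are inputs (real data)
  or detection draws (synthetic data).
- dTRE condition-specificity is taken from input file labels; no dTRE
  discovery from nascent-RNA signatures is performed.
- bigWig is not read or written; bedGraph is the canonical track format.
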