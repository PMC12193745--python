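# Methods

## The procedure and its assumptions

`genusrank` operationalises genus delimitation as a calibration exercise:
the existing, accepted genera of a higher taxon define what "genus-level
divergence" means there, and a candidate lineage is judged against that
empirical distribution rather than against a universal cutoff. The
procedure assumes

1. a trustworthy rooted phylogeny of the higher taxon (topology only;
   branch lengths are ignored),
2. monophyly of every genus entering the calibration (audited in step 1;
   offenders halt the run unless explicitly excluded or the
   `allow_nonmonophyletic` audit-and-continue switch is set, in which case
   they are dropped from the calibration),
3. an approximately normal distribution of sister-comparison means, so that
   μ ± 2σ brackets ~95 % of legitimate genus-level divergences. The
   Shapiro–Wilk test guards this assumption; a rejection (p ≤ 0.05)
   downgrades the report with a prominent warning instead of halting,
   because the banding is still interpretable as an empirical range, and
4. comparability of divergences within the higher taxon — the calibration
   is never meant to be carried across distantly related groups, whose
   genus-level divergences can differ severely.

One comparison contributes one observation regardless of how many species
pairs it averages. This deliberately weights each sister split equally:
species-rich genera would otherwise dominate μ and σ. When a genus is
sister to a clade of several genera, the focal genus is compared against
all species of all of them; the resulting mean is a conservative estimate
of the focal lineage's distinctiveness.

## Distances

K2P with pairwise deletion: a site enters a pair's counts only when both
residues are unambiguous A/C/G/T. IUPAC ambiguity codes are treated as
missing rather than as fractional observations. Complete deletion
(discarding a column whenever *any* sequence is gapped or ambiguous there)
is available via `deletion_mode="complete"`; on ragged alignments of
GenBank fragments the two modes give visibly different matrices, which is
why the choice is prominent in the configuration and in reports. Distances
are percent substitutions per site, held at full precision internally and
rounded to two decimals only in written tables.

Saturated pairs — where 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 makes a logarithm
undefined — are recorded as `NA`, logged with the pair's identifiers,
counted in the report, and excluded from every downstream mean and SD. At
genus-level mitochondrial divergences (≲ 35 %) saturation is rare; it
becomes common only beyond ~100 % true distance.

Representative selection keeps, per species, the record with the most
unambiguous A/C/G/T residues (not the longest raw string: gaps and Ns carry
no distance information), breaking ties by lexicographic accession and then
record id for determinism.

## Statistical choices

- Aggregate σ uses the sample (n − 1) denominator over comparison means.
- Per-comparison and within-genus SDs default to the sample denominator;
  `sd_denominator="population"` switches to n for sensitivity analyses,
  since the descriptive convention differs between software packages.
- Band boundaries are inclusive toward the genus side: a value exactly at
  μ − 2σ is a (weak) genus, a value exactly at μ + 2σ a (high) genus; only
  strictly beyond two sigma rejects or elevates.
- A verdict *supports genus rank* when it is any of the middle three bands.
  Note that "all comparisons within one sample SD of their own mean" is not
  a meaningful expectation: for n observations the largest standardized
  deviation is at most (n − 1)/√n, and with n ≤ 4 it always exceeds 1 for
  some observation unless the values are nearly equispaced, while it can
  never reach 2. Recovery checks therefore assert qualification for genus
  rank, not membership in the innermost band.
- `classify` refuses a zero-σ distribution (degenerate calibration).

## The simulator

The generator exists so every pipeline stage can be exercised without
downloading data, under the exact model the distances assume: K2P with
equal base frequencies, independent sites, no indels, and no among-site
rate heterogeneity. Substitution along a branch of expected length *d* uses
the closed-form probabilities (with κ = α/β the transition/transversion
rate ratio and d = (α + 2β)t):

    P(transition)        = 1/4 + 1/4 e^(−4βt) − 1/2 e^(−2(α+β)t)
    P(each transversion) = 1/4 − 1/4 e^(−4βt)

verified in the tests against matrix exponentials of the K2P rate matrix.
Reproducibility comes from a single NumPy generator keyed by the seed and a
fixed draw order: root sequence first, then one uniform per site per branch
in preorder.

Scenario geometry: genus MRCAs hang off a zero-length backbone at depth
(inter − intra)/2 from the root, species tips a further intra/2 below, so
*every* between-genus tip-to-tip path equals `inter_depth` and every
within-genus path equals `intra_depth` exactly. Defaults are chosen to
mirror a genus-level Cytb survey: κ = 4 (a typical mammalian mitochondrial
transition/transversion rate ratio), 8 % within- and 21 % between-genus
divergence (the middle of the observed vespertilionine ranges), and 10,000
sites, long enough that single-pair estimation error (SD ≈ 0.4 % at 17 %
truth) is small against the band widths. Recovery and end-to-end runs in
the tests and the acceptance script use a 5-genus × 3-species scenario at
those defaults and 50 replicate pairs per distance point — desk-scale sizes
that keep the whole suite in seconds while leaving Monte-Carlo error well
inside the asserted 3-SE envelopes.

What the simulator does **not** emulate: codon structure and selection on a
protein-coding gene, rate variation among sites and lineages, indels and
ragged sequence ends, misidentified or chimeric GenBank records, and
phylogenetic error. Passing recovery tests therefore show the machinery is
correct under the model's own assumptions, not that real Cytb data meet
them; gap handling and saturation paths are exercised separately with
hand-crafted alignments and deliberately extreme branch lengths.

## Numerical and degenerate-input conventions

- Distance matrices are exactly symmetric with a zero diagonal by
  construction; `NA` round-trips through the TSV writer/reader.
- A pair with zero overlapping unambiguous sites is an error, not a zero.
- Sister-comparison enumeration is invariant to child order; reciprocal
  single-genus pairs are deduplicated by the unordered pair of genus sets,
  while genus-versus-lineage comparisons stay per focal genus.
- A genus whose MRCA is the root has no sister and is skipped with a
  warning; a run that ends with fewer than two comparisons aborts as
  insufficient data.
- Fewer than three comparison means, or constant means, leave the
  Shapiro–Wilk fields unset with a degenerate-distribution warning.

## Known limitations

- The calibration inherits every bias of the reference taxonomy: if the
  accepted genera of the higher taxon are themselves over- or
  under-split, the band moves with them.
- Single-marker mitochondrial distances reflect the maternal genealogy
  only; introgression or incomplete lineage sorting can displace them from
  the species divergence.
- The within-genus profile summary averages profile means without
  weighting by species count; like the sister aggregate, it treats each
  genus as one observation.
- Published aggregates can differ in conventions (deletion mode,
  SD denominator) that are rarely stated; when comparing against reported
  values, both switches may need to be explored.
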