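# Methods

## Distance model

Pairwise distances use the Kimura 2-parameter (K2P) model, which assigns
one rate to transitions (A↔G, C↔T) and another to transversions. With
transition and transversion proportions P and Q over the sites compared for
a pair, the distance in substitutions/site is
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q).

**Missing data.** Sites where either sequence carries a gap, N or any IUPAC
ambiguity code are excluded per pair (pairwise deletion), so each pair has
its own count of compared sites; complete deletion (drop a column when any
sequence is ambiguous there) is available as an option. Pairwise deletion
is the default because Sanger-derived herbarium data is sparse and ragged,
and per-pair site counts are what the NA bookkeeping reports. How partial
ambiguities (e.g. R against A) should be counted is genuinely
convention-dependent; here every non-ACGT symbol is missing, which is the
conservative choice.

**Degenerate pairs.** A pair whose log arguments are non-positive is
saturated: its distance is undefined (NA), never clamped, because clamping
would silently bias the minimum-interspecific statistic downward. A pair
with zero comparable sites carries a distinct "no sites" flag. Pairs with
fewer than `min_sites` (default 100) compared sites are also set NA with a
warning — 100 sites is small enough never to trigger on the ~641–750 bp
loci this tool targets while still guarding against distances computed from
tiny overlaps.

## Barcode-gap statistics

For each species: MaxID = maximum intraspecific distance (NA for
singletons), MinID = minimum distance to any heterospecific specimen, plus
the nearest heterospecific's name. Globally: the gap exists iff the
smallest interspecific distance exceeds the largest defined intraspecific
distance. Design choices:

* Singleton species contribute no intraspecific information; they are NA
  rows and are excluded from the global MaxID rather than counted as 0.
* Species pairs whose minimum interspecific distance is exactly zero are
  reported as `zero_separation_pairs` **before** any exclusion is applied.
  Excluding such species from the headline table is an explicit analyst
  decision (`exclude_species`); the pipeline never drops them silently.
* If no species has two individuals the global MaxID is undefined; the gap
  verdict then degenerates to "is there any interspecific divergence at
  all" (MinID > 0).
* Report tables show percent (distance × 100) rounded half-up to 2
  decimals; NA renders as an en dash. On-disk matrices always stay in
  substitutions/site.

## Trees and monophyly

The tree stage is deliberately a **neighbor-joining surrogate** for full
model-based phylogenetic inference: barcoding monophyly checks need
topology, not posterior probabilities, and NJ on the same K2P matrix is
fast and deterministic. Saitou–Nei agglomeration minimizes
Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), with ties broken by the
smallest (row, column) index pair in the current label order so runs are
byte-reproducible. Negative branch lengths (possible with noisy,
non-additive matrices) are clamped to zero with the deficit logged —
harmless for monophyly, which uses topology only. Rooting places the root
at the midpoint of the single edge separating the declared outgroup; a
non-separable outgroup is an error, not a silent rearrangement. A species
is monophyletic iff some node of the rooted tree subtends exactly its
specimens; singletons are trivially monophyletic. Matrices with NA entries
cannot be used for NJ; the error message points to the `min_sites`/
exclusion remedies.

## Sequence simulator

The generator emulates a small multi-locus barcoding study: a star species
tree whose root sequence is i.i.d. uniform over {A,C,G,T}; each species
ancestor evolves along a stem of expected length (d_inter − d_intra)/2 and
each individual along a further d_intra/2, so by Markov additivity expected
pairwise distances are d_intra within and d_inter between species.
Per-site changes are drawn from the K2P transition probabilities
(βt = d/(κ+2), αt = κd/(κ+2)), which round-trip through the distance
estimator to 1e-10. An `overlap_pair` makes two species share one ancestor
with zero-length stems — their expected separation collapses to d_intra,
and to exactly zero when d_intra = 0 — emulating nominal species that
barcodes cannot split. One outgroup specimen at expected distance
`d_outgroup` (default 0.05) supports rooting.

Defaults are frozen to a realistic herbarium study design: 10 species with
per-species specimen counts (2, 2, 3, 8, 5, 5, 6, 3, 3, 3) totalling 40,
loci of 641/730/750 aligned bp named ITS/matK/trnL-trnF, d_intra = 0.002
and d_inter = 0.01 (the ~0.2%/0.3% scale typical of congeneric grasses),
κ = 2, and one overlap pair.

What the simulator does **not** model: indels (output is trivially
aligned, so alignment quality is untested), within-species coalescent
structure, rate heterogeneity across sites, nested species relationships
(a star tree only, though any of these could be layered on), and
chimeric/contaminated reads. Passing tests therefore demonstrate the
correctness of the distance/gap/tree machinery, not robustness to
alignment error or deep phylogenetic structure.

With the design above, the concatenated barcode gap is intentionally
narrow: expected intraspecific separation 0.2% versus interspecific 1% on
~2.1 kb leaves the extreme order statistics (max of ~24+ intraspecific
pairs vs min of ~250+ interspecific pairs) close together, so a minority
of replicate datasets show no gap — as real studies at this divergence
scale sometimes do. The acceptance script reports the measured recovery
rate rather than asserting it away.

## Flow-cytometry simulator and estimator

Synthetic runs draw non-debris events equally from two normal populations
— reference (mean `ref_mean`, sd = CV·mean) and sample (mean
`ratio·ref_mean`) — plus optional debris from an exponential at 0.2× the
smaller peak mean (low-channel clutter; the scale is a package choice);
negative draws are redrawn. Defaults follow routine practice: ≥ 10,000
nuclei per run, triplicate runs, peak CVs around 5%.

Peak detection: 512-bin histogram, 5-bin moving-average smoothing, the
requested number of highest local maxima at least 10 bins apart (the
histogram is zero-padded so degenerate single-bin spikes at the range edge
are still found), an initial sd from the full width at half maximum, then
two rounds of mean/sd re-estimation from raw events within ±2.5 sd. The
±2.5 sd truncation biases the sd slightly low (≈5%), which is immaterial
for the mean-ratio estimate and acceptable for CV-based QC at the 10%
threshold. Which peak is the reference must be declared (`smaller` or
`larger` mean): real reference species bracket samples from both sides, so
positional auto-assignment would be ambiguous. QC passes only when both
CVs are strictly below the threshold (default 10%). Replicate estimates
are averaged; a replicate whose peaks cannot be detected is flagged and
skipped, never fatal to the batch.

The estimator is scale-invariant (multiplying all channel values by a
constant leaves 1C unchanged), so channel calibration does not matter —
only the within-run ratio does, which is exactly the internal-reference
rationale.

## Numerical and I/O conventions

* Distances are stored and serialized in substitutions/site; percent
  appears only in formatted reports.
* Distance matrices: square CSV with "NA" plus lower-triangle
  PHYLIP-style text. Trees: newick via scikit-bio. Concatenations ship
  with a `locus = start-end` partitions file (1-based, inclusive).
* FASTA headers are matched to metadata by their first whitespace- or
  pipe-delimited token, tolerating "voucher accession species" tip-label
  styles; metadata is a 3-column TSV (specimen_id, species, status with
  status ∈ {native, non-native, outgroup}).
* All simulation randomness flows through one `numpy` Generator seeded
  once per run; identical seeds give byte-identical FASTA/event files.
* The test suite and the acceptance script use reduced problem sizes
  (e.g. 50×10 kb pairs, 100 replicate designs, 200 random trees, 20,000
  flow events) chosen so the whole battery runs in seconds while keeping
  Monte-Carlo standard errors well inside the asserted tolerances.

## Known limitations

* Only the K2P distance is implemented (plus its Jukes–Cantor limit as a
  cross-check); no TN93/GTR distances or bootstrap support.
* NJ is the only tree method; no model-based inference or support values.
* The tool consumes pre-aligned FASTA; it performs no alignment and no
  chromatogram handling.
* Flow input is plain one-column text; binary FCS parsing, gating,
  compensation and doublet discrimination are out of scope.
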