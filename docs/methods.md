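# Methods

This note records the models, conventions and calibration choices behind
`plastobarcode`, in the spirit of a statistical-software methods appendix.

## Coordinates, alphabets, labels

All internal coordinates are 0-based half-open; 1-based positions appear only
in report columns explicitly marked as such (window midpoints). Sequences are
normalised to upper case with U→T and validated against the IUPAC nucleotide
alphabet plus `-`. Sample metadata travels in FASTA headers as
`sample_id|species|tissue`; when the tissue field is absent, a `_leaf` suffix
on the sample id marks leaf material and everything else defaults to
`unknown`. This dialect is the package's own convention — public records
rarely encode tissue, and only the `_leaf` suffix is an established usage in
the wood-barcoding literature.

## Nucleotide diversity and hotspot calling

Pi is Nei's nucleotide diversity computed as the *uncorrected* average
pairwise difference proportion — no multiple-hit correction — matching the
convention of the DnaSP-style sliding-window analyses this package mirrors.
The default masking policy is **complete deletion**: an alignment column is
removed for every pair if any sequence carries a gap or ambiguity there.
Pairwise deletion is available but non-default; the two disagree once missing
data are present, so report metadata names the policy in use.

Windows start at 0 and advance by `step` (defaults 800/100 columns); only
full windows are emitted, except that an alignment shorter than one window
yields a single full-length window with a warning. Two routes compute the
same quantity: `nucleotide_diversity` iterates explicitly over all n(n−1)/2
pairs, while `sliding_window_pi` uses per-column allele counts
((n² − Σc²)/2 differing pairs per column) with prefix sums. The suite
cross-checks one against the other on random alignments; a window with no
usable column carries an explicit undefined flag rather than a NaN.

Hotspots are maximal unions of overlapping or touching windows whose Pi
strictly exceeds the threshold (default 0.005, applied per window — whether a
regional mean would be more appropriate is an open question upstream, and the
per-window rule is the simpler, more sensitive choice). Called intervals
therefore extend up to one window beyond a planted divergent block on either
side. Names come from overlapped genes (hyphen-joined, first-occurrence
order) or, for intergenic hotspots, the two flanking genes.

## K2P distances, barcoding gap, ISR

Transitions are A↔G and C↔T; everything else is a transversion. With P =
ts/n and Q = tv/n over comparable sites, d = −½ ln[(1 − 2P − Q)√(1 − 2Q)].
The two log arguments are computed from integer counts so exact saturation
(1 − 2P − Q = 0) is detected without rounding artefacts; saturated or empty
pairs are *undefined* — flagged in a boolean mask, excluded from summaries,
treated as "not nearest" in identification, and counted in output (never
silently zero or infinite). Distance matrices default to complete-deletion
masking for consistency with the diversity scan.

The barcoding gap is summarised by `gap_margin = inter_min − intra_max`;
a negative margin means at least one heterospecific pair is closer than the
most divergent conspecific pair.

The identification success rate is per-individual. Two criteria are
implemented because the quantity's operational definition varies across the
literature:

* **nearest neighbour (default)** — a sample is identified iff *every*
  sample attaining its minimum defined distance is conspecific (strict tie
  rule: a tie with a heterospecific fails);
* **tree monophyly** — all individuals of a species count as identified iff
  the species' full leaf set is an exclusive clade on the BIONJ tree.

Individuals of singleton species cannot self-match; by default they are
excluded from the denominator (`count_fail` counts them as failures).
`evaluate_combinations` concatenates every non-empty subset of the supplied
loci (2^k − 1 rows, ordered by subset size then input position) and reports
both ISRs plus the distance summaries, Table-style. ISR is invariant under
uniform scaling of distances, and single-locus rows are bit-identical to
standalone single-locus analyses because they share one code path.

## NJ and BIONJ

Both builders agglomerate by the Saitou–Nei Q criterion,
Q(i,j) = (r−2)d(i,j) − R_i − R_j, taking the first minimum in row-major
order so ties break deterministically on the lowest index pair. Branch
lengths use the standard rate-corrected formulas; a negative estimate is
clamped to zero with the deficit moved to the sister edge, preserving the
cherry's total. BIONJ differs only in the reduction step: the new distances
are d(u,k) = λ(d(i,k) − b_i) + (1−λ)(d(j,k) − b_j) with λ chosen to minimise
the variance of the reduced matrix (variances tracked alongside distances and
initialised to the distances, the first-order Poisson model; λ is clamped to
[0,1] and falls back to ½ when v(i,j) = 0). On additive inputs any λ yields
identical reductions, so NJ and BIONJ provably agree there — the suite
exploits this, and checks that both builders exactly invert path-length
matrices of random trees (4–12 taxa, 50 replicates, 1e-9 tolerance), with
scikit-bio's NJ as an independent topology oracle. Undefined distance entries
are a hard error with advice to impute or drop samples.

Monophyly of a leaf set holds iff some edge bipartition equals it or its
complement; singletons and the full set are trivially monophyletic and
singletons are flagged so discrimination counts can be read with or without
them. Outgroup rooting splits the outgroup's pendant edge at its midpoint.
Two-leaf trees are written with the single edge split at its midpoint.

## Quadripartite structure

The inverted repeats are defined as the longest pair of disjoint intervals
that are exact reverse complements (mismatch-free; near-identical IRs with
SNPs are an acknowledged limitation). Detection binary-searches the repeat
length with a rolling hash, verifies candidates by direct comparison, and
breaks ties leftmost-longest; it is validated against an O(n²) full
match-matrix oracle on small genomes. Search operates on the linear sequence:
public plastome records are conventionally rotated so both IRs are internal,
and a single-copy region wrapping the origin raises an explicit "rotate
genome first" error. Between the IRs the longer gap is LSC, the shorter SSC
(an exact tie assigns LSC to the gap containing position 0, with a warning);
the earlier repeat is IRb, matching the canonical LSC–IRb–SSC–IRa layout.
Junction distances are signed: positive from the nearest feature edge to the
junction, zero at coincidence, negative (overlap depth) when a feature spans
the junction; the IRa/LSC junction of an LSC-first genome is circularly
adjacent and is evaluated at both coordinate images, keeping the smaller
magnitude. GC content excludes ambiguity codes and gaps from numerator and
denominator alike. The default minimum IR length is 1000 bp (real plastome
IRs are ~25 kb); tests parameterise it down to tens of bp.

## In-silico PCR

Pure string matching on linear templates — no melting-temperature or
thermodynamic modelling, and no primer design (primers are inputs). A primer
anneals where it has at most `max_mismatch` mismatches (default 2) and zero
mismatches in its 3'-terminal `three_prime_exact` bases (default 3), since
polymerase extension is 3'-critical; on the minus strand the reverse
complement is matched, flipping the exact window to the left end. A primer
base matches a template IUPAC code iff it belongs to the code's set (so N
matches anything; gaps match nothing). Products pair a plus-strand forward
site with a downstream minus-strand reverse site, non-overlapping footprints,
length ≤ `max_product` (default 5000 bp). Amplification rate is the fraction
of templates with ≥ 1 product, reported with numerator and denominator; the
published rates it parallels were wet-lab measurements, so the in-silico rate
is an analogue, not a reproduction.

## Synthetic panel generator

The generator's defaults define the study conditions: 20 species, 55
individuals (2–6 per species), four loci P/F/R/Y of 6000/6000/5000/7000
columns, each carrying one window-sized (800-column, step-aligned) hotspot
with rate multiplier 10, kappa = 2, no missing data.

* **Species tree.** Forward pure-birth (Yule) simulation at unit rate per
  lineage, with a final Exp(n·rate) wait so the youngest split is not at the
  present; the ultrametric tree is rescaled to the requested root-to-tip
  depth. Tree-shape statistics are cross-checked against dendropy's
  pure-birth simulator.
* **Diagnosable species.** In the full panel each species pendant edge gets
  a floor of `min_species_pendant` (default 0.5) × tree height before
  rescaling. This encodes the working assumption that recognised species
  carry private divergence — the situation a barcode screen presupposes —
  and prevents the pure Yule tail from producing sister species arbitrarily
  younger than the intraspecific variation.
* **Inter/intra semantics.** `interspecific_depth` is the expected per-site
  divergence between individuals of different species, `intraspecific_depth`
  between conspecifics. The species tree is rescaled so the mean
  between-species path equals their difference, and individuals attach as
  star subtrees with pendants of half the intraspecific depth. Consequently,
  as intraspecific depth approaches interspecific depth the species signal
  shrinks to exactly zero and all individuals become exchangeable — the
  correct null for permutation tests of identification.
* **Calibration.** The assembled genealogy is rescaled once so the realised
  mean pairwise path equals `background_pi` (default 0.0007), the background
  per-site divergence. Whole-panel mean Pi then lands near
  background_pi × (weighted hotspot multiplier) ≈ 0.0015 — between the
  whole-genome average (~0.001) and the hotspot grade (>0.005) of the panels
  this emulates — and hotspot windows sit near 0.007, comfortably above the
  0.005 calling threshold. With background at the genome-wide 0.001 the same
  hotspot share would push windowed and whole-panel Pi outside both stated
  targets simultaneously; 0.0007 is the value satisfying both, chosen as a
  design constant.
* **Evolution.** Sites evolve under K80 via the exact per-branch transition
  matrix (expected substitutions = branch length × site multiplier), so
  multiple hits occur and distance correction is genuinely exercised;
  simulation and estimation are deliberately model-matched. The root sequence
  is uniform over {A,C,G,T}.
* **Missing data.** `inject_missing` replaces independent random cells by
  `N` (~90% of the budget) and short runs of 3 by `-` (~10%), logging every
  cell, so masking policies can be tested against ground truth.
* **Determinism.** One root seed drives named substreams (tree, counts,
  per-locus evolution, missing data); identical seeds give byte-identical
  panels.

What passing tests on these panels show — and what they do not: the panels
have no indels beyond injected gaps, no rate autocorrelation beyond the
planted blocks, no alignment error, star intraspecific genealogies rather
than coalescent ones, and diagnosably separated species. Success here
demonstrates correctness of the machinery and calibration, not that real
congeneric panels will show a barcoding gap — indeed the motivating system
does not (negative gap margins throughout its published table).

## Problem sizes in the shipped checks

The test suite and acceptance script run default 55-sample panels over
5–10 seeds, a 10-level intra/inter sweep on a reduced panel (12 species × 3,
one 3 kb locus, background 0.003) with a 499-permutation null at equality,
structure detection on ≤ 2 kb genomes against the quadratic oracle, and PCR
scans on 5 kb templates — sizes at which the independent oracles remain
exact and the whole suite completes in well under a minute of compute per
component.

## Known limitations

* IR detection is exact-match only; a single SNP inside a real IR truncates
  the detected repeat at that point.
* Circular coordinates are not modelled anywhere; rotate genomes so the
  quadripartite structure is internal, and PCR products cannot span the
  origin.
* BIONJ's variance model assumes distances ≪ 1 (a warning is emitted
  otherwise).
* The ISR's operational definition in the surveyed literature is often
  unstated; both implemented criteria are reasonable readings, and neither is
  claimed to be the one behind any particular published table.
* Mean intra/inter distances are unweighted over pairs, not over species
  pairs; with unbalanced sampling the two conventions differ.
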