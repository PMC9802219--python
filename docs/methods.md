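# Methods

This note documents the models, parameter choices and numerical conventions
behind `omixlink`, and what the simulated benchmarks do and do not show.

## Fingerprint model

Both BGCs and MS/MS spectra are represented as vectors over the dataset's
sample axis. The value of sample column *g* is the *maximum* similarity of
the object to that sample's objects of the same kind: best pairwise BGC
similarity for gene clusters, best modified cosine score for spectra. Using
the per-sample maximum makes the fingerprint a presence profile weighted by
homology: 1.0 marks an (effectively) identical cluster/metabolite in the
sample, values near 0.7 a distant homolog, and 0 absence.

Values below the similarity cutoff (default **0.7**) are zeroed rather than
kept or treated as missing:

* 0.7 is the calibrated family cutoff of the upstream BGC comparison
  (BiG-SCAPE-style 1 − raw distance scores), so sub-cutoff similarity is
  "likely absent" by construction;
* zeros (not NaNs) keep the vectors dense, which the KNN distance requires.

Consequently all nonzero similarity entries lie in [0.7, 1.0] and the
matrices are sparse in content. The same cutoff is applied to the spectral
columns by default (`apply_cutoff_to_spectra`), because the query matrix
must carry the same kind of features as the training matrix; it can be
toggled off, since the original choice is not observable from published
outputs.

### Feature blocks

Optional binary columns extend both fingerprints:

* **Biosynthetic class** — default 12-name vocabulary (PKS, NRPS, terpene,
  siderophore, RiPP, phosphonate, oligosaccharide, phenolic, other, minor,
  unknown, hybrid-other). A hybrid cluster sets the bit of every constituent
  class. The vocabulary is configurable; class names for spectra typically
  come from external class-prediction tools.
* **Substructures** — an opaque user-supplied vocabulary (amino acids,
  acyl units, ...), treated purely as named bits.

## Modified cosine

The spectral similarity is the molecular-networking modified cosine:
intensities are raised to `intensity_power` (default **0.5**; square-root
weighting moderates dominant base peaks), each spectrum's weight vector is
normalised to unit Euclidean norm, and candidate peak pairs are those with
|Δm/z| ≤ `fragment_tolerance` (default **0.1 Da**) either directly or after
subtracting the precursor-mass difference (sign preserved). A one-to-one
matching is chosen greedily by descending weight product, ties broken by
ascending peak indices so identical spectra deterministically match along
the diagonal and score exactly 1. The score is clamped to [0, 1], and zeroed
when fewer than `min_matched_peaks` (default 1) pairs match.

Greedy matching is the de-facto standard in molecular-networking tools; the
test suite keeps an exhaustive branch-and-bound matcher as an oracle and
verifies that greedy never exceeds it and equals it on ≥ 95% of random
small-spectrum pairs (empirically 100% on the acceptance fixtures). No
precursor-m/z window restricts which pairs are scored, because fingerprints
need the maximum over entire metabolomes. Low-intensity noise peaks are not
filtered before scoring (no published basis for a particular filter);
zero-intensity peaks are dropped at read time since they cannot contribute
to a cosine product.

## Family assignment

A gene cluster family is a connected component of the BGC similarity graph
at the cutoff (single linkage). This stands in for the upstream tool's own
family calls, which use the same cutoff; when those calls are available they
can be supplied as a two-column table and override the computed components.
Labels `GCF1, GCF2, ...` are numbered by each component's lexicographically
smallest member, making the assignment invariant to input order. Pairs
absent from the network files are similarity 0 (sparse outputs only list
pairs under the distance cutoff).

## KNN linking and co-occurrence filter

The classifier retrieves the k (default **3**) nearest BGC rows under
Euclidean distance (Manhattan and cosine distance are options; no metric is
canonical for this problem, and Euclidean is the common default in the
field's KNN implementations). Distance ties are broken by ascending
`bgc_id`: training rows are sorted by id at fit time and a stable argsort
preserves that order, so results are reproducible to the byte.

The ordered neighbor label list itself is the prediction — top-n counts the
true family anywhere in the first n labels, repetitions preserved — rather
than a majority vote, which matches how ranked GCF candidates are read in
practice.

The Jaccard co-occurrence index binarizes both fingerprints at the
similarity cutoff and takes intersection over union of the presence bits.
By default it is computed over all feature columns, with a `strains-only`
option restricted to the sample columns. A link is retained when *any* of
the k neighbors reaches the threshold (default **0.7**); filtering on the
best neighbor only would be stricter, but "any neighbor" is the natural
reading when all k candidates are reported. Queries with all-zero
fingerprints are never retained (no co-occurrence evidence exists) and are
flagged with a warning. Filtered links count as *not tested*: they reduce
the annotation rate, not the precision denominator, and they are not false
negatives for recall.

## Evaluation

* precision(n) = correct / tested over retained, truth-covered results;
* annotation rate = tested / |truth|;
* recall = TP / (TP + truth spectra with no result rows);
* randomness baseline = mean top-n precision after permuting the
  result-to-spectrum assignment (permutation without replacement, default
  **100** repetitions, seed mandatory). For uniformly distributed labels the
  expectation is ≈ 1/(number of families), which the tests verify within
  three standard errors.

## Synthetic data

The simulator emulates exactly the structure the linker exploits, at sizes
chosen to be realistic for a culture-collection study while keeping every
benchmark fast on a single CPU:

* **20 genomes, 10 families** by default (40 genomes, 50 families for the
  large recovery benchmark); family prevalence **0.4** (each genome carries
  a given family's BGC with probability 0.4; every family is forced to have
  at least one carrier);
* **expression rate 0.9** — a carried family's metabolite appears in the
  carrier's metabolome with probability 0.9 (at least one expressing
  carrier is forced, so every ground-truth link is recoverable in
  principle); expression dropout is the main realistic failure mode of
  co-occurrence methods;
* **within-family similarity** 1 − |N(0, 0.05)| floored at 0.7; cross-family
  pairs are omitted from the network file (similarity 0), matching sparse
  pairwise-distance outputs; an option draws sub-cutoff values instead;
* **spectra** are synthetic peak lists: 30 peaks, m/z uniform in
  [100, 1500] Da, log-normal intensities; expressed copies and query
  replicates get N(0, 0.005 Da) m/z jitter, 10% peak dropout and mild
  intensity jitter; **5 decoy spectra per sample** and **10 decoy BGCs**
  add unlinked background.

What this does *not* emulate: chemically realistic fragmentation, shared
substructures between related metabolites, retention-time structure,
metagenome assembly fragmentation (only approximated by the dropout knob),
and the extreme sparsity/imbalance of repository-scale collections. Passing
the recovery benchmarks therefore shows the machinery is correct and the
co-occurrence signal is recovered under controlled noise — not that the
same precision will hold on any real dataset.

Two stress modes probe known failure cases: `co-resident-families` forces
two families onto an identical genome presence pattern, making their
fingerprints collide and their queries mutually confusable (top-1 accuracy
on them collapses toward chance — the classic false-positive mode when two
clusters always travel together); `dropout-heavy` lowers expression to 0.2,
which thins co-occurrence evidence and lowers the annotation rate under the
Jaccard threshold.

## Reference worked example

`src/omixlink/data/reference_links.tsv` is a published benchmark table of
14 validated spectrum→GCF links (GNPS accessions) with the three
nearest-neighbor GCF labels a k = 3 classifier returned on a public paired
collection; 13 of 14 carry the true family among the candidates (92.9%
top-3 precision). The table is the set that survived the 0.7 co-occurrence
threshold out of 50 validated spectra, 22 of which received candidates with
the threshold off — yielding the 28% / 44% annotation-rate worked examples.
Only these printed rows and counts are bundled; the ids of the 8
non-retained and 28 result-less spectra are synthesized in the evaluation
harness since only their counts are published.

## Numerical and degenerate-input conventions

* Duplicate m/z within one spectrum keep the higher-intensity peak; peaks
  are stored sorted strictly ascending.
* MGF round-trips preserve ids, precursor masses and peaks to 1e-6;
  charge 0 (unknown) writes no CHARGE line.
* Duplicate spectrum ids across merged files of one sample are suffixed
  with the file index.
* Out-of-range similarities in network files are clipped to [0, 1] with a
  warning; a similarity exactly at a cutoff counts as present/linked.
* Empty metabolomes score 0; empty peak lists are errors for scoring and
  fingerprinting.
* Matrices are written as TSV with 6-decimal values; feature-space layout
  travels in a JSON sidecar so the link step can separate similarity
  columns from binary blocks.

## Known limitations

* Single-linkage components can chain distinct families together at
  repository scale; supplying upstream family calls avoids this.
* The KNN has no distance weighting or probability calibration by design;
  ranked labels plus the Jaccard confidence filter are the interface.
* The modified cosine here is the classic score; embedding-based spectral
  similarities are out of scope.
* Fingerprints require the query's producer (or a close relative) to be in
  the training samples; a query with no similarity to any sample yields an
  all-zero fingerprint and is reported unretained.
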