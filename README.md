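# omixlink

Pattern-based linking of biosynthetic gene clusters (BGCs) to the MS/MS
spectra of the metabolites they encode, across paired genome–metabolome
datasets.

## The problem

Microbial specialized metabolites are made by biosynthetic gene clusters, but
connecting a metabolite observed by untargeted LC-MS/MS to the gene cluster
that produces it remains a major bottleneck in natural-product discovery.
When a collection of samples has *paired* data — a (meta)genome and an
LC-MS/MS metabolome for each sample — the co-occurrence premise of
pattern-based genome mining applies: a metabolite's distribution across the
samples should mirror the distribution of the gene cluster family (GCF) that
makes it. `omixlink` turns that premise into a supervised classifier, for
researchers who have antiSMASH/BiG-SCAPE-style BGC comparisons and GNPS-style
MS/MS data for the same strains and want ranked, confidence-filtered
GCF candidates for each query spectrum.

## The method

Let the dataset have samples $g = 1, \dots, m$. Each side of the paired data
is embedded into the same $m$-dimensional sample space as a **similarity
fingerprint**:

* **BGC fingerprint** — for BGC $b$, column $g$ holds
  $\max_{b' \in g} \mathrm{sim}(b, b')$, the best pairwise BGC similarity
  (1 − BiG-SCAPE raw distance) against the clusters of genome $g$; a self
  hit scores 1.0. Values below the similarity cutoff $c = 0.7$ (the
  calibrated BiG-SCAPE cutoff) are set to 0: the cluster is likely absent
  from that genome.
* **MS/MS fingerprint** — for query spectrum $q$, column $g$ holds
  $\max_{s \in g} \cos_{\mathrm{mod}}(q, s)$, the best modified cosine score
  against the spectra of metabolome $g$ (peaks matched directly within a
  fragment tolerance, or shifted by the precursor-mass difference; greedy
  one-to-one matching on square-root-weighted, unit-normalised intensities).

Optional binary blocks append biosynthetic-class (12-name default
vocabulary) and substructure presence/absence features to both fingerprints.

BGC fingerprints, labelled by their GCF (connected components of the BGC
similarity graph at cutoff 0.7, or externally supplied family calls), form
the training matrix of a **k-nearest-neighbor classifier** (k = 3 by
default, Euclidean distance). The prediction for a query spectrum is the
ordered label sequence of its k nearest BGC rows — repeated labels are kept,
since several neighbors often share a family. A link is **retained** only if
some neighbor's **Jaccard co-occurrence index**
$J = |A \cap B| / |A \cup B|$ — computed on the binarized presence patterns
of the query and neighbor fingerprints — reaches 0.7, i.e. the metabolite is
found in essentially the same samples that contain the candidate BGCs.

Evaluation reports top-n precision (true GCF within the first n labels, over
retained links), annotation rate (retained links over all validated
spectra), recall (result-less spectra are the false negatives), and a
shuffled-assignment randomness baseline.

## Worked example

The bundled simulator generates a complete paired dataset (genome table,
pairwise-similarity network file, per-sample MGF metabolomes, manifest,
query spectra and a ground-truth table) and the pipeline runs end to end on
its files:

```python
import pathlib, tempfile
from omixlink import SimConfig, simulate_paired_dataset
from omixlink.workflow import PipelineConfig, run_pipeline

d = pathlib.Path(tempfile.mkdtemp())
out = simulate_paired_dataset(SimConfig(seed=7), d)   # 20 genomes, 10 families
res = run_pipeline(PipelineConfig(base_dir=d, seed=7))
print(res.report.to_text())
```

prints

```
top-3 evaluation
  tested links     : 10
  correct links    : 10
  precision        : 1.000
  annotation rate  : 1.000
  recall           : 1.000
  randomness       : 0.091
```

All 10 simulated query spectra pass the co-occurrence filter and carry their
true family among the three candidates (precision 1.0); the randomness line
is the precision a shuffled assignment would achieve (≈ 1/10 with ten
families), confirming the signal is real. Individual results expose the
ranked neighbors:

```python
r = res.results[0]
print(r.spectrum_id, "->", r.ranked_gcfs, "retained:", r.retained)
# query_F001 -> ['GCF10', 'GCF10', 'GCF10'] retained: True
```

The same pipeline is available from the shell:

```bash
omixlink simulate --outdir data --seed 7
omixlink fingerprint --dataset-dir data --outdir matrices
omixlink link --matrix-dir matrices --outdir links
omixlink evaluate --results links/results.tsv --truth data/truth.tsv --outdir eval --seed 7
```

For real data, point `fingerprint` at your own manifest, MGF files,
BiG-SCAPE `.network` file(s) and genome table (formats documented in
`docs/methods.md`).

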