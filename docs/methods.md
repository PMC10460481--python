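# Methods

## The estimation problem

Sequencing depth of coverage is the average number of times each
nucleotide of the *source* DNA appears in the read set.  Mapping-based
estimates are biased by contamination (foreign reads mismapping onto the
reference), by individual genome-length variation, and by genomic material
absent from the reference.  `tagdepth` instead counts a pre-filtered set
of marker k-mers directly in the unmapped reads, so the estimate depends
only on the conserved, single-copy part of the target genome and is
insensitive to foreign DNA that shares essentially no k-mers with it.

## Marker k-mer selection

All k-mer identity in the package is **canonical**: a k-mer and its
reverse complement are one object, represented by the lexicographically
smaller word under A<C<G<T in a packed 2-bit encoding (k ≤ 32, one 64-bit
word).  Reads come from both strands, so without canonical matching about
half of all true hits would be lost.

A **tag k-mer** passes three filters, applied in this order:

1. *Uniqueness / universality.*  Count exactly 1 in the primary assembly
   and exactly 1 in every additional assembly supplied.  With one
   assembly, this is plain single-copy filtering.
2. *Hamming isolation.*  No other genomic k-mer of the primary assembly
   lies within Hamming distance 1 (strand-aware).  A single sequencing
   error can therefore never convert one genomic k-mer into a tag k-mer,
   and an error inside a tag window always knocks the k-mer out of the
   list rather than onto another list entry.
3. *Window spacing.*  Each record is partitioned into consecutive 100 bp
   windows; only every third window (indices 0, 3, 6, … restarting per
   record) may contribute, and from each eligible window the
   smallest-position candidate is kept.  Any two tags on a record are
   then ≥ 201 bp apart, so a 100 bp read touches at most one tag — this
   caps the contribution of a single read to the tag-count sum and keeps
   the counts close to independent Poisson draws at low depth.

An **error k-mer** is a random single-substitution variant of a tag k-mer
(position and replacement base uniform over the 3k possibilities, up to 4
distinct variants per tag, drawn without replacement) that is (a) absent
from the genome, (b) not within Hamming distance 1 of any genomic k-mer
other than its parent, and (c) distinct from all tags and all previously
accepted error k-mers.  Error k-mers are unreachable from the genome
except through exactly one substitution of exactly one locus, which makes
their counts a clean probe of the substitution-error capture rate.

### Distance-1 detection

Isolation filtering needs every pair of genomic k-mers at strand-aware
Hamming distance ≤ 1, over tens of millions of k-mers.  This is found
exactly by *position masking*: two words (in some orientation pairing)
are at distance ≤ 1 iff for some position p they agree everywhere outside
p.  For each of the k positions, the distinct genome words and their
reverse complements are masked at p and sorted; duplicated masked values
expose the colliding pairs.  A masked value shared only by the two
orientations of one and the same k-mer — a near-palindrome one
substitution from its own reverse complement — is the same genomic locus,
not a pair, and is ignored.  Cost is k sorts of 2n integers; no all-pairs
comparison and no per-candidate neighbor lookups are ever done on the
genome scale.  (Single-mismatch neighbor enumeration, 3k variants per
query, is still used where the query set is small: error-k-mer
validation and the public `single_mismatch_neighbors` primitive.)

## Counting

Every ACGT-only window of every read is canonicalized and looked up in
the sorted union of tag and error codes.  Windows overlapping any
non-ACGT character are skipped but their bases still count.  The sample
tallies are

* `n_nucl` — all bases in the sample, N included (depth is defined over
  all sequenced source nucleotides);
* `n_kmer` — ACGT-only k-windows (read edges and N bases both shrink this);
* `n_reads`.

Counting is associative: results from file chunks merge by field-wise
addition, checked against a database fingerprint.  Quality strings are
ignored throughout.

## Estimation

With per-k-mer means over the retained lists, `D_tag` and `D_err`,

```
P_e = D_err / (D_err + D_tag / 3)
D   = D_tag * N_nucl / ((1 - P_e)^k * N_kmer)
```

Derivation: a read window covering a tag locus reproduces the tag k-mer
with probability `(1-P_e)^k` and reproduces one *specific* single-mismatch
variant with probability `(P_e/3)(1-P_e)^(k-1)` (the mismatch position
must take that exact wrong base; the other k−1 positions must be right).
Hence `D_err/D_tag = (P_e/3)/(1-P_e)`, which inverts to the `P_e`
formula.  `D_tag/(1-P_e)^k` is then the k-mer-level depth, and the factor
`N_nucl/N_kmer` converts it to nucleotide-level depth, absorbing window
loss at read edges and around N bases.

A subtlety of what `P_e` estimates: with an N rate `p_N` and a
substitution rate `p_sub` per base, the surviving-window algebra gives
`P_e → p_sub/(1-p_N)` — the substitution rate *among non-N bases* — and
the `(1-P_e)^k` and `N_kmer` corrections then cancel so that the depth
estimate stays exactly unbiased.  At the default 1% rates this is a 1%
relative distinction on `P_e`, below the Monte-Carlo resolution of the
precision study.

### Contamination cutoff

A contaminant that happens to share a list k-mer inflates that k-mer's
count far beyond what the sample-wide depth supports.  Such k-mers are
removed from the counts *and* from the list denominators.  The cutoff `c`
is the smallest integer ≥ 1 such that

```
list_size * P(X >= c) < alpha ,   X ~ Poisson(rate)
```

— a union bound on seeing even one such count anywhere in the list;
`alpha` defaults to 0.01.  K-mers with counts strictly above `c` are
dropped; ties at `c` are kept.  The rate is the 1%-trimmed mean of the
counts (top 1% dropped before averaging) so the outliers being targeted
do not inflate the cutoff itself.  The cutoff is computed separately for
the tag and error lists, whose rates differ by a factor of about
`P_e/3`, and in a single pass; an optional second pass
(`CutoffPolicy(refine=True)`) recomputes the rate on the retained counts.

Trimming on *sparse* counts is deliberately conservative: when fewer than
1% of list entries have nonzero counts, the trimmed rate is 0, the cutoff
degenerates to 1, and k-mers counted twice or more are dropped.  Under a
homogeneous null this removes an O(rate²) fraction of the observed
counts — negligible for the conditions studied here — but it is the main
reason the cutoff should not be pushed far below the default alpha on
very shallow samples.

### Undefined estimates

Zero reads, zero valid windows, an empty retained tag list, or no
observed tag *and* no observed error k-mers raise an error instead of
returning a number: there is no usable signal, and `P_e = 1` (only error
k-mers seen) leaves the depth formula singular.

## Read simulation

The simulator reproduces the evaluation protocol end to end on synthetic
data:

* genomes are i.i.d. uniform ACGT (optionally with engineered exact or
  1-mismatch repeats to exercise the filters); reference N bases are
  replaced by random bases before simulation;
* reads are 100 bp, single-end, uniform over `[0, L-100]`, from either
  strand with probability ½; the read count is `round(depth*L/100)`
  (half-to-even);
* per base, mutually exclusive events: N with probability `p_N` (default
  0.01), a uniformly chosen *different* base with probability `p_sub`
  (default 0.01), unchanged otherwise — so the realized substitution rate
  is exactly `p_sub`;
* contamination: total foreign nucleotides `target*(1-f)/f` for human
  fraction `f`, split equally among the contaminant genomes, each
  simulated with the same read/error model, all reads shuffled.

All randomness derives from one seed through `numpy` `SeedSequence`
spawning; identical configurations are byte-identical down to the FASTQ
output.

What the simulator does *not* model — and therefore what passing the
precision study does not show about real data: indels, quality-dependent
or motif-dependent error profiles, GC-biased or otherwise non-uniform
coverage, paired-end fragment geometry, DNA damage patterns, and —
most importantly — contaminants with genuine sequence homology to the
target.  Random synthetic contaminants share essentially no 25-mers with
a random target, so contamination robustness here demonstrates the
accounting (the `N_nucl/N_kmer` scaling and the cutoff), not robustness
to homologous contamination such as another individual of the same
species, which k-mer identity cannot separate.

## The precision study and its problem sizes

The study conditions are: a 20 Mb target genome (66,667 tags, ~266,668
error k-mers at k=25), three synthetic contaminant genomes of 4, 2 and
1 Mb in equal nucleotide shares, depths from 0.001 to 0.333, and human
fractions from 1.0 down to 0.1 (10× contamination).  Estimates at a given
condition are made on k-mer counts *pooled* over independent replicate
simulations; the pooled estimate of the summed depth is compared with the
simulated truth.

Replicate counts per condition are sized from the Poisson error budget:
the relative SE of the pooled depth estimate is approximately

```
sqrt( 1/sum(tag counts)  +  (k*P_e/(1-P_e))^2 / sum(err counts) )
```

and the second term dominates at low depth — the error-k-mer pool needs
roughly ≥ 1,000 counts before the `P_e` noise stops being the limiting
factor (at `k*P_e = 0.25`, an x% error on `P_e` moves the depth by
~0.25·x%).  The shipped settings (320 replicates at depth 0.01 with
contamination; 3,200 at depth 0.001 pure; 320 at depth 0.001 with
contamination; 10 at depth 0.1 with contamination) put the predicted SE
at ~0.75%, ~0.75%, ~2.4% and ~4% respectively, comfortably inside the
2% / 2% / 10% / 15% bands the acceptance checks assert.

## Numerical and design notes

* Base order A<C<G<T; 2-bit packing with the leftmost base most
  significant; positions are 0-based on the forward strand; a k-mer's
  position is its leftmost base.
* Lowercase bases are folded to uppercase (soft-masked FASTA); every
  other character, N and IUPAC codes included, breaks the sliding window.
* Spacing tie-break: the leftmost candidate in an eligible window —
  deterministic and order-independent.
* "Every third window" restarts at window 0 in each record; the ≥ 200 bp
  guarantee holds for any phase.
* Error-k-mer isolation is tested against the primary assembly only, and
  the distance requirement to non-parent genomic k-mers is ≥ 2 (i.e.
  reject if any non-parent genomic k-mer is within distance 1) — the
  minimal requirement for the capture-probability algebra above to hold.
* A tag may yield fewer than 4 error variants if too many candidates
  collide; the deficit is logged and recorded in provenance.  On random
  genomes at k=25 the acceptance rate is ~100%.
* List building, error-variant drawing and simulation are fully
  deterministic given their seeds; rebuilding with identical inputs is
  byte-identical.
* The estimator reports no confidence intervals (raw count sums are
  exposed in the diagnostics so users can form Poisson SEs themselves).
* Per-record / per-1 Mb-window annotations are carried in the database
  but regional depth estimation is out of scope.

## Known limitations

* k is capped at 32 (single 64-bit word).
* Uniqueness across additional assemblies requires an exact single copy
  in *every* assembly; population-frequency ("universal in most
  individuals") filtering is not implemented.
* The cutoff assumes Poisson-distributed null counts; strong real-world
  overdispersion (GC bias, mappability) would make it too aggressive.
* Contamination by the same species cannot be detected or filtered —
  the contaminant shares the tag list itself.
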