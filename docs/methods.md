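# Methods

This note documents the models, parameter choices and numerical
conventions behind `mitoforge`, and what the simulation-based tests do
and do not demonstrate.

## Read recruitment (bait)

The recruitment screen indexes every length-`seed_k` substring of the
reference mitogenome in canonical form (the lexicographic minimum of
the k-mer and its reverse complement). The reference is treated as the
circular molecule it is: seeds spanning the linearization origin are
included. A read "hits" when it contains at least `min_hits` indexed
canonical seeds; a pair is recruited when either mate hits, and both
mates are kept (pair rescue), since the partner of a mitochondrial
read is mitochondrial regardless of its own quality or errors.

* `seed_k = 31` (default): long enough that chance 31-mer sharing
  between a ~16.5 kb mitogenome and unrelated sequence is negligible
  (4³¹ ≈ 4.6 × 10¹⁸ possible words), short enough that one or two
  sequencing errors rarely erase every window of a 90 bp read
  (60 windows; one error kills at most 31). `seed_k` must be odd so no
  seed equals its own reverse complement.
* `min_hits = 1` (default): recruitment is deliberately permissive;
  the downstream consensus vote tolerates impure pools, and the bait
  stage's job is sensitivity, not precision.
* Exact containment rather than alignment: deterministic,
  dependency-free, and adequate when the reference is a congeneric
  mitogenome (a read diverging a few percent from the reference still
  carries many exact 31-mers). Divergence much beyond ~3% uniformly
  distributed would start to cost sensitivity; that regime is outside
  what the screen is designed for.

The reported alignment rate is `100 × hitting_reads / total_reads`,
rounded half-up to two decimals.

## Quality pools

A mate passes threshold `t` when *every* base has Phred ≥ `t`
(minimum base quality ≥ `t`). For each threshold in {20, 25, 30} two
pools are built: PE-only (both mates passed) and PE+SE (the same pairs
plus the surviving mate of each broken pair) — six pools. Coverage is
estimated as `C = (N_pairs·L·2 + N_se·L)/G` with `G = 16,500` bp by
default, reported rounded half-up to the nearest integer (the in-memory
variant sums actual base counts, so variable-length reads are handled).

## Assembly

Each (pool, k) job builds a canonical-k-mer de Bruijn graph and emits
unitigs (maximal non-branching paths). `k` is odd (no self-complementary
k-mers); k-mers containing N are skipped; reads shorter than `k`
contribute nothing at that `k`.

Error cleanup is three iterated rules, all restricted to paths shorter
than `2k` bases — the footprint of a single substitution error is at
most `k` consecutive k-mers, i.e. a path of `2k−1` bases:

1. **coverage floor** — k-mers seen fewer than `min_count = 3` times
   are dropped before graph construction;
2. **tips and isolated fragments** — short paths with at least one
   dead end are removed;
3. **simple bubbles** — when two or more short parallel paths join the
   same pair of junction k-mers, only the highest-coverage branch
   survives (ties broken lexicographically). Bubble popping turned out
   to be necessary, not optional: at ~100× with 1% substitution error,
   the probability that three reads carry the *same* substitution is
   high enough (per position-and-base rate λ ≈ coverage·error/3 ≈ 0.3,
   thousands of opportunities) that error bubbles routinely pass the
   floor and would otherwise split the circular unitig.

A clean circular genome appears in the graph as a single cycle; the
walk emits it as a linear string of `G + k − 1` bases whose last
`k−1` bases repeat the first `k−1` — exactly the overlap the finishing
stage looks for. Traversal starts are processed in lexicographic
canonical-k-mer order and contigs are sorted by canonical sequence, so
output is byte-reproducible.

Paired-end scaffolding and gap filling are deliberately absent: at the
coverages this pipeline targets (hundreds-fold over ~16.5 kb), unitigs
alone recover the molecule, and candidates that fail to do so simply
contribute no vote.

## Finishing and consensus

* **End overlap**: the longest `m ≥ min_overlap` with
  `prefix(m) == suffix(m)`, exact by default. `min_overlap = 20` is
  conservative — the assembler's terminal repeat is `k−1 ≥ 60` under
  the default sweep. A Hamming-mismatch-tolerant mode
  (`max_mismatch_rate`, suggested ≤ 0.02) exists but is off by default.
* **Circularization** trims the overlap once (last `m` bases).
* **Size window** 16,500–16,700 bp, both bounds inclusive.
* **Canonical form**: lexicographic minimum over all rotations of the
  circular sequence and all rotations of its reverse complement,
  computed with Booth's O(n) least-rotation algorithm on both strands.
  FORWARD/REVERSE strand form records which strand the minimum came
  from (ties → FORWARD); it is bookkeeping relative to the canonical
  string, not a claim about the biological heavy strand. The optional
  `--rotate-like-ref` output mode rotates/flips the final sequence to
  start where a user-supplied reference starts.
* **Clustering** is exact string equality of canonical forms —
  "identical sequences", not a similarity threshold. One substitution
  makes a separate cluster.
* **Consensus**: the largest cluster's representative. A tie for
  largest raises an error carrying all tied representatives; an
  arbitrary silent pick would be unreproducible.

## Simulator

The generator emulates the targeted study design: a circular genome
(default 16,563 bp, GC 0.44) sheared into ~500 ± 50 bp fragments read
inward as 2×90 bp pairs (R2 reverse-complemented), fragments wrapping
the circular origin so the junction is covered. Defaults: 37,500 total
pairs of which 20% are decoys — leaving 30,000 genome pairs ≈ 325×
raw coverage — and a 1% substitution error rate. The genome is drawn
i.i.d. with a rejection check that no 100-mer repeats (keeping it
single-unitig-assemblable at every k in the sweep); the decoy
background is an independent 50 kb linear sequence at GC 0.40,
rejection-checked to share no canonical 31-mer with the target.

Qualities follow a tiered profile chosen so the QV 20/25/30 pools
genuinely differ: each read draws a quality floor
(30 / 25 / 20 / 10 with probabilities 0.35 / 0.30 / 0.25 / 0.10) and
correct bases score uniformly between the floor and 40, while
erroneous bases always score Phred 2–19. Consequently a read
containing an error fails every pool — which is precisely the
stratification the quality pools exploit on real data, in idealized
form.

What the simulator does *not* model: indels, platform-specific error
spectra and quality-by-cycle trends, PCR duplicates, NUMT-like decoys
sharing homology with the target, and reference/target divergence
(the pipeline is exercised with the true genome as its own
"reference"). Passing the end-to-end tests therefore shows the method
is correct under its stated assumptions — substitution-dominated
errors, quality-correlated errors, a repeat-free target, a divergent
but k-mer-sharing reference — not that it is robust to every artifact
of real libraries.

## Problem sizes in the tests and acceptance script

The end-to-end acceptance run uses the full study design (37,500
pairs, 90 jobs; ≈45 s). The pipeline unit tests use a reduced sweep
(k 61–65) at 20,000 pairs, the smallest configuration at which the
quality-pool coverages still comfortably clear the k-mer floor;
module-level oracle tests run at 2 kb genome scale. Seed-stability of
the full design was checked across several seeds during development;
every run yielded a single winning cluster of 20–30 identical
candidates and exact recovery.

## Known limitations

* Exact-match baiting requires a reasonably close reference
  (congeneric in practice).
* Exact-identity clustering means a systematic assembler artifact
  reproduced identically across many jobs would out-vote the truth;
  the diverse (pool, k) grid is the defense, not a similarity
  threshold.
* Heteroplasmy is invisible by construction (bubbles are resolved to
  the majority branch).
* The control-region CpG count is linear on the presented strand (no
  origin wrap, no strand union); other conventions exist.
* Phred+64 input must be declared explicitly (`offset=64`); it is not
  auto-detected.
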