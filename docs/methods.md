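# Methods

## The problem

Mutator (Mu) elements are class II DNA transposons of maize defined by a
highly conserved terminal inverted repeat (TIR) of roughly 220 bp, internal
sequences that are unrelated between elements, and a 9-bp duplication of
host sequence (target-site duplication, TSD) created on insertion. New
family members are found by screening genomic sequence for TIR homology and
validating candidates structurally: a conserved TIR on both ends, intact
terminal motifs (`GAGATA` at the 5′ end, its reverse complement `TATCTC` at
the 3′ end), and a perfect TSD, which marks a recent insertion. `mulescan`
implements this screen and its downstream characterization — family
clustering, captured-gene (Pack-MULE) detection, an internal-sequence
phylogeny, and in-silico Southern prediction — as a tested, reusable
package.

## Alignment engine

All sequence comparison uses the package's own Needleman–Wunsch (global)
and Smith–Waterman (local) implementations with linear gap penalties;
no external aligner is called anywhere.

* Default scores: match +1, mismatch −1, gap −2. No published scoring
  scheme underlies the identity figures the screen targets, so a simple
  scheme that a brute-force oracle can verify was fixed and exposed as
  parameters.
* `N` matches nothing, including another `N` (conservative).
* Tie-break on equal dynamic-programming scores: diagonal, then gap in the
  second sequence, then gap in the first — every alignment is
  deterministic.
* Percent identity = matched columns / all columns between the first and
  last column where both rows carry a residue; internal gap columns count
  as mismatches, terminal overhangs are excluded. Published identity
  percentages for TIR comparisons can shift by about ±1 point under other
  conventions; this one is fixed package-wide so tests are exact.
* The matrix fill is vectorized row-wise in numpy; the linear-gap
  left-dependency is resolved with a running-maximum transform, which is
  exact for linear penalties. Traceback walks the stored matrix.

Correctness is anchored by an independent oracle: exhaustive enumeration
of every gapped alignment (no dynamic programming, no shared code), run on
hundreds of random short pairs in the test suite and the acceptance
script.

## The screen

`scan_tirs` seeds candidate regions by exact 12-mer matches between the
consensus (each strand) and the genome, merges seed diagonals into
windows, and aligns the consensus to each window with Smith–Waterman. Two
numerical choices matter:

* **Core trimming.** A window's best local alignment is trimmed to its
  maximal-scoring contiguous run under a harsher re-scoring (match +1,
  mismatch −2, gap −3) before the identity/length filter is applied.
  Rationale: an optimal local alignment extends a perfect match of a
  *truncated* TIR into unrelated flanking sequence whenever the net score
  creeps upward, diluting identity below the 85% criterion; trimming
  strips such overhangs while leaving a uniformly diverged (decayed) TIR
  intact, so decayed copies are still rejected on identity.
* **Thresholds.** Defaults follow the selection criteria of the screen:
  identity ≥ 85% to the consensus over ≥ 180 columns (the E-value cutoff
  of a BLAST-based screen is not portable without BLAST statistics; the
  identity form is the criterion restated directly). For structural-class
  surveys the minimum hit length is lowered (60 bp in the benchmark
  analyses) so the ~90–100 bp short-TIR classes are detectable; the strict
  selection is unaffected because criterion 1 separately requires both
  TIRs ≥ `long_min` (150 bp).

`pair_tirs` forms all forward/reverse hit pairs with spans in
[400, 6000] bp (known elements run 1.4–2.5 kb, the autonomous element
about 4.9 kb; the envelope is generous and configurable). Unpaired hits
become SOLO candidates. `screen_elements` additionally lets every hit
compete as a SOLO candidate, because a genuine SOLO's only pairing options
may be spurious bridges to a neighbouring element; overlap resolution then
decides.

Overlap resolution is deterministic: among candidates sharing a TIR hit,
priority is (TSD present, terminal motifs intact, mean TIR identity,
pair-over-half, shorter span). TSD detection compares the 9 bp on each
side of the element; a flank shorter than 9 bp yields an *indeterminate*
result, never a confident absence. The default tolerance is zero
mismatches ("perfect TSD"); it is configurable for exploratory use.

Structural classes from TIR lengths: full/full (both ≥ 150 bp),
long/short (one ≥ 150 bp, other in [60, 150)), short/short (both in
[60, 150)), SOLO (a single TIR). The 150/60 boundaries are midpoints
between the ~215/~90–100 bp class anchors and are exposed in the config.

## Family analysis

* **Clustering** is greedy incremental: longest-first (ties by id), join
  the first family whose representative matches at ≥ 90% identity over
  ≥ 90% of the shorter sequence by local alignment, else found a new
  family. The pre-sort makes the partition input-order invariant. The
  90/90 defaults operationalize "identical sequences" clustering; both are
  configurable.
* **Capture detection** harvests local alignments of the internal sequence
  against each host gene iteratively (masking each hit with `N` and
  re-aligning, so multiple fragments per gene are found), then selects
  best-score-first subject to non-overlap on the internal sequence.
  Defaults (≥ 80% identity, ≥ 50 bp) bracket reported capture identities
  (89–98%). Boundaries are fuzzy by a few bp where flanking sequence
  happens to extend the alignment.
* **Phylogeny**: pairwise distances d = 1 − identity/100 from global
  alignments; tree by neighbor-joining (scikit-bio's implementation,
  negative branch lengths clamped to zero). NJ was chosen over an
  unspecified guide-tree method because only topological grouping is
  interpretable for unrelated internal sequences; on additive matrices NJ
  reproduces the generating path metric to numerical precision, which the
  tests assert at 1e−9.

## In-silico Southern

Digestion cuts at every exact occurrence of the recognition site
(linear-molecule semantics; fragments provably tile the input). The
built-in table carries the five enzymes used for Mu presence/absence
blots: EcoRI G^AATTC, EcoRV GAT^ATC, HindIII A^AGCTT, KpnI GGTAC^C, SalI
G^TCGAC; cut offsets are the standard positions and are irrelevant to
fragment sizes at gel resolution. Hybridization aligns the probe (both
strands) to each fragment and assigns a tier: **strong** at ≥ 150 matched
columns and ≥ 90% identity, **weak** at ≥ 80 columns and ≥ 85%, else
none. The thresholds are conventions chosen so that the documented
cross-hybridization cases (a 258 bp region at 95% identity, a 126 bp
region at 98%, an 80 bp TIR carried in a probe) fall in the weak tier;
all are parameters. Methylation sensitivity is not modeled — the enzyme
record carries an informational flag only.

## The simulator

`simulate` builds an i.i.d. background genome with configurable GC, then
plants elements by the insertion mechanism itself: at a host position the
9 bp to the right are duplicated and the element is written between the
copies, so TSD detection holds by construction and genome length is
exactly base length + Σ(element length + 9). With `tsd_enabled=False` the
duplication step is skipped — the negative control for the TSD criterion.

Per class, TIRs are the template (a random 220-mer starting `GAGATA`, or
a user-supplied sequence) truncated to 90 bp (long/short right TIR) or
100 bp (short/short), with per-copy substitution-only divergence
(Bernoulli per site) — no indels by default, so planted boundaries stay
exact and recovery is scored to the base pair. Decayed negatives are
template copies mutated at an exact 25% of sites. Internal sequences are
random by default (1000–2100 bp, matching 1.4–2.5 kb elements minus two
TIRs); capture mode copies fragments (150–400 bp at 95% identity by
default) from synthetic host genes into chosen internals and records the
source.

What the simulator does *not* emulate: real repeat landscapes and nested
insertions, indel divergence, methylation, transposition dynamics, and
the biased base composition of a real maize genome. Passing recovery
tests therefore demonstrate correctness of the screen's logic and
coordinate arithmetic under the stated element anatomy, not performance
on real genomic sequence.

`score_recovery` matches predictions to planted elements greedily by
reciprocal overlap ≥ 0.9 (one-to-one), reports precision/recall, mean
boundary error (mean of |Δstart| and |Δend| averaged per element), and a
(true class × predicted class) confusion table.

## Benchmark problem sizes

The analysis drivers and the acceptance script use a 200 kb genome with
10 full/full, 5 long/short, 5 short/short and 5 SOLO elements at zero TIR
divergence plus 5 decayed TIRs; alignment verification uses 400 random
short pairs; digest conservation uses 100 random sequences × 5 enzymes.
These sizes exercise every code path while keeping a full run in seconds
on one CPU.

## Known limitations

* The seeded scan requires at least one exact 12-mer shared with the
  consensus; TIRs diverged far beyond the screen's 85% criterion may seed
  nothing (they would be rejected by the filter anyway).
* `find_captured_fragments` stops harvesting a host once its best
  remaining alignment fails the thresholds; a shorter high-identity
  fragment shadowed by a longer low-identity one could in principle be
  missed.
* Local-alignment intervals (capture boundaries, probe match lengths) can
  over- or under-shoot a planted feature by a few bp when adjacent
  sequence extends the optimal alignment.
* Only substitution divergence is modeled in recovery scoring; with the
  simulator's optional indel-free guarantee removed, boundary-exact
  assertions no longer apply.
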