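# Methods

## The screening design

A BAC library is screened with N short hybridization probes (overgos) by
pooling rather than probing one at a time. The probes are arranged in a
virtual grid of P plates of R rows × C columns (reference layout
6 × 6 × 6 = 216 slots) and pooled along four dimensions:

* **plate pools** — all probes of one plate (P pools of R·C probes),
* **row pools** — all probes sharing a row index across plates,
* **column pools** — likewise for columns,
* **diagonal pools** — all probes whose cell satisfies
  `(row + col) mod n_diag = d`, with `n_diag = max(R, C)`.

Each probe enters exactly one pool per dimension, so the full round is
P + R + C + n_diag hybridizations (24 for the reference layout) instead
of N. A clone carrying a probe's target should light that probe's four
pools; the probe's identity is read off the intersection. The first
three dimensions already identify the slot; the diagonal is redundant
and acts as a parity check — for any valid address,
`diag = (row + col) mod n_diag` holds, so a single miscalled pool is
detectable.

The modular anti-diagonal is our fixed convention. It keeps diagonal
pool sizes equal on square grids and is isolated in `diagonal_index` so
that a different convention (e.g. `(row − col) mod n`) is a one-line
change; the decoder is agnostic to the choice. Probe→slot assignment is
row-major in input order (plate, then row, then column); decoding
correctness does not depend on the arrangement. Partial final plates
are allowed, with unequal pool sizes.

## Decoding rule

A candidate (clone, probe) assignment is scored by **support**: how many
of the probe's four pools are positive for the clone. Candidates with
support ≥ 3 are considered — the rule tolerates exactly one missing pool
call per true assignment; two missing calls always reject. When support
is 3 the unsupported dimension is reported by name.

Acceptance is per clone: the candidates at the clone's maximum support
are its top set. A unique top candidate is accepted outright. Tied top
candidates form an **ambiguity group**, the machine-readable analogue of
the manual review queue that real filter screens require; with
`accept_ambiguous=True` they are also placed in the accepted set,
flagged. Ties are never broken by heuristics — probe id ordering is used
only for deterministic output.

One structural asymmetry is worth knowing. Row, column and diagonal
together determine the cell within a plate, so deleting a ROW, COL or
DIAG call still leaves a unique support-3 candidate. Deleting the PLATE
call leaves one support-3 candidate per plate — an unavoidable P-way
tie. The "a single deleted call never removes a true assignment from the
accepted set" guarantee therefore holds under `accept_ambiguous=True`;
under the strict default the plate-deleted assignment sits in the
ambiguity queue instead. Similarly, with a full grid, a clone whose four
pools are all positive also produces support-3 "phantom" candidates at
the same (row, col) of every other plate; these never displace a
support-4 truth because acceptance compares against the clone's maximum
support.

Missing pool columns in a call matrix are a validation error rather than
implicit negatives: silently treating an absent hybridization as
negative would deflate support and bias rejection.

## Simulator

The generator emulates the statistical structure the image-analysis
step would have produced, end to end:

* **Genome** — linear, 0-based, half-open Kb coordinates; default
  1,339,860 Kb (the 1.37 pg C-value × 978 Mb/pg).
* **Library** — default 196,354 clones; insert lengths truncated-normal
  with mean 144 Kb and sd 30 Kb (only the mean is an external given; the
  sd is a modeling choice of ~20% spread typical of size-selected BAC
  libraries), truncated to [1 Kb, genome]; starts uniform. The screened
  subset is the first `filters_used/n_filters` fraction of clones
  (default 4/11), matching a screen of 4 of 11 filters: full-library
  fold 21.1X, screened fold 7.7X.
* **Probe efficacy** — per-probe Bernoulli by sequence class, defaults
  coding 0.637, UTR 0.162, intron 0.148, other non-coding 0.145,
  exon–intron boundary 0.167. Failure is probe-level, not clone-level:
  screens tally success per probe, and a bad probe yields nothing on any
  filter.
* **Hits** — clone c truly hits probe p iff p drew "effective" and p's
  locus coordinate lies inside c's insert interval.
* **Calls** — the union of a clone's hit probes' pools, then noise:
  each true positive dropped with `pool_fn_rate`, each negative added
  with `pool_fp_rate` (defaults 0; the real per-spot error structure of
  phosphor images is not recoverable, so the knobs exist but stay off).
* Probe placement is `"even"` (deterministic equal spacing, like a
  spacing-optimized panel) by default, `"uniform"` optionally.

Everything is reproducible from one seed; identical config + seed gives
bit-identical outputs.

**Scaled-down configurations.** `SimConfig.desk()` keeps 216 probes but
uses 2,000 clones on a genome shrunk by the same factor (13,648 Kb),
preserving both fold coverages — the right scale for coverage and
calibration questions. For decoder-recovery questions we instead keep
the full-size genome with 2,000 clones: there the probe spacing
(~6.2 Mb) dwarfs the insert length, so clones hit at most one probe,
which is the regime the real screen operates in. On the shrunk genome
the ~63 Kb probe spacing makes multi-probe clones common; decoding then
legitimately produces ambiguity groups and occasional phantom
candidates, which is useful for exercising those paths but is not a
feature of the real screen's geometry.

What passing simulation tests does **not** show about real data:
hybridization thermodynamics, cross-hybridization between paralogous
loci, spot-intensity calling, spatial filter artifacts and chromosome
structure are all outside the model. The simulator validates the
decoding and bookkeeping machinery, not probe chemistry.

## Statistics and rounding

All printed-style numbers go through a single half-up decimal rounding
function operating on the shortest decimal representation (so 20.54/4
behaves as 5.135 → 5.14, not as its binary neighbour). Conventions,
each verified against the published tables cell by cell:

* genome Kb from C-value: pg × 978 × 1000;
* fold coverage: clones × mean insert / genome, subset fold computed
  from the *unrounded* full fold;
* mean probe interval per chromosome: length / (n + 1) — n probes cut a
  chromosome into n + 1 intervals. The alternative length/n is rejected
  by every cell of the published table. One printed cell (GGA13, 4.74)
  is inconsistent with its own length and count columns under any
  rounding (18.91/4 = 4.7275); we compute 4.73.
* global coverage: Σ lengths over included chromosomes, pooled mean
  interval = total / Σ(nᵢ + 1). The pooled denominator reproduces the
  published 4.2 Mb; the mean of per-chromosome intervals (≈4.4) does
  not. The unplaced bin (GGAUn_random) is excluded by default; the
  exclusion set is a parameter.

**The dual-listed probe.** The chromosome table's probe counts sum to
217 for a 216-probe screen, per-chromosome successes to 78 for 77, and
positive BACs to 655 for 640. All three reconcile if one probe is listed
under both GGA16 and the unplaced bin (the rows carrying the otherwise
undefined ``a`` flag): 217−1, 78−1, 655−15. The packaged probe table
encodes this as 216 unique probes, one with a secondary chromosome;
summaries report listed counts per chromosome and unique totals, and the
footnote flags are carried through verbatim.

## Comparative map

Successful probes (≥ 1 decoded clone) become map loci anchored at their
chicken position, carrying their supporting clone ids, with tracks in
chromosome-table order and loci position-sorted and bounds-checked. The
finch annotation joins a plain lookup table: matched loci get
coordinates; loci absent from the lookup are parked on the non-specific
chromosome TGUUn, starred; loci whose finch coordinate derives from a
chicken-sequence alignment rather than a direct match keep coordinates
but are starred (the figure-legend convention). Exports: a lossless
TSV (byte-exact round-trip), a MapChart-style text of
`locus position` blocks per chromosome, and BED point features (Mb ×
10⁶, 0-based half-open, width 1; loci are points, not intervals).

## Synthetic fixtures

The packaged probe table reproduces the real panel's marginals —
per-chromosome counts, class mix 91/37/27/55/6, species mix 194/19/3,
turkey probes on GGA3, the three zebra-finch probes on GGAZ — with
evenly spaced synthetic positions (the real coordinates came from
genome-browser alignments and are inputs, not derivable). The demo
decode report spreads 77 successful loci over 26 chromosomes following
the published per-chromosome pattern (23 on GGA3, 6 on GGA4), trimmed by
one GGAZ locus so the distinct-locus total is exactly 77. Cross-table
details the publication does not pin down (which classes the turkey
probes had, which loci map where beyond the stated counts) are chosen
deterministically and labeled synthetic.

## Problem sizes in the shipped tests

Decoder-recovery properties run 50 zero-noise screens of 2,000 clones;
calibration runs 200 screens at the fold-preserving desk scale and
checks the successful-probe fraction against the published 35.6% within
three binomial standard errors; the brute-force candidate oracle is
compared on 1,000 random call sets. These sizes keep the full suite in
seconds while leaving Monte-Carlo error well below the tested margins.

## Known limitations

* No probabilistic decoding from spot intensities; calls are Boolean.
* No optimal pooling-design search and no >4-dimensional layouts.
* The comparative map is anchor-based; no synteny-block inference.
* The sparrow's own chromosome nomenclature (ZAL2/ZAL2^m and the
  morph-associated rearrangement) carries no published coordinates and
  is outside the model.
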