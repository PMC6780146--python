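# Methods

## The screen

Given a panel *P* of short peptide sequences over the 20 canonical amino
acids and a proteome (an ordered set of protein sequences), the screen
records every exact occurrence of every panel peptide in every protein —
"in-situ mapping". Occurrence semantics are maximal: overlapping
occurrences of one peptide all count ("AAAA" contains "AA" three times),
co-located occurrences of different peptides all count, and each protein is
scanned independently (a peptide never matches across record boundaries).
This follows from treating each localization as an independent record of a
potential hydrolysis product; the distinction between "all occurrences" and
"distinct peptide–protein pairs" is preserved downstream, where both totals
and distinct-peptide counts are reported.

Per species the summary statistics are

- total hits *H* — number of occurrence records;
- mapped proteins *M* — proteins with ≥ 1 occurrence;
- total proteins *T* — all FASTA records (no redundancy collapsing:
  published total-protein counts equal full annotated gene-set sizes);
- mapping rate *M/T* and average hits per mapped protein *H/M*
  (both defined as 0 when the denominator is 0, for totality on degenerate
  inputs);
- the per-peptide hit spectrum, the top-*n* peptides and top-*n* proteins
  by abundance, and the number of mapped proteins whose description
  satisfies the collagen rule.

Ratios are carried at full precision and rounded only at report time, to 4
decimals, half-away-from-zero. This convention exactly reproduces the
published 4-decimal mapping rates and averages of the five-mammal screen
from their integer counts, which the acceptance script re-derives at run
time.

## Matching algorithm

The main path builds an Aho–Corasick automaton over the deduplicated panel:
a trie with BFS-computed failure links and merged output sets, flattened
into a dense per-state transition map so that scanning costs one dictionary
lookup per residue with no failure chasing. Characters outside the
canonical alphabet (ambiguity codes B, J, O, U, X, Z, retained from input
proteomes) have no transitions and reset the automaton to the root, so they
break matches rather than acting as wildcards — a panel peptide is a
concrete chemical entity and cannot match an ambiguous residue.

The contract of `map_peptides` is defined operationally as exact
equivalence with `naive_scan`, a per-peptide sliding-window comparison with
no indexing structure. The suite verifies this equivalence on 500+
randomized instances (protein lengths 0–1000 over alphabets from 2-letter
low-complexity to the full canonical set plus ambiguity codes; panels of
1–50 peptides of length 2–11) and via a derandomized property test. Hit
ordering is deterministic: protein input order, then start position, then
peptide sequence.

Coordinates are 0-based half-open internally; exported tables are 1-based
inclusive (with the convention stated in a leading comment line), and a
BED-like 0-based export is available behind a flag.

## Panel conventions

Activities are IC50-style concentrations in micromolar: lower = more
active, the standard convention for ACE-inhibitory peptides. Top-*n*
selection ranks by ascending activity, excludes entries without an activity
value, and breaks ties by sequence lexicographic order for determinism.
Duplicate sequences across database entries are kept as entries but
collapsed to a single search pattern; hits are attributed to the sequence.
The packaged database (`data/ahtp_reference_synthetic.tsv`) is a synthetic
literature-style fixture of 58 entries — real, widely reported
ACE-inhibitory sequences with plausible activity magnitudes — not a
curated resource; screens of real data should supply their own library.

The collagen rule is a case-insensitive substring search for the token
"collagen" in the protein description (configurable). RefSeq/Ensembl-style
descriptions carry the word for collagen chains; the rule is transparent
and reproducible, at the cost of depending on description quality.

## Synthetic proteomes and ground truth

The generator emulates the shape of a downloaded mammalian protein set:

- protein count of order 10³–10⁴ (caller-chosen);
- lengths i.i.d. log-normal (default location 5.8, scale 0.7 on the log
  scale: median ≈ 330 residues, mean ≈ 420, heavy right tail), truncated by
  rejection to [20, 50 000];
- residues i.i.d. from configurable background frequencies — uniform by
  default (analytically tractable: a length-*k* peptide is expected
  (L−k+1)·20⁻ᵏ times in a length-*L* protein), with a vertebrate-like
  SwissProt-style preset available;
- a caller-chosen fraction of records (floor rule) described as
  "collagen type IV alpha 5", the collagen subunit most prominent in
  comparative screens;
- planted peptide copies written over non-overlapping windows at uniform
  random offsets, optionally restricted to a random fraction of proteins.

Planting can create incidental new occurrences at window boundaries, so
ground truth is never taken from the plant plan: after generation the naive
oracle re-scans the final sequences, planted coordinates are subtracted to
give background hits, and `per_peptide_totals` (planted + background) is by
construction exactly what the mapper must report. Generation is fully
deterministic given the seed.

What passing the synthetic tests shows: the mapper finds exactly the set of
true occurrences on realistic sequence volumes (millions of residues) and
the statistics aggregate them correctly. What it does not show: real
proteomes are not i.i.d. sequences — they contain repeats, low-complexity
regions and homologous families, so absolute hit rates in real screens
(typical mapping rates 0.6–0.7) differ sharply from the uniform-background
model (rate ≈ 1 for tripeptide panels). The generator validates machinery,
not biology.

## Numerical and degenerate-input choices

- Rounding: half-away-from-zero via decimal arithmetic, applied only in
  reports (default 4 decimals).
- Empty proteome → empty hit table; empty hit table → all-zero summary
  with rate = average = 0; pattern longer than its protein → no hit;
  ambiguity characters interrupt matches. All verified without error.
- '*' (stop) characters are stripped from input proteins before mapping,
  with a logged count; sequences empty after sanitation are dropped.
- Chi-square goodness of fit of generated residue composition against the
  background model is not rejected at α = 0.001 on ≥ 10⁶ residues.
- The occurrence-rate sanity check uses a non-self-overlapping tripeptide
  so position indicators are effectively independent, giving the binomial
  variance for the 4-standard-deviation band.

## Problem sizes in the shipped checks

The test suite and acceptance script use a 5,000-protein planted proteome
(~2 × 10⁶ residues, 50-peptide panel) for exact-recovery verification and a
24,000-protein proteome (~10⁷ residues) for the analytic occurrence-rate
check; both complete in well under a minute on one CPU. Larger runs scale
linearly in total residue count.

## Known limitations

- Exact matching only: no substitution tolerance, no mass-based
  identification, no activity prediction.
- The collagen count depends on description strings, not sequence
  homology.
- Functional-category tallies consume a user-supplied annotation table;
  the package does not generate GO/KEGG annotations.
- Raw hit counts of published screens depend on the exact panel membership
  and proteome releases used there; with a different panel or dataset
  version the integer counts will differ even though the ratio logic and
  machinery reproduce exactly.
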