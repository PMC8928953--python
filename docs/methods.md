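# Methods

## The screening model

The screen treats DPP-IV inhibitory potential as a motif-density problem.
A reference library holds short amino-acid motifs (length ≥ 2) with
documented DPP-IV inhibitory activity; a candidate peptide of length *N* is
scored by the occurrence frequency

    A = a / N,

where *a* is the number of occurrences of library motifs in the peptide as
substrings. Three counting conventions are load-bearing and fixed:

- **Multiplicity.** *a* counts occurrences, not distinct motifs: AG matching
  at positions 1–2 and 4–5 contributes 2.
- **Overlap.** Overlapping matches each count: AAAA against {AA} scores
  3/4.
- **Nesting.** A motif inside a longer motif counts independently: in
  SFDIPPPPMD the tetrapeptide PPPP contributes 1 and the three nested PP
  matches another 3.

These conventions are the only ones consistent with the packaged survey's
annotated profiles, all 48 of which the scanner reproduces position for
position. Positions are 1-based inclusive (`GP [7–8]`). A is held as an
exact `Fraction` internally; display rounds half-up to 4 decimals (5/6 →
0.8333, 10/11 → 0.9091).

The scanner groups library motifs by length and hashes windows of each
length at every start position — O(N · L) window lookups per peptide, ample
for peptidomic sequences (≤ ~20 residues). A deliberately naive
per-fragment sliding-window oracle lives in `synthetic_data` and the test
suite holds the two equivalent on large random batches, so the production
path is never its own referee.

## Stability filter

Detection tables carry one boolean per (trial, period). The filter is
consensus-then-count: a peptide is *present in a period* when detected
there in ≥ `min_trials` trials, and retained when present in ≥
`min_periods` periods. Published summary tables print only the
period-level consensus, so they load as a single trial and the filter
reduces to the period count; the trial dimension is exercised on synthetic
matrices. The filter is idempotent and monotone (raising either threshold
never adds survivors), and both properties are tested.

Defaults: `min_trials = 1` (consensus input), `min_periods = 3` of the five
aging periods (days 28, 90, 180, 270, 360 — labels are data, not code).

## The packaged DPP-IV library

The shipped `dppiv_survey` library is the union of every motif annotated
in the packaged WSF/SSF survey tables: 105 motifs — 100 dipeptides plus
PPL, IPI, IPM, IIAP, and PPPP. Two transcription slips in the source
annotations are corrected, because each admits exactly one reading
consistent with the annotated positions and occurrence counts: PRL at
positions 4–6 of FKRPPL is stored as PPL, and PI at positions 8–9 of
LFDKPVSPL is read as PL. One survey row (SAPILNIPIV) prints A = 0.7778
where its own annotated occurrence list gives 7/10 = 0.7000 — an apparent
carry-over from the preceding row (SAPILNIPI, 7/9 = 0.7778); the scanner
reports 0.7000 and the tests document the exemption.

The tripeptide RPL, analyzed downstream as a ligand, is deliberately *not*
a library motif: adding it would change FKRPLP's occurrence count from the
annotated 4 to 5. Ligand tables downstream may therefore contain sequences
outside the scanning library.

## Ligand enumeration and SMILES construction

Candidates are decomposed into the distinct library motifs of length ≤ 3
they contain (dipeptides dominate oral bioavailability; C-terminal-proline
dipeptides resist gut proteolysis). Each ligand is rendered as SMILES by
concatenating per-residue template blocks N→C:

- standard residue: `N[C@@H](<side chain>)C(=O)`,
- glycine: `NCC(=O)` (no stereocentre),
- proline: `N1[C@@H](CCC1)C(=O)` — the backbone nitrogen opens the
  pyrrolidine ring, valid at the N-terminus and internally,
- the final block gains the C-terminal `O` (carboxylic acid).

Ring-bond numbers close within each block, so concatenation is always a
valid molecular graph. Output is neutral (non-zwitterionic) with one
consistent L-configuration tag on every chiral α-carbon; reference SMILES
in the wild mix `[C@]`/`[C@@]` conventions, so equivalence is asserted on
constitution (canonical graph, stereo stripped), with RDKit as the test
oracle only. Two conservation laws pin the assembly arithmetic: heavy
atoms = Σ residue heavy atoms − (k−1) oxygens, and backbone amide count =
k−1 (plus side-chain amides of Asn/Gln).

## ADMET rules and probability ranking

External predictors' outputs are ingested as data; the package applies the
decision thresholds, which ship as a flat JSON config:

| parameter | rule | default |
|---|---|---|
| Caco-2 permeability | optimal | > −5.15 log cm/s |
| HIA | class | flag 1 → HIA+ (probability attached) |
| PPB | acceptable | < 90 % |
| BBB score | BBB+ | ≥ 0.1 |
| VD | optimal | 0.04–20 L/kg |
| T1/2 | low / moderate / high | < 3 h / [3, 8] h / > 8 h |
| CYP2D6 | pass-through | non-interactor / inhibitor / substrate |

The half-life band edges are closed on the moderate side (3.0 h and 8.0 h
are both "moderate") — the band definition leaves the endpoints open and a
convention had to be fixed; it is configurable. The VD rule is applied
literally to the ingested column even where the source values appear to be
on a log scale (all negative); no packaged summary value depends on it.
Summaries report exact min/max and 3-decimal arithmetic means per column,
HIA-positive and CYP-substrate tallies, with optional exclusion of named
fragments (used for a toxicity mean without the most toxic ligand, GP).
The packaged profile's true PPB extremes are 13.60–53.96 % (the WT ligand
tops the column); narrative summaries elsewhere quote 45.60 % as the
maximum, which is the second-largest value, and this package reports the
computed extremes.

Ligand–target probabilities are ranked descending; a fragment shared by two
parent peptides collapses to one row (identical probabilities required),
ties break alphabetically, so zero-probability ligands sort last
deterministically.

## Synthetic data

Three generators produce inputs with ground truth, each drawing from a
single `numpy` Generator seeded per call (same seed → byte-identical
output):

- **Detection matrices** — i.i.d. Bernoulli(p) flags per
  (peptide, trial, period). The ledger recounts survivors for any
  (min_trials, min_periods) directly from the raw flags. With one trial,
  five periods and p = 0.5, survival at min_periods = 3 is the
  Binomial(5, 0.5) tail = 0.5 exactly, which anchors a distributional test
  at n = 2000 within 3 standard errors.
- **Planted-motif peptides** — background residues are drawn from letters
  appearing in no library motif when such letters exist (with the full
  packaged library only cysteine qualifies; small test libraries have rich
  backgrounds), and motifs are planted at recorded positions. Planting can
  create accidental overlaps, so expected counts are *always* recomputed by
  the naive oracle on the final sequence, never read off the planting plan.
- **ADMET-like tables** — uniform draws per column within configurable
  ranges (defaults straddle every threshold), Bernoulli HIA and
  CYP-substrate status; expected class counts come from direct threshold
  recounts.

What the generators do not emulate: mass spectra, identification error,
retention behaviour, realistic cleavage chemistry, or correlated
detection across periods. Passing tests therefore demonstrate the
correctness of the filtering/scanning/classification arithmetic under the
stated data model, not robustness to instrument-level artifacts.

## Problem sizes and numerical choices

The packaged study is small (48 peptides, 105 motifs, 15 ADMET rows), so
all published-value checks are exact and instantaneous. Property tests use
1000 random scanner cases, 500 random SMILES, detection matrices of
200–2000 peptides — sizes at which every distributional bound above is
comfortably resolved while the whole suite runs in seconds. Report
rendering is deterministic byte-for-byte: stable sort keys, fixed float
formats, sorted JSON keys, no timestamps.

## Known limitations

- The packaged library is the reconstruction from the survey annotations;
  the full curated DPP-IV motif collections used interactively online are
  larger, so absolute A values from this library are comparable only
  within runs using the same library (the ranking logic is
  library-agnostic).
- A is a density prior, not a binding model: no significance, no
  positional weighting, no C-terminal-proline bonus beyond what the motif
  set encodes.
- SMILES cover the 20 standard L-amino acids, neutral forms, no
  post-translational modifications, no D-residues, no 3-D structure.
- ADMET classification is only as good as the ingested predictions; the
  package never recomputes them.
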