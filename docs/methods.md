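# Methods

## Scope and data model

The package analyses a protein complex given one orthologous MSA per
subunit, each with exactly one row per species and a species tag parseable
from the FASTA/Stockholm header (default pattern: trailing `_SPECIES`
mnemonic; duplicate species keep the first row and log a warning; letters
outside the 20 amino acids map to `X`). Two proteins become comparable by
restricting both MSAs to shared species, sorted lexicographically so the
row order is reproducible. Columns whose gap fraction over the shared rows
exceeds `max_gap_frac` (default 0.5, the conventional MSA occupancy cutoff)
are dropped per protein; retained columns keep their 1-based alignment
indices, and labels in a named reference species' residue numbering are
obtained by skipping that row's gaps.

## Mutual information

MI is the plug-in (maximum-likelihood) estimator
`H(a) + H(b) − H(a,b)` in bits, computed on the species rows where both
columns carry a residue (pairwise-complete policy). `-` and `X` are treated
as missing data rather than as informative states: counting gaps as a 21st
symbol manufactures apparent covariation from alignment-length variation.
No average-product or bias correction is applied by default, so the
reported score is plain mutual information; an APC option
(`mi − row_mean·col_mean/grand_mean`) exists behind a flag. The estimator
is biased upward on finite panels (order (k_a−1)(k_b−1)/(2N ln 2) bits for
support sizes k), which is why raw MI is summarised only via the
"nonzero-MI" fraction and all significance statements go through the
permutation null, whose replicates share the same bias. A pair with fewer
than two jointly observed rows is flagged missing, kept in the
tested-pair denominator, and never counted significant; a constant column
gives MI exactly 0 and permutation p exactly 1.

"Nonzero MI" means strictly greater than zero after clamping tiny negative
floating-point results to zero. Invariant columns give exactly 0; variable
independent columns generically give a small positive value under the
plug-in estimator, so the nonzero-MI fraction of a real protein pair is
typically close to 1 and the discriminating metric is the significant
fraction.

All-vs-all grids are computed by one one-hot matrix product per replicate
(all joint contingency tables at once) followed by an integer `c·log2 c`
table lookup; `mutual_information` is an independent straight per-pair
implementation, and the two routes are required to agree to 1e-9 in the
test suite.

## Permutation null and multiple testing

The null hypothesis is "no interprotein covariation". Protein B's species
rows are permuted as a block — one shared permutation per replicate across
all of B's columns — preserving B's intraprotein column dependence while
making the A–B pairing random. Under the simulator's star phylogeny the
rows are exchangeable, so the test is exact. The p-value uses the add-one
formula `p = (1 + #{MI_perm ≥ MI_obs})/(1 + n_perm)`, bounded below by
`1/(n_perm+1)`; ties (`MI_perm = MI_obs` within 1e-12) count toward the
numerator, which makes the test slightly conservative on small discrete
panels (measured null rejection at α = 0.05 is typically 0.03–0.05). For
panels of ≤ 8 species an exhaustive mode enumerates all n! permutations
and returns the exact proportion. Default `n_perm = 999`, always seeded;
per-protein-pair seeds are derived from the sorted pair names so results
are independent of iteration order and symmetric under A/B swap.

Benjamini–Hochberg q-values (statsmodels step-up, monotone, capped at 1)
are computed within each protein pair by default, matching per-pair summary
metrics; `--global-fdr` pools all protein pairs instead. Because BH
multiplies the smallest p by (pairs tested)/(rank), the attainable q floor
is `m/(k·(n_perm+1))` for k true signals among m tested pairs — n_perm must
be chosen with the grid size in mind, which is why the package default is
999 rather than a smaller value.

## Synthetic-data generator

The simulator emulates the statistical structure the scan assumes, not
realistic molecular evolution. Star phylogeny: every species descends
independently from one ancestral sequence, so rows are exchangeable under
the null and permutation calibration can be verified exactly. Per column:
ancestral residue uniform on 20 amino acids; each species substitutes with
probability `m` (default 0.3, giving roughly the residue diversity of a
deep mammal panel at a moderately conserved site) to a uniform choice among
the other 19. A planted pair (i, j, ρ) couples j to i: whenever i
substitutes in a species, with probability ρ column j substitutes in that
species to a deterministic bijective image of i's residue (the bijection
fixes ancestral→ancestral, so a coupled substitution always changes j);
with probability 1−ρ, and whenever i is ancestral, j evolves independently.
ρ = 0 is full independence; at ρ = 1 the planted MI approaches the source
column's entropy (≈ 2.1 bits at m = 0.3) and admits closed-form checks.
Gaps are injected i.i.d. with probability `g` after substitution (default 0;
the validation studies use 0.02 to exercise the missing-data path).
Randomness is expanded from the single seed through per-column
`SeedSequence` keys, so output is byte-identical regardless of iteration
order. Deliberately not modelled: shared tree structure (and hence
phylogenetic autocorrelation), realistic substitution matrices, indel
evolution, site-rate heterogeneity. Passing tests therefore demonstrate
correctness and calibration of the statistics under exchangeability, not
robustness to phylogenetic confounding in real alignments — the classic
caveat for MI-based coevolution scans.

## Validation studies and problem sizes

The studies in `coevmi.validation` choose sizes that keep the full suite
and the reproduction script at a couple of minutes on one CPU while leaving
the conclusions stable across seeds:

* MI identities: 10,000 random column pairs of length 4–15 over 2–5
  letters.
* Exhaustive agreement: 20 random panels of 3–5 species, 1–3 columns per
  protein.
* Type-I calibration: 500 independent single-column null complexes,
  n_species = 100, m = 0.3, n_perm = 199, α = 0.05, compared against the
  central 95% binomial interval.
* Headline pattern: 10 proteins named for the SG–SSPN complex members plus
  the GAPDH and ATP1A1 controls, 20 columns each, n_species = 200, m = 0.3,
  g = 0.02, 12 planted ρ = 1 pairs between the SSPN and SGCG blocks,
  n_perm = 999, q < 0.05. Twelve planted pairs is the smallest number that
  lets a majority of the global top-20 be planted; with 400 tested pairs
  per protein pair the BH floor is then 0.001·400/12 ≈ 0.033 < 0.05, which
  dictates n_perm = 999 (at n_perm = 199 the floor, 0.005·400/12 ≈ 0.17,
  makes significance unattainable for any configuration where the planted
  pairs can dominate the top-20 — the q floor grows as L²/k while the
  majority requirement forces k ≥ 11 ≤ L).
* BH agreement: 1,000 uniform p-vectors of length 1–59 against an
  independently coded step-up.

## Conservation

Pairwise identity/similarity uses Biopython's global Needleman–Wunsch
(BLOSUM62, gap open 10, gap extend 0.5 — common defaults, configurable)
with the full alignment length, gap columns included, as denominator.
Similarity groups are the conventional strong classes {ILMV}, {FWY}, {KRH},
{DE}, {NQ}, {ST}, {AG}, {C}, {P}, overridable. Among co-optimal alignments
the aligner's deterministic first traceback is reported; identity counts
were invariant across co-optimal paths in all tested cases. Per-position
conservation maps reference residue numbers to columns by gap-skipping and
reports identity/similarity fractions over non-gap rows, with the number of
species scored, so results can be reproduced against any mammal panel. The
synthetic paralog study builds a 291-residue ancestor, substitutes exactly
47% of sites and deletes a 5-residue block — sarcoglycan-paralog-like
divergence — and checks the aligner recovers the construction-implied
identity (≈ 52%) within alignment-convention tolerance.

## Structure contacts

Coordinates are parsed with gemmi (PDB and mmCIF); hydrogens and waters are
dropped and alternate locations resolve to the highest-occupancy conformer
(ties prefer 'A'). Salt bridge: side-chain N of Arg (NE/NH1/NH2), Lys (NZ)
or His (ND1/NE2) within 4.0 Å of Asp (OD1/OD2) or Glu (OE1/OE2) carboxylate
oxygens on a different chain; His is accepted as donor (protonation unknown
in predicted models) and flagged. Hydrophobic: side-chain carbons of
A/V/L/I/M/F/W/P plus Tyr's ring carbons within 4.5 Å across chains. Both
cutoffs are standard literature values and configurable. One record per
residue pair with the minimum qualifying atom distance; detection is
restricted to interchain pairs and is invariant under rigid-body motion.
The interface diff compares two models under a declared chain and residue
correspondence: conserved (same residues in contact at corresponding
positions), substituted-partner (position kept, residue identity changed —
e.g. a Phe→Leu swap in a pocket), lost, gained. The canonical/compensatory
test fixture is wholly synthetic constructed geometry emulating the
reported interface chemistry (Arg–Asp bridge at 2.9 Å; a Leu packed
against Phe and Tyr side chains), not coordinates from any predicted or
experimental model.

## Known limitations

* No phylogenetic correction beyond the permutation null: shared ancestry
  in real alignments inflates MI for fast-evolving position pairs, and the
  star-phylogeny simulator cannot detect that failure mode.
* Plug-in MI bias makes "nonzero MI" nearly universal on variable columns;
  the metric is reported because it is the dot-plot colour convention, not
  because it discriminates strongly.
* The BH q floor ties n_perm to the column-grid size (see above); runs on
  long proteins with small n_perm will silently lack power.
* Contact criteria are geometric only — no angular terms for salt bridges,
  no solvent accessibility for hydrophobic packing.
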