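# Methods

## Scope and model

`hcpquant` implements the post-identification stage of host-cell
protein (HCP) analysis for biotherapeutics. Its input is a peptide-run
evidence table as exported by a DIA search engine (one row per stripped
peptide sequence per product × digest × injection, with summed
fragment-ion PSM area and assigned accessions), plus FASTA databases
(host proteome subset, contaminants, product sequences, Hi3 standard),
an annotation map, a risk list, and a study design. Spectral
processing, FDR control and peptide-spectrum matching are upstream of
this package and are taken as given.

## Filter cascade

Peptide evidence passes four filters in a fixed order, each emitting a
reconciling `FilterTrace` (in − removed = out):

1. **Contaminants.** A peptide is removed if any assigned accession is
   in the contaminant database, if any assigned accession's description
   matches a configured keyword (default `keratin`, catching host
   keratins absent from cRAP-style databases), or if its sequence
   occurs verbatim in a contaminant sequence.
2. **Shared peptides.** Peptides with more than one assigned accession
   are removed; survivors are the *unique* peptides. Peptides with an
   empty accession set are removed with a distinct `unmapped` reason —
   they can support no protein.
3. **Replicate consistency.** A peptide (per product) is kept only if
   some digest contains it in *every* injection of that digest; a
   passing peptide is kept in all runs where observed. With one
   injection per digest this degenerates to "seen at least once".
4. **Product similarity.** The degradation screen — an exact-identity
   local match against a product (or optionally contaminant) sequence
   covering more than 80 % of the peptide — is evaluated exactly: with
   no mismatches or gaps permitted, the best local alignment is the
   longest common substring, so a peptide of length L > 5 is removed
   iff LCS(peptide, target)/L > 0.8 (strict). Both the length gate and
   the coverage comparison are strict, making the BLAST-style screen
   deterministic and parameter-free.

The order — uniqueness before replicate consistency — reflects that the
replicate rule is stated for *unique* peptides. Identification then
requires ≥ 2 surviving unique peptides per product × accession,
quantifiability ≥ 3. An optional stricter reading
(`require_same_digest_pair`) additionally demands one digest whose both
injections each contain ≥ 2 of the protein's peptides; it is off by
default, since the peptide-level reading is the weaker and safer
interpretation. A post-identification exclusion step removes proteins
by annotation term (e.g. desmosome/keratinization), by explicit
accession list, or by Ig-like description keyword; the Ig-like
exclusion is list/keyword-driven, never abundance-driven.

## Hi3/Top3 quantitation

For each run, a protein's signal is the summed intensity of its three
most abundant surviving unique peptides (ties broken lexicographically,
so selection is deterministic). Dividing by the Top3 sum of the spiked
Hi3 standard (F fmol on column, unit response assumed) gives molar
amount; molecular weight (average masses, full sequence, signal peptide
not trimmed) and the product mass on column convert to ng HCP / mg
product:

    C = (S_HCP / S_Hi3) · F · M_w · 10⁻⁶ / m

(fmol · Da · 10⁻⁶ = ng). Defaults: F = 50 fmol (500 fmol reconstituted
in 50 µL, 5 µL injected), m = 5 × 10⁻⁴ mg (500 ng loads), three digests
× two injections.

Choices in the replicate structure, both configurable:

- **Per-run Top3** (default): the top-3 set may differ between runs,
  matching "three most abundant" applied to each measurement and
  robust to dropout; a fixed global top-3 set is available
  (`global_top_set`).
- **Digest-first statistics** (default): injections are averaged within
  digest, then mean/SD/CV are computed across digests (n ≤ 3), because
  digestion is the replication unit; pooling all runs (n ≤ 6) is
  available (`replicate_unit="run"`). A protein seen in one digest only
  reports SD = 0 with `n_digests_used = 1`.

Runs where a protein shows fewer than 3 observed peptides contribute no
value. Proteins with exactly two unique peptides are *estimated* from
Top2 sums (still against the Hi3 Top3) and flagged; they are excluded
from threshold fractions and product totals. Concentrations are never
censored; reporting thresholds live in the summary layer.

**Known bias.** Per-run Top3 selects the highest-response peptides, so
under a log-normal response-factor model the estimate is biased upward
(the selected peptides' response factors are upper order statistics).
With σ_rf = 0.5 and ~10–15 detectable peptides per protein this
contributes most of the observed ≈ 0.9 median |log2(est/truth)|; the
Top3-equals-molar-response assumption, not the arithmetic, limits
accuracy. The bias vanishes as σ_rf → 0, which the noiseless tests
exploit.

## Physicochemical descriptors

Implemented locally with shipped, cited constant tables
(`_physchem_tables.py`) so results are exactly reproducible offline:
Kyte–Doolittle GRAVY; Ikai aliphatic index
(X_A + 2.9 X_V + 3.9 (X_I + X_L), mole percent); Guruprasad instability
index ((10/L) Σ DIWV over consecutive dipeptides; *stable* strictly
< 40); average molecular weight (residue masses + one water); and
theoretical pI under the Bjellqvist pKa set used by ExPASy ProtParam,
solved by bisection on [0, 14] — the net charge is strictly decreasing
in pH, and the interval is narrowed to machine precision, leaving
|charge(pI)| far below 10⁻⁴. *Hydrophilic* is GRAVY strictly < 0. No
post-translational modifications are considered. Note that the
Bjellqvist set assigns residue-specific pKa values to the *terminal*
residues, so pI is invariant under permutation of the sequence interior
but not under moving a residue onto a terminus; GRAVY, aliphatic index
and MW are fully composition-determined, while the instability index is
deliberately order-sensitive.

## Risk flagging and enrichment

Statuses in precedence order: `listed_high_risk` (accession on the
curated list) > `functionally_related` (Cohen's kappa between binary
annotation vectors ≥ 0.5 with term overlap ≥ 3 against some list entry;
the best qualifying entry is reported) > `histone_smuggler`
(description/gene matches a configurable histone pattern) > `none`.
The kappa universe defaults to all terms annotated to any background
protein plus the risk-list terms, and is configurable because curated
annotation universes differ between services. Degenerate agreement
(P_e = 1) is defined as κ = 1 for identical vectors, else 0.

Enrichment uses the EASE score: the one-tailed Fisher exact
(hypergeometric upper-tail) probability with one observation removed
from the list-hit cell — P(X ≥ k−1), with k = 0 defined as p = 1 — which
is uniformly conservative relative to the plain Fisher test. P-values
are Benjamini–Hochberg adjusted; a term is significant iff adjusted
p ≤ 0.01 *and* it has ≥ 3 list hits (both configurable; 0.05 is a
common alternative gate).

## Synthetic-data generator

The generator is the test bed and defines the study conditions: a
cohort of products (default 5, classes cycled over Fc-fusion and IgG
subclasses), each analysed as 3 digests × 2 injections; ~20 HCPs per
product (Poisson) drawn from a 100-protein host pool; true
concentrations log-uniform on 0.2–350 ng/mg. Observed intensity is

    I = scale · fmol · RF_peptide · penalty^mc · exp(ε_run)

with RF = exp(σ_rf · Z) fixed per peptide (ionisation response is a
peptide property), ε ~ N(0, σ_inj²) per run, a ×0.1 abundance penalty
per missed cleavage, and detection probability logistic in
log-intensity. Defaults σ_rf = 0.5, σ_inj = 0.2, detector scale 10⁶
counts/fmol and a dropout midpoint of 2 × 10⁴ counts — about one decade
above the weakest peptides, so low-abundance proteins occasionally fall
below three detected peptides and exercise the Top2-estimate path. The
Hi3 standard is emitted as 3 peptides at F fmol with RF = 1 in every
run (a spiked standard is never below detection).

Synthetic proteins are concatenations of unique tryptic "blocks"
(non-K/R stretch closed by K/R, lengths 7–30), so each protein has a
guaranteed count of fully cleaved peptides in the searchable range, and
with all noise off every such peptide's intensity is exactly
scale · fmol. The Top3 sum is then exactly 3 · scale · fmol and the
pipeline returns the planted concentration to machine precision — the
construction is the oracle, no tolerance tuning involved. Planted
artefacts exercise each filter: cRAP-style contaminant peptides and a
host keratin (keyword path), shared peptides carrying two accessions
(never reducing a protein below four unshared peptides, preserving the
noiseless guarantee), and product-degradation peptides that are
verbatim product substrings of length 7–18 attached to dedicated
carrier accessions. All random draws are made for every candidate
observation regardless of σ values (common random numbers), so datasets
at different noise levels but the same seed are coupled, making
error-monotonicity checks sharp.

What the generator does *not* emulate: chromatographic effects,
interference/chimericity, FDR-level errors in accession assignment,
real CHO sequence composition (uniform residue usage instead), or
correlated peptide responses. Passing tests therefore validate the
arithmetic, the contracts and the statistical behaviour of the
pipeline under its stated error model — not search-engine behaviour on
real spectra.

## Numerical conventions and degenerate inputs

Strict inequalities throughout: "below X ng/mg" (<), coverage (> 0.8),
length gate (> 5), stability (< 40), hydrophilicity (< 0). Top-k ties
break lexicographically by sequence. Empty evidence yields empty,
headers-only reports with the manifest still written; a missing Hi3
standard in any run with evidence is a hard error naming the run; a
single-digest protein reports SD = 0 rather than NaN. BH adjustment
rejects p-values outside (0, 1]. Reports are byte-deterministic given
identical inputs and configuration.

## Problem sizes

Default test and acceptance runs use 3–10 products with ~20 HCPs each
(≈ 10⁴ evidence rows per 5-product cohort), 1,000-iteration oracle and
type-I-control loops, and complete in well under a minute apiece; the
sizes are chosen so the full validation cycle stays interactive while
keeping ≥ 100 quantifiable instances for the stochastic recovery
checks.

## Known limitations

- Top3's equal-response assumption produces an upward bias under
  response-factor dispersion (quantified above); reported CVs capture
  replicate scatter, not this bias.
- The BLAST-equivalent degradation filter is exact only for the stated
  thresholds (100 % identity); allowing mismatches would require a real
  local aligner.
- The kappa universe and annotation granularity strongly affect
  functional-relatedness calls; both are explicit configuration here,
  whereas hosted services keep them internal.
- Molecular weights use the full database sequence; signal peptides and
  processing are not modelled.
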