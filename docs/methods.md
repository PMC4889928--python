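# Methods

## The damage-tolerance model

The simulator follows each eligible cytosine on both strands of a
double-stranded reference through one round of replication. Per clone,
each C (top strand) or G (top strand, i.e. a bottom-strand C) is
deaminated independently with probability `deamination_rate × w`, where
`w` is the 3-mer motif weight read on the C-bearing strand (5′N, C, 3′N;
bottom-strand contexts are read on the reverse complement, so a
TpC-preferring deaminase targets top-strand G followed by A). Positions at
the reference edge lack a flank and take the default weight 1.0 rather
than being silently excluded. The product `deamination_rate × w` must not
exceed 1; the simulator raises an error rather than truncating.

Each lesion then takes one branch:

1. **Replicated over** (probability `1 − p_ap`): the polymerase reads the
   uracil as thymine; the lesion strand fixes C>T (reported on the top
   strand as C>T or G>A).
2. **AP-site, reprimed** (probability `p_ap · p_reprime`, only when the
   lesion strand templates leading-strand synthesis): synthesis restarts
   downstream and the gap behind the fork is repaired against the intact
   sister — no mutation. Repriming on the lagging-strand template is fixed
   at 0: discontinuous synthesis restarts at the next Okazaki primer
   anyway, so a dedicated repriming activity has nothing to add there.
   Whether lagging-strand repriming is impossible or merely redundant is
   not distinguishable in this model; the zero is a modelling choice, not
   a mechanistic claim.
3. **AP-site, translesion synthesis** (otherwise): a base is drawn from
   `tls_insertion` and placed opposite the non-instructive site. Inserted
   A fixes C>T, C fixes C>G, T fixes C>A; inserted G restores the original
   base pair and produces no mutation (the model enumerates only the three
   mutagenic outcomes, so G is the error-free insertion by base-pairing
   logic).

One lesion per site per clone; sites are independent Bernoulli draws.
At realistic per-site rates (≤ 0.05) multiple hits per site per round are
negligible, which keeps the closed form exact rather than approximate.

The closed-form expected count per class is the sum over sites of the
branch probabilities, e.g. for a top-strand C of weight `w` with leading
template = top:

    E[C>T] = d·w·[(1 − p_ap) + p_ap·(1 − p_reprime)·π_A]
    E[C>G] = d·w·p_ap·(1 − p_reprime)·π_C
    E[C>A] = d·w·p_ap·(1 − p_reprime)·π_T

and symmetrically (without the repriming factor) for bottom-strand
lesions reported as G>A/G>C/G>T. On a reference whose two strands carry
equal C content in identical contexts, the expected transversion ratio is
`E[G>C]/E[C>G] = 1/(1 − p_reprime)`; the estimator
`p̂ = 1 − M[C>G]/M[G>C]` inverts this and is valid **only** under that
symmetry, a top leading-strand template, and zero lagging repriming. On an
asymmetric reference the estimate is biased by the ratio of strand-wise
eligible-site weights, which is why the tests use the self-reverse-
complementary `(ACGT)ⁿ` repeat.

An optional flat per-A/T-base substitution rate (default 0, uniform over
the three alternatives) stands in for mismatch-repair-driven collateral
mutagenesis around U/G mismatches. No quantitative mechanism is modelled;
the parameter exists so A/T classes are not structurally forced to zero.

**Reproducibility.** A single `numpy` generator seeded from the config is
used in a fixed draw order: the clone × site lesion matrix first, then per
lesion (clone-major, left-to-right) three uniforms — AP-versus-replication,
repriming, TLS base — drawn for every lesion regardless of which branch
consumes them, so the stream never shifts; collateral A/T draws follow.
Identical configs give byte-identical FASTA output.

## The SHM pipeline

Coordinates are 0-based half-open; substitutions are reported on the top
(sense) strand. Calling compares pre-aligned equal-length clones to the
germline within the analysis window: gaps set a clone-level indel flag,
IUPAC ambiguity codes are no-calls (that position also leaves the clone's
denominator contribution — the conservative treatment of Sanger ambiguity).
Exclusions, applied in order and logged per clone: indel-bearing clones
(removed entirely from counts and denominators — the clone-level reading
of "insertions and deletions are excluded", made auditable via the log),
unmutated clones, then clonal deduplication *within a sample* by identical
mutation set plus identical CDR3 (the lexicographically smallest clone id
is kept; exact duplicate sequences fall out of the same rule). Clones from
different animals cannot be clonally related, hence the per-sample scope.

The spectrum corrects for base composition by weighting each class count
by its per-base denominator `N_X × n_sequences` (adjusted for no-call
positions) and renormalising — algebraically identical to forcing each
base to 25% of the composition. Under uniform composition the correction
is the identity. Tandem mutations are adjacent mutated position pairs
(p, p+1) within one clone. Mutation frequency is
`100 × mutations / sequenced bp`, reported to 2 decimals.

Strand-bias testing offers two 1-df Pearson χ² constructions, both without
continuity correction (counts here are large enough that Yates' correction
only biases): `pair_only` tests the two transversion counts against equal
expectation, `(a−b)²/(a+b)`; `vs_sequenced` (the default, matching the
mutations-of-base-x versus sequenced-base-x construction) tests the 2×2
table of mutated versus sequenced G and C bases. The within-genotype bias
test is reported under both labels because the exact table construction
used upstream of this package is ambiguous; on large balanced data the two
agree closely. Cross-cohort class comparisons use the analogous 2×2 of
mutated-versus-sequenced bases per cohort.

## The tumor-cohort analysis

Substitutions are collapsed onto the pyrimidine strand (purine-reference
records are reverse-complemented, flanks swapped and complemented), making
classification strand-involutive by construction. TpC is defined after
collapse: reference C with 5′ flank T. N flanks classify the context as
unknown and drop the record from TpC tallies only. Trinucleotide contexts
are emitted alongside for forward compatibility, though the analysis uses
dinucleotides. Per-tumor loads are raw counts — no per-megabase
normalisation, since covered territory is not part of the input schema —
and duplicate mutation records count with multiplicity (positions are not
in the schema; a duplicate-tumor roster is rejected instead).

Group comparison: Mann-Whitney, two-sided. With both groups ≤ 8 the p is
computed by full enumeration of all `C(n1+n2, n1)` labelings on average
ranks (tie-safe), `p = 2·min(P(U ≤ u), P(U ≥ u))` capped at 1; larger
groups use the tie-corrected normal approximation without continuity
correction (the two agree within 0.02 at n = 8). "Deficient versus all"
includes the deficient subset in the comparison group by default (the
cohort-wide box is the reference in the figures this mirrors); a disjoint
mode is available. Both median and mean fold-changes are reported, since
either could underlie a published fold. Spearman correlations use average
ranks with the t-approximation (n − 2 df); stars mark p < 0.01. No
multiple-testing correction is applied by default, matching per-test
reporting conventions; a Benjamini-Hochberg helper (`adjust_p_bh`) is
available for users who need it downstream — deliberately not wired into
the default outputs.

## The synthetic cohort

Per tumor, expression is log-normal per gene (RSEM-scale defaults);
deficient tumors (Bernoulli with the cohort-scale fraction 14/817) get
PRIMPOL expression 0. Class counts are negative-binomial (dispersion 3;
exome loads spread over orders of magnitude, so Poisson would be wrong by
construction) with mean

    λ0[c] · (1 + α[c]·Ã3B) · (1 − s[c]·g(PRIMPOL)) · m

where `Ã3B` is min-max-scaled **log** expression — on the raw log-normal
scale the minimum-maximum span is owned by a few extreme tumors and the
effect would not be a cohort-wide monotone trend; Spearman is rank-based,
so the monotone rescaling changes only the effect's spread, not its
meaning — `g(x) = x/(x + median)` saturates in [0, 1), and `m` is the
deficient multiplier (default 2.0, the "nearly doubled" contrast,
controllable independently of the continuous correlation). Baseline rates
λ0 total ≈ 29 point mutations per exome; α is concentrated on C classes,
s strongest for C>G/C>A. C-class mutations are TpC with probability 0.54
(the observed TpC majority among C mutations), flanks drawn accordingly,
and each record is emitted on a random strand so the collapse logic is
exercised. The truth record stores all per-tumor means for recovery tests.

The generator targets the qualitative surface only — correlation signs,
an approximately doubled deficient load, a TpC majority near 54% — and
makes no claim of reproducing real-cohort magnitudes, mutation totals, or
inter-gene expression correlation structure (genes are drawn
independently). Passing tests therefore demonstrate that the analysis
recovers planted structure of realistic shape and size, not that it would
reproduce any particular cohort's values.

## Problem sizes and numerical choices

Monte-Carlo/closed-form agreement is tested at 2,000 clones (3 binomial
SE per class); strand-bias convergence and parameter recovery at ≥ 50,000
lesions (±0.05 on p̂); cohort sign-recovery at n = 800 tumors over 20
seeds (≥ 19 must recover all signs at p < 0.01). These sizes put the
statistical properties well inside their tolerance bands while keeping the
full suite under a minute. Percentages are reported to 2 decimals in
tables with full precision retained internally; spectrum invariants hold
to 1e-9, Spearman's closed-form equivalence to 1e-12.

## Known limitations

- One replication round per clone; no clonal genealogy, no selection, and
  no mutation accumulation over germinal-center cycles.
- The Ung2-versus-Msh2 processing split and error-prone U/G mismatch
  repair are not mechanistically modelled (only the flat A/T collateral
  rate).
- Indels are counted, never simulated or classified.
- The repriming estimator is a two-count moment estimator; no likelihood
  or confidence interval is provided.
- Real MAF dialects, copy-number inference and expression normalisation
  are out of scope; deficiency is an input flag.
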