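# Methods

## Transaction model

A cohort is a binary matrix **A** (n subjects × m items); an item is an
attribute=value pair and an itemset J has tidset J↓ = {x : a_xj = 1 ∀j∈J}
and support σ(J) = |J↓| (σ(∅) = n). Attribute names are unique within a
transaction: a subject cannot carry two codes of one attribute, nor both
directions of one probe. Transaction ids are 1-based in all public output.

## Rule metrics

For J ⇒ H over n transactions: conf = σ(J∪H)/σ(J), comp = σ(J∪H)/σ(H),
lift = n·σ(J∪H)/(σ(J)·σ(H)). Lift is deliberately the relative-frequency
form: the raw count ratio σ(J∪H)/(σ(J)·σ(H)) is not scale-free and does not
equal 1 under independence, whereas the normalised form reproduces the
conventional published values (e.g. counts 14/14/74 at n=143 give
143·14/(14·74) = 1.93). Metrics are held as exact integer ratios;
display rounding is half-up to two decimals (22/26 → 84.62%), and
completeness is always printed at that full precision (5/7 → 71.43, never
pre-rounded to integers).

## Closed-itemset mining

Only closed frequent itemsets are enumerated; they determine the support of
every frequent itemset, so rule generation loses nothing while the output
stays parsimonious. The closed family is unique, so correctness is defined
by oracle equivalence, not by any particular algorithm. Two enumerators are
provided and cross-checked against a 2^m brute-force oracle on randomized
databases:

- **lcm** — depth-first prefix-preserving closure extension over integer
  bitmask tidsets; items are ordered lexicographically by (attribute,
  value), which also fixes all tie-breaks. Used for clinical-scale inputs
  (n ≈ 143, m ≈ 60).
- **rowset** — every closed itemset is the item-intersection of the rows of
  its tidset, so for databases of at most 12 transactions all row subsets
  are intersected and deduplicated with vectorised numpy. Its cost does not
  grow with m, which makes it the right tool for the per-group expression
  sub-databases (≤ 7 subjects, thousands of gene items).

The empty itemset is reported iff no item is universal (it is then its own
closure); it never takes part in rule generation. `min_sup` is an absolute
transaction count throughout, never a fraction. `min_conf` is validated
only as positive: values above 1 are a supported way of switching rule
emission off.

## Rule generation and constraints

Rules come from splits of closed sets: each closed C emits J ⇒ H for every
nonempty H ⊆ C satisfying the consequent constraint, J = C \ H nonempty;
σ(J) and σ(H) are recomputed by direct tidset intersection, so metrics are
exact even when a split part is not itself closed. Duplicate (J, H) pairs
across closed sets are emitted once. Output order — confidence desc, rule
support desc, canonical item order — is total, making rule tables
byte-reproducible.

The clinical analysis constrains consequents to periodontal attributes with
at least one active disease item (PPDi6mm=2; GI, BOP, CALi3-4mm, CALi5mm,
SUPP ∈ {2,3}). The cardiovascular analysis further restricts the item
universe to the five risk attributes (BMI, WHR, AC, FPG, N-HDL-C) plus the
periodontal six, and antecedents to the risk attributes alone; consequents
stay periodontal — a consequent drawn from the risk attributes themselves
would make the analysis circular. The diabetic-dyslipidemia subset analysis
relaxes the consequent to any periodontal item at any code (healthy-range
periodontal codes are informative in a ten-subject subset) and computes lift
over the subset size. Because no support threshold is stated for that
subset, the default scales the cohort threshold proportionally
(round(14·n_subset/143), at least 1) at the same 70% confidence; an explicit
`MiningParams` overrides this.

Class association rules J ⇒ c are mined per class: closed sets within the
class's transactions at min_sup give σ(J∪{c}); σ(J) is counted over **all**
transactions, so conf = σ(J∪{c})/σ(J) penalises patterns shared with other
groups; comp divides by the class size, lift uses the full n. A class
smaller than min_sup yields no rules, with a warning.

## The two-phase CF+DEG analysis

Expression preprocessing is order-fixed: (1) range filter — drop probes with
max−min < 0.1 on the raw summarised values (a profile at exactly 0.1
survives); (2) per-probe z-normalisation with the *sample* (n−1) standard
deviation; (3) ternary discretisation with strict thresholds — z > 1.0
gives an over-expressed item, z < −1.0 under-expressed, boundary values give
no item. Phase 1 mines CARs (min_sup 3, min_conf 90%, groups 1–5 as target)
over gene items alone. The probes covered by those rules, minus the
conflicting ones, form the phase-2 gene universe. A probe conflicts when
the same signed item appears both in a control-group (group 5) rule and in
a disease-group rule; matching at the probe level regardless of direction
is available via `conflict_key="gene"`, since the published conflict
counting is ambiguous between the two readings. Conflicting probes are
removed with both directions. Phase 2 joins each subject's surviving gene
items (both directions remain admissible — the direction filter is the
item's own, not inherited from phase-1 rules) with all 29 clinical codes,
and mines CARs with the same parameters; the group label is the only
permitted consequent.

## Clinical discretisation

Cutoffs live in a versioned YAML shipped as package data, not in code. Bins
are half-open [lo, hi) unless printed otherwise; deliberate exceptions are
encoded exactly as published, e.g. the HDL middle band [40, 60] closed on
both ends with >60 strict, the percentage bands [30, 50] closed at both
ends, and the ≤/> two-code attributes (INS, HOMA-IR, TNT, Age). Waist/hip
ratio uses sex- and age-stratified cutoffs with age bands ≤39, (39, 49],
>49 taken from the subject's raw age in years — the binary age code (≤50 vs
>50) cannot express these strata. Abdominal circumference stratifies by sex
(80/88 cm female, 94/102 cm male). Every discretisation is total on the
non-negative half-line (property-tested on grids plus all cutpoints), and
negative measurements are rejected.

Missing values produce no item for that attribute, with a warning — the
subject simply lacks the item. The diabetic-dyslipidemia filter (TG ≥ 204,
HDL < 38, groups 1–2) requires raw lipid values: the TG code-3 bin starts
at 200 mg/dL and cannot resolve 204, so coded-only cohorts must supply an
explicit subject-id list instead.

## Synthetic cohorts: what they emulate, and what not

The generator reproduces the study's shape: five groups of 28/29/29/29/28
subjects, a microarray subset of 5/7/6/6/6, 54 675 probes of which 50 441
are low-variance. Each group carries a planted code pattern reflecting its
clinical definition; a patterned attribute takes its target code with the
adherence probability and otherwise a uniform draw over the *other* codes,
so per-attribute pattern support is exactly binomial in the adherence —
the calibration the recovery tests rely on. Unpatterned attributes are
uniform over their domains. Raw measurements are sampled uniformly inside
the chosen code's bin (clipped to a per-attribute plausible range), so
discretisation round-trips by construction; sex is balanced and age uniform
on the study's 35–60 band, with the Sex/Age codes derived rather than
patterned. Exactly `ddlp_size` subjects in groups 1–2 receive raw lipid
values inside the diabetic-dyslipidemia window, and every other group-1/2
subject is kept out of it.

Expression: background entries are N(0, noise_sd) (default 0.1);
low-variance probes are a per-probe baseline plus 0.01-sd jitter, which the
0.1 range filter removes with certainty at 30 subjects; signature probes
take a *deterministic* offset of `signature_shift_sd × noise_sd` (default
3 noise-sd, mostly over-expressed with one under-expressed probe per group)
in the owning group's subjects. The offset is deterministic rather than
noise-added by design: after per-probe z-normalisation the planted z-score
is bounded by √((n−k)/k) ≈ 1.8–2.2 for group sizes k = 5–7 of n = 30, and
an additive noise draw on planted entries would push ~16% of them below the
+1 cutoff at a 3-sd shift *regardless of the noise scale* (the failure
probability depends only on the shift/noise ratio). With deterministic
offsets, recovery at shifts ≥ 3 noise-sd is exact up to a ≳4-sigma margin,
which is the behaviour the recovery tests certify.

What the generator does **not** emulate: probe-level microarray noise
models, probe–probe correlation, batch effects, realistic marginal code
frequencies (backgrounds are uniform), or group assignment from clinical
criteria (groups are labels, not diagnoses). Passing recovery tests
therefore certify the pipeline's correctness on planted structure, not its
behaviour on real measurement noise.

## Numerical and reproducibility choices

- All supports are exact integer counts; confidences and completenesses are
  `Fraction`s internally; only display rounds (half-up, two decimals).
- No stage outside the generator uses randomness; all sort orders are
  total; repeated runs on identical inputs produce byte-identical tables
  (tested).
- Each generated artefact consumes a single `numpy.random.default_rng(seed)`
  stream; the clinical and expression stages of a combined cohort use seed
  and seed+1 so either can be regenerated alone.
- Degenerate inputs fail loudly with located diagnostics: empty databases,
  duplicate attributes (naming transaction and attribute), codes outside
  their domain (naming subject, attribute, value), non-numeric or missing
  expression cells (naming probe and subject), zero-variance profiles
  (directing to the range filter), empty-tidset closures.

## Problem sizes in the test suite

Unit tests run on toy databases and on a reduced expression matrix (800
probes); the recovery and determinism checks run the full study-sized
generator (143 subjects, 54 675 probes), which completes in about a second
per cohort. Oracle equivalence is checked on 200 randomized databases of up
to 10 transactions × 12 items, the regime where the 2^m brute-force oracle
is exact and fast. The adherence calibration check aggregates one planted
attribute over 200 seeds and compares the total against its 99% binomial
band.

## Known limitations

- The full-data rule counts can only be verified against the original
  subject-level tables, which are not redistributable with the package; the
  corresponding tests fail with a clear diagnostic until those files are
  supplied.
- Conflict counting (`item` vs `gene` key), and with it the phase-2
  universe size, is convention-sensitive; both conventions are implemented.
- Expert rule selection is encoded only as the stated ordered ranking
  criteria (`rank_rules`); the final subjective choice among top-ranked
  rules is out of scope.
- No statistical significance testing of rules is performed.
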