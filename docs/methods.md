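# Methods

This note documents the models implemented in `uidseq`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data can and cannot establish about real cfDNA experiments.

## The generative model (`uidseq.simulate`)

A UID-tagged targeted library is simulated in four stages, all driven by a
single integer seed (independent substreams per stage, so changing
`reads_sequenced` does not perturb fragment sampling).

**Fragmentation.** `n_fragments` molecules receive start positions inside
the enriched panel regions (length-weighted region choice, uniform start)
or, with probability `1 − on_target_prob` (default 0.95 on target),
uniformly in the off-panel remainder of the reference. Lengths are
truncated normal with mean 166 bp and sd 40 bp — the canonical
nucleosome-protected cfDNA fragment size; no published length distribution
exists for any specific assay, so a truncated normal is the simplest
defensible choice. Fragments are clipped at the reference edge and never
shorter than 30 bp.

**UID tagging.** Each fragment draws a UID uniformly from the 4^L
sequences (L = 6 by default, 4096 tags). Tags attach before amplification,
so all PCR copies inherit them. Tumor variants are spiked by giving each
fragment overlapping a site the alternate allele with probability equal to
the spiked allele fraction.

**PCR.** Amplification is a per-cycle Bernoulli branching process
(Galton–Watson): in each cycle a molecule duplicates with probability
`eff_i · max(0, 1 − N/K)`. Two features deserve comment.

* *Fragment-specific efficiency* `eff_i` is drawn once per fragment from a
  Beta distribution with mean `pcr_efficiency` (default 0.55) and sd
  `pcr_efficiency_sd` (default 0.08). This models amplification bias
  (GC/length-dependent polymerase preference). It is not merely cosmetic:
  in a *homogeneous* branching process the coefficient of variation of
  clone sizes saturates after roughly ten cycles, so 19- and 25-cycle
  libraries would be statistically indistinguishable at fixed sequencing
  depth. With fragment-level bias, the spread of log clone proportions
  grows linearly in cycle number, which is what makes mean UID-family size
  and the fraction of reads lost to oversized (>50-read) families increase
  with PCR cycles — the behavior observed in real libraries that this
  package reproduces.
* *Carrying capacity* `K` (default 1.5 M molecules) models reagent
  exhaustion as a logistic efficiency decay. `split_reactions=2` halves
  the input into two independent reactions, each with its own capacity,
  and merges the products — doubling the total molecule yield.

Each duplication introduces independent substitution errors at
`polymerase_error_rate` per base (default 10⁻⁵) over insert and UID;
copies share their parent's byte strings unless mutated. A hard pool cap
(20 M molecules) guards against runaway configurations.

**Sequencing.** `reads_sequenced` molecules are drawn from the pool and
each read receives substitution errors at `seq_error_rate` (default 10⁻³,
typical short-read error) on the insert and `uid_error_rate` (default
10⁻³) on the UID, then is truncated to `read_length` (default 150 nt,
single-end) from its 5′ end. Two sampling modes exist:

* `with_replacement` (default): proportional cluster sampling, the right
  approximation when the amplified pool vastly exceeds the read budget.
* `without_replacement`: each read consumes a distinct physical molecule,
  so useful yield is capped by library complexity (the pool size).

The distinction matters for the split-amplification question. Under
proportional sampling, only clone *proportions* reach the sequencer, and
splitting a reaction leaves the proportion distribution statistically
unchanged (mean reads per fragment is fixed at R/n and clone-size CV is
essentially the same whether growth freezes at K/n or 2K/n) — so split
amplification is provably neutral there. The empirically observed benefit
of splitting appears exactly when sequencing depth is comparable to the
number of distinct library molecules: a single capacity-bound reaction
(≤ K molecules) then cannot fill the read budget with new information,
while two reactions (≤ 2K) can. The split experiments in the test suite
therefore run in `without_replacement` mode; this interpretation —
increased complexity, not changed per-molecule behavior — is stated as
the package's explanation of the effect.

**Truth table.** Every emitted read carries exactly one record: source
fragment, true UID, true 5′ mapping key, strand, tumor flag, and
sequencing-stage substitutions. PCR errors live in the molecule sequences
and surface as differences from the fragment's true sequence.
`truth_recovery` scores the fraction of consensus reads that map
one-to-one onto original fragments.

## Consensus calling (`uidseq.consensus`)

Reads group by (chromosome, 5′ mapping coordinate, strand). Strand is
included in the key to avoid collapsing opposite-strand fragments that
share a coordinate. Within a group, UIDs cluster by the directional rule:
a directed edge a→b exists iff Hamming(a,b) = 1 and
count(a) ≥ 2·count(b) − 1; clusters grow breadth-first from nodes in
descending count order (ties lexicographic), each UID assigned once; the
canonical UID is the seed, necessarily the highest-count member. The
constants (Hamming radius 1, the 2c−1 count test) are the standard
directional-adjacency choice; UID errors are modelled as substitutions
only, which is what makes Hamming distance the right metric. An `exact`
mode (one family per distinct UID string) is retained as the baseline
whose inflated low-count variant calls motivate directional clustering.

Families of ≥ `min_family_size` reads (default 3) collapse by per-position
majority vote: ties and positions without an A/C/G/T vote give N, and N
never counts as reference or alternate downstream. Members of a family
share their 5′ coordinate, so minus-strand families are aligned from the
right before voting; the consensus length is the shortest member length
(heterogeneous lengths are rare in practice — they arise here only from
fragments shorter than the read length).

For a family of exactly three reads with per-base error e (uniform over
the three wrong bases), exhaustive enumeration of the 4³ read-triple
outcomes gives the consensus error probability — roughly e²·(1 wrong-base
term) plus 2e² for all-distinct ties resolved to N, i.e. ~2.7 × 10⁻⁵ at
e = 0.003 versus 3 × 10⁻³ raw. The test suite verifies the simulator
against this closed form within Monte-Carlo error, and verifies the
implementation's cluster assignments against an independent brute-force
implementation of the directional rule on enumerated UID multisets.

## Saturation modeling (`uidseq.saturation`)

Complexity curves use *nested* subsampling: one seeded shuffle, prefixes
at every multiple of `step`, full collapse per prefix — so curves are
monotone by construction and deterministic given the seed. Yield follows
`unique = a·√total + b`, fitted by OLS with an intercept (an
intercept-free √ law cannot pass through realistic curve pairs; the
intercept absorbs the ≥3-read threshold's onset). Points from several
samples are pooled by default; a per-total averaging mode exists for
cohort-level fits. Unique coverage (consensus bases over panel bp per
position) relates to unique reads linearly; both models together answer
"what detection limit does allocating T raw reads buy", since the limit at
a position is 1 / unique coverage.

## Panel design (`uidseq.panel`)

Genes rank by total somatic events per coding nucleotide (exons only,
lengths supplied as input), ties broken by larger event count then name.
The panel is the smallest ranking prefix whose detectability — the
fraction of patients with at least `target_k` events summed over the
prefix — strictly exceeds `target_fraction`. This is greedy-by-density
with a prefix cut, not set-optimal, matching how such panels are designed
in practice; a patient's detectable events count multiplicities within one
gene. Forced regions (e.g. a recurrently mutated promoter) add footprint
without entering the ranking. If the target is unreachable the full gene
list is returned with a shortfall flag.

The synthetic catalog generator emulates a public tumor-cohort mutation
table: lognormal coding lengths (median 2 kb, log-sd 0.6), gamma
per-nucleotide gene propensities (shape 0.35, so a few driver genes carry
most events), lognormal patient burden (log-sd 0.5), Poisson counts
scaled to 6 somatic events per patient across the gene universe —
defaults chosen once as a realistic cohort shape. At those defaults the
"3 mutations in >50% of patients" target selects ~30 genes (~75 kb).

## Variant metrics (`uidseq.metrics`)

Base counts tally consensus A/C/G/T/N per panel position; unique depth is
the non-N sum, raw depth is interval coverage of the pre-collapse reads.
Error rates are the non-reference fraction per position after discarding
known SNP positions, positions with unique depth < 20 or raw depth < 200
(low-coverage inflation), and positions with > 10% non-reference
(systematic artifacts); all filters are position-local, hence
order-invariant, and the sample rate is the unweighted mean over retained
positions. Detection limit is 1 / unique coverage (0.4% at 249×, 0.18% at
551×, printed to two significant digits); the coverage required for an
allele fraction f is ⌈1/f⌉ (1000× for 0.1%). Detection of a tracked
mutation means ≥ 1 alternate consensus read — the single-molecule
convention, symmetric with accepting one positive droplet in a digital
PCR assay; the threshold is configurable. Variants detected in more than
3 samples of a cohort are discarded as systematic errors. Concordance
against an orthogonal truth table reports sensitivity to one decimal
(24 of 38 → 63.2%), Pearson correlation of allele fractions over shared
detections, and a per-mutation flag for whether unique coverage reaches
the theoretically required level. The de novo scanner (alt count ≥ 2 and
VAF above the position's detection limit) is a naive base-count screen,
deliberately not a somatic caller.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; `TaggedRead.pos` is the
  strand-aware 5′ coordinate, sequences are stored in reference
  orientation.
- Randomness: one seed per simulation; stage substreams derived from it;
  nested subsampling seeded separately. Reports serialize with sorted
  keys, making full pipeline runs byte-identical for a given seed.
- Degenerate inputs fail loudly: empty catalogs, empty families, zero
  retained error-rate positions, single-total model fits, zero coverage
  detection limits all raise `ValueError` rather than returning NaN.
- `required_coverage` subtracts 10⁻⁹ before the ceiling to absorb binary
  floating-point noise in 1/f.

## What passing tests do and do not show

The simulator reproduces the *mechanisms* — UID family formation, error
suppression by consensus, saturation shapes, cycle/split trends — under
substitution-only errors, uniform fragment sampling within the panel and
a clean reference. It does not model alignment artifacts, indels, quality
variation, GC-coverage bias beyond per-fragment efficiency, strand bias,
or contamination; absolute error rates and coverage figures from patient
cohorts are properties of those cohorts and are not reproduced here, only
the arithmetic that connects them (e.g. coverage → detection limit).
Simulation scales (tens of kb of panel, 10⁵–10⁶ molecules) are
proportionate scale-downs chosen so the full pipeline runs in minutes;
ratios such as raw-to-unique read conversion (~32:1 at defaults) mirror
deep targeted cfDNA experiments.
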