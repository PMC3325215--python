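# Methods

## Generative model of the simulator

The simulator emulates a two-condition (wild type vs mutant) random-primed
RNA-Seq experiment over a transcriptome of three gene groups: nuclear
control genes, prime exosome targets, and chloroplast-encoded transcripts.

**Transcripts.**  Lengths are log-normal (log-mean 7.3, log-sd 0.45,
floored at 300 nt), giving a median around 1.5 kb, typical of plant
mRNAs.  Relative molar abundances are log-normal (log-sd 1.0).
Chloroplast-encoded transcripts carry a per-gene abundance multiplier
(default 100): organellar mRNAs are high-copy, and in leaf tissue the
~100 organellar genes take a read share comparable to the entire nuclear
transcriptome.  Group sizes default to 5,617 / 68 / 34.

**Steady-state decay.**  Decay is modelled as a mixture, not as explicit
kinetics: a molecule is full length with probability `f_intact`, otherwise
its remaining 5′-anchored length follows a truncation law on
`{min_remaining, …, L}` — uniform, or `L − Geometric(rate)` clamped at
`min_remaining`.  The mixture reproduces the 5′ > 3′ coverage signature of
3′→5′ exonucleolytic decay with two interpretable knobs and no rate
constants (which are unknown).  Because the uniform law's support includes
`L`, `f_intact` is a lower bound on the realised intact fraction; the
difference is a few percent at default widths and cancels in two-condition
comparisons.  `min_remaining` (default 150 nt, ≥ read length) represents
the point below which an intermediate is degraded too far to be captured.

Mutant stabilisation is encoded as a higher intact fraction:
control 0.35 → 0.45 (mild), exosome targets 0.25 → 0.75 (strong),
chloroplast 0.60 → 0.60 (unchanged — chloroplast RNA metabolism is
independent of the cytosolic exosome pathway).

**Reads.**  Random priming places a fixed-length read (default 75 nt)
uniformly over a molecule's feasible starts `[0, remaining − r]`.  A
library of fixed size (default 3×10⁵ per sample — desk scale; the real
experiment had ~2×10⁷) is drawn multinomially over molecules with weight
(expression × number of priming sites), using a pool of 50 molecules per
transcript.  An optional monotone positional-bias weight
`1 + slope·(x − ½)` over relative position x mimics the technical 5′/3′
bias of cDNA synthesis; it is off by default and, critically, shared
between conditions when used — the metaprofile check verifies that shared
bias does not masquerade as a condition difference.  No fragmentation
chemistry, sequencing errors, paired ends or genome coordinates are
simulated; reads are emitted directly as transcript-coordinate alignments
(SAM or BED6).

**Analytic oracle.**  Under this model the expected read count at start
`s` is proportional to `bias(s/L) · P(remaining ≥ s + r)`, so the expected
index is a ratio of two exact window sums (`expected_index`).  Note the
edge effect: even for fully intact molecules the 3′-most window offers
only `w − r + 1` feasible starts against `w` in the 5′ window, so the
index baseline exceeds 1 at `f_intact = 1` (w/(w−r+1) ≈ 1.6 for L = 1000,
r = 75).  This mirrors the real assay — fixed-length reads cannot start in
the terminal r−1 bases — and is one reason observed index distributions
are skewed above 1 even before any decay signal.  The baseline is common
to both conditions and cancels in wild-type/mutant ratios.  With r = 1 the
edge effect vanishes and uniform coverage gives exactly 1, which is how
the symmetry fixed point is asserted in the tests.

## Index, filters, group statistics

Windows are `floor(0.2·L)` wide at both ends so the uniform fixed point is
exact for any L; reads are assigned by leftmost base (start-in-window), so
window counts partition reads.  No pseudocounts are used: zero-count
windows yield flagged "nonsense" rows that are removed, exactly as 0/∞
index values must be.  Filters: covered fraction (depth ≥ 1 positions / L)
must be ≥ 0.5 in both samples; indices ≥ 10 or ≤ 0.1 (inclusive bounds)
are outliers.  The covered-fraction threshold interprets "covered" as
depth ≥ 1 (configurable).

Group ratios are ratios of group summaries (mean-of-WT / mean-of-mutant,
likewise medians), not means of per-gene ratios — per-gene ratios of small
counts are badly behaved, and group summaries are what the box-plot view
of the data reports.  The resampling null draws gene sets of the target
group's size from the passing control genes, without replacement within a
set and independently across sets, from one seeded generator; the
empirical p uses the add-one correction so it is never 0.  Group-vs-group
location differences use the two-sided Mann–Whitney U test (tie-corrected;
exact for small tie-free samples): index distributions are heavy-tailed,
so a rank test is the defensible default.  Quartiles use linear
interpolation (the numpy default).

The alternative slope index regresses per-base depth on relative position
over all L positions (scaled to [0, 1]) and normalises the OLS slope by
mean depth; it is undefined for fewer than two covered positions.  Its
sign agrees with the coverage index direction in ≥ 95 % of well-covered
simulated transcripts.

The metaprofile accumulates read starts in `floor(100·s/L)` bins over the
top 10 % of nuclear transcripts ranked by wild-type read count (ties
broken lexicographically by id for determinism), normalised to sum to 1
per sample; the same transcript set is used for both samples so the two
profiles are directly comparable.

## qPCR arithmetic

Relative quantity is `E^(−Ct)` with amplification efficiency E ∈ (1, 2],
default 2 (perfect doubling; the efficiency of each primer pair is
configurable).  Replicates are combined as means of linear-scale
quantities, not of Cts, because the downstream ratios are linear-scale.
The per-genotype 5′/3′ end ratio and the wild-type/mutant ratio of ratios
follow; > 1 flags stabilisation in the mutant.  The in-silico counterpart
counts molecules long enough to template each amplicon (5′ amplicon: first
100 nt; 3′ amplicon: requires the transcript 3′ end), giving a
sequencing-independent route to the same directional call.
Housekeeping-normalised relative expression is the same arithmetic with
the reference gene in the denominator slot.

## Frameshift translation

Deletions are applied in 1-based inclusive ORF coordinates; translation
walks standard-code codons from the start codon to the first stop,
reporting whether a stop was found (a frameshifted frame may run off the
annotated sequence, which is flagged rather than silently truncated).
Masses are average (not monoisotopic) residue masses plus one water,
reported rounded to whole kDa as such predictions are customarily quoted.
The packaged `vip3_synthetic.fasta` is an artificially constructed
stand-in (synthetic, as named): a 1,055 nt mRNA whose ORF spans nt 1–873
and whose 7 bp deletion at ORF nt 861–867 shifts the frame one base,
reading through the stop into the 3′ UTR and extending a 290-residue,
~32 kDa product to 326 residues and ~36 kDa.  It exercises the deletion
arithmetic end to end; it is not the At4g29830 sequence, and analyses of
the real gene should load the real mRNA FASTA.

## Problem sizes and numerical choices

Simulation-based tests run at deliberately reduced scale, chosen as the
smallest sizes at which each property is statistically decidable: the
parameter-recovery study uses 20 replicate simulations of the full
5,719-transcript design at 3×10⁵ reads per sample with 1,000 null sets
each; the type-I-error study uses 200 repetitions of a 300-gene no-effect
design at 3×10⁴ reads with 200 null sets; analytic-vs-simulated index
agreement uses a 20-point decay grid at 10⁵ reads per point, with the
Monte-Carlo standard error inflated by (1 + reads/molecules) to account
for molecule-pool reuse.  Miniature fixtures scale the chloroplast
abundance multiplier down with the gene-count ratio so the organellar read
share stays realistic.

Determinism: every stochastic routine takes either a seed or a
`numpy.random.Generator`; the experiment driver derives per-sample
substreams from one root seed via `SeedSequence`, and pipeline runs are
byte-identical under a fixed configuration (manifests record SHA-256
checksums, the seed and a configuration hash).

## What passing tests do and do not show

The simulator validates the statistical machinery — filters, index
arithmetic, null construction, p-value calibration — under a model where
3′→5′ truncation is the only coverage-shaping force besides an optional
shared positional bias.  Real libraries additionally contain spliced-form
ambiguity, mappability and GC effects, 5′ decay pathways, and
condition-specific technical bias, none of which are modelled; a real
analysis should therefore lean on the metaprofile comparability check and
the qPCR validation rather than on simulation-derived guarantees.  The
absolute index level is assay-dependent (edge effect plus priming bias);
only comparisons between conditions and groups are interpretable.

## Known limitations

Single-isoform transcript models only; unstranded reads assumed; no BAM
emission (SAM/BED only, though pysam reads what it reads); the slope index
uses unweighted OLS and is sensitive to long zero-coverage tails; the
geometric truncation law concentrates mass near the 3′ end and is the
right choice only for weakly processive decay.
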