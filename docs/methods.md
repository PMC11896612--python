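# Methods

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention) internally;
publication-style 1-based fully-closed coordinates are converted once at
the boundary (`GenomicInterval.from_one_based`). Every overlap question in
the package — mark evidence, binding, co-occupancy, annotation overlap —
uses a ≥ 1 bp intersection with no reciprocal-overlap requirement, since
no such requirement is part of the screen's definitions. Merging of mark
intervals into candidate regions fuses spans closer than a configurable
gap (default 500 bp, chosen as roughly the scale of a nucleosome-depleted
enhancer flank; candidate construction is a deterministic surrogate for
what was originally a by-eye selection of regions in a genome browser, so
results that depend on exact candidate boundaries should be read with that
in mind).

Cross-species mapping is an explicit orthology block map (source interval →
target interval, linear interpolation within a block), not a chain-file
engine. This keeps the artifact self-contained and matches how orthologous
enhancer sequences are in practice read off a browser alignment track. A
region with no overlapping block is "unmapped": human datasets then record
no evidence, with a note, rather than an error.

## The putative-enhancer rule

For a gene robustly transcribed in both species' ECs, a candidate region
is putative iff at least one mouse dataset and at least one human dataset
carry a mark overlapping it. For genes poorly transcribed in the human
cell lines the rule is relaxed to at least two **distinct mouse datasets**
(two intervals from the same track do not count — evidence is counted per
dataset, not per interval). Transcription status is an input, not a
computation: it comes from promoter open-chromatin/H3K4Me3 assessment done
upstream. Marks whose signal extends to many non-EC cell types still count
as evidence but are propagated with a non-specific flag rather than
silently dropped.

## Enhancer naming

`<gene><sign><kb>`: distance from the enhancer midpoint to the TSS,
rounded to the nearest kb with ties away from zero; sign is "+" downstream
of the TSS in the direction of transcription, "−" upstream. Midpoint
rather than nearest-edge distance is used (the convention is only
"approximate distance", and midpoint is representation-invariant). A
distance that rounds to 0 kb renders as "+0" — a signed zero has no
meaning here.

## Motif scanning and conservation tiers

Motifs are IUPAC consensus strings scanned on both strands; all matches,
including overlapping ones, are reported (summaries use existence, not
counts, so greedy masking would only lose information). A sequence `N`
never satisfies a constrained consensus position. An optional 4×w weight
matrix with a score threshold can replace consensus matching per motif.

The default motif set pairs the two consensi stated in the source analyses
(RBPJ `TGGGAA`, ETS core `HGGAAR`) with standard literature consensi for
the remaining families (SOX `WWCAAW`, FOX `RYAAAYA`, MEF2 `CTAWWWWTAG`,
NR2F2 `TGACCT`, KLF4 `GGGGNGGGG`, TCF/LEF `CTTTGWW`, SMAD `GGCGCC`).
These defaults are deliberately config-overridable (TSV motif file):
reproducing any specific study's tallies requires that study's own motif
definitions, which are not shipped here.

Conservation tier per hit, against an aligned orthologous profile
(reference row first, equal-length rows, gaps `-`):

* D_e — species whose row covers ≥ 50% of the core with non-gap bases
  (the enhancer's own conservation depth);
* D_m — species whose bases at the hit's columns match the consensus on
  the hit's strand (any gap in the window fails).

Tier = **strong** if human ∈ D_m and D_e ⊆ D_m; **weak** if human ∈ D_m
but D_e ⊄ D_m; **none** if human ∉ D_m. The subset relation is the
formalization of "conserved to the same depth as the surrounding
sequence"; the 50% coverage threshold makes "the enhancer aligns in this
species" precise and is exposed as a parameter. Deleting a species from
D_m can never upgrade a tier (tested property).

The FOX:ETS composite is geometric: a FOX hit immediately 5′ of an ETS hit
on the same strand with ≤ 2 bp gap (both parameters exposed). Composite
FOX hits are excluded from the independent-FOX status and reported under a
separate `FOX:ETS` key.

## Binding calls and co-occupancy

Per (enhancer, TF family): bound iff ≥ 1 bp peak overlap; `C` when the
family also has a conserved motif (strong **or** weak — the encoding does
not restrict "corresponding motif" to strong tier), `c` when bound without
one, unbound otherwise. Peak spans are used as deposited; no summit
extension. Co-occupancy reports, per reference peak, overlap with each
query set, with their union and with all jointly; the union fraction is
necessarily ≥ every per-query fraction and the joint fraction ≤ every one
(tested invariants). Fractions are reported to 0.1%.

## Activity classification

Active iff `n_gfp_positive / n_injected > 0.05`, strictly — "more than
5%" — so a region at exactly 5% is inactive. The weak/strong split among
actives is an input flag (weak GFP and/or restricted to a few ECs is a
microscope judgement, not a count), and a vein-restricted active region
remains "active": arteriovenous pattern is carried by a separate label,
not by the activity rule. Counts are used as printed; whether the
denominator excludes unscoreable embryos is not modelled. At a true
positive rate of 0 the classifier's false-positive rate is exactly 0 (zero
positives can never exceed the threshold); at rate 0.5 and n = 50 its
power exceeds 0.999 (binomial tail).

## Class summaries and the enrichment contrast

Status tables store (k, n) per family × class for a chosen status set
({M}, {M, m}, {C}, {C, c}); counting is by set intersection, so the motif
and binding dimensions can be queried jointly or separately. The
enrichment contrast between two classes is a two-sided exact
hypergeometric test (summation of tables no more probable than the
observed one), with a Haldane 0.5 correction on the odds ratio when a cell
is zero. This test is an extension — the source analyses report raw
fractions only — and is marked as such here. In silico labels are opaque
strings matched exactly; no re-derivation from chromatin signal is
attempted.

## Synthetic data generator

The generator emulates the screen's structure: eight loci of 130 kb (TSS
centred), 41 planted putative enhancers of 350 bp at signed offsets from
the TSS, five mark datasets (three mouse, two human), a six-taxon species
ladder (mouse, rat, human, dog, chicken, zebrafish) with substitution
rates growing with divergence rank (0.04 → 0.35 per base), noise marks at
an expected 2 per track per locus, peak-edge jitter of sd 50 bp, and
binomial assay counts with 40–250 injected embryos at true rates of 0.5
(active), 0.15 (weak) or 0 (inactive) — sizes and rates chosen to match
the scale of the real screen. Three loci are flagged poorly transcribed in
human ECs and exercise the relaxed rule.

Design choices that make truth recovery exact rather than probabilistic:

* Orthologue rows use per-base substitution **without indels** inside
  cores, so alignment columns are trivial — the tier logic, not aligner
  behaviour, is under test.
* Planted motif realizations are rejection-sampled so they embed no match
  of any other default family, and background core sequence is scrubbed of
  chance motif matches after planting; recovery of position/strand/tier is
  then exact by construction. Palindromic consensus patterns (the MEF2
  box) necessarily match both strands at the planted position, so truth
  comparisons key on (family, position, tier).
* Tier semantics are enforced literally: strong plants stay intact in
  every aligning species, weak plants only in human, none plants are
  disrupted in human (one substitution at a constrained consensus
  position).
* Noise marks are placed with a 600 bp exclusion margin around planted
  spans and each other — above the 500 bp merge gap — so a noise candidate
  can never accumulate a second dataset's mark by merging, and every
  false candidate fails the calling rule by construction.

What passing on synthetic data does **not** show: robustness to indels and
alignment error, to partially overlapping/jittered mark boundaries around
true enhancers, to motif matches inside repetitive sequence, or to the
enumeration of candidate regions as done by eye in the original screen.
The desk-scale analyses (mark survey, activity, concordance) run on the
transcribed published tables and are independent of the simulator.

## Pipeline

Stages run in a fixed order (call-enhancers → scan-motifs → call-binding →
classify-activity → summarize), each consuming and producing only
documented TSV/BED/FASTA formats so they are independently runnable. The
run manifest is a flat key=value file; validation returns every problem at
once. Outputs carry a provenance header (version, manifest hash, seed) and
contain no timestamps, so reruns on unchanged inputs are byte-identical
(tested).

## Known limitations

* Candidate-region construction is a declared surrogate; the original
  region enumeration is not reconstructible.
* The default motif consensi are placeholders for family-level scanning,
  not any specific study's matrices; per-family tallies on real enhancers
  therefore require a user-supplied motif file.
* Co-occupancy percentages on real CUT&RUN peak sets require the deposited
  peak data; the functions support them, but no real peaks ship here.
* The exact test in the enrichment contrast is unconditional on nothing
  beyond the margins; with the small class sizes typical here its power is
  limited, and no multiple-testing policy is applied (raw p-values only).
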