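# Methods

This note records the models, parameter choices and numerical decisions
behind `pseudoquant`, and what the synthetic test bed does and does not
establish about real data.

## Homologous-locus discovery

The search is seed-and-extend: exact 12-mer seeds on both strands, seeds
clustered into same-diagonal segments (diagonal drift ≤ 20, target gap
≤ 1 kb, ≥ 2 seeds), segments chained colinearly with intra-chain target
gaps up to 30 kb so a parent gene chains across its own introns while a
processed pseudogene chains as one contiguous segment. Each chained block
is aligned with a banded Gotoh affine aligner (match +2, mismatch −3, gap
open −5 for the first gapped base, gap extend −2 — blastn-like so
identities are comparable to a megablast search; band 48 beyond the length
difference). The kernel is one plain-numpy function, jit-compiled by numba
when available and run interpreted otherwise.

Three refinements matter for correctness:

* **Junction refinement.** Seeds stop short of exon edges, so the query
  bases between two chained segments are split between the upstream and
  downstream exon by a gapless match-count search over every split point
  (ties → leftmost). Applied at intron-like joints (genomic-side gap
  ≥ `g_intron` = 50 bp) with up to 90 bp of unseeded query.
* **Fill blocks.** Unseeded query stretches ≥ 25 bp (missed exons,
  truncated ends) are aligned separately into the intervening window and
  accepted only above 70 % identity — glocal alignments of random sequence
  top out near 65 %, so a truncated copy's missing tail is reported as
  reduced query coverage rather than dragged-down identity.
* **Identity denominator.** Identity = matches / aligned columns, with
  gaps counting as columns *within* blocks but intron-scale gaps (the
  chain joints) excluded. Counting introns as columns would make the
  parent self-hit incomparable with the intronless copies.

Hits require identity ≥ 0.70 and query coverage ≥ 0.50; overlapping hits
keep the higher raw score (ties → leftmost start) and are sorted by
descending identity.

**Classification.** A hit overlapping the parent gene model is `parent`.
Otherwise it is `pseudogene` if intronless (no genomic-side gap ≥ 50 bp)
or if its reading frame is broken, else `paralog`. For intronless hits the
ORF test is literal: longest ATG→stop frame in the locus sequence ≥ 0.9 of
the parent CDS length. For intron-containing hits a literal scan cannot
see the spliced ORF, so the implied transcript (concatenated aligned
segments) is aligned to the parent cDNA with stiff gap costs (−16/−8;
gaps only at true indels) and parent-CDS codons are read through that
alignment: a stop in a cleanly aligned interior codon breaks the frame,
codons within 6 bp of a reconstructed junction are ignored (junction
splits can slide a few bases), and unreadable stretches ≤ 4 codons are
neutral while longer ones (a missing exon) break the frame. The longest
clean codon run over the CDS length is the reported ORF fraction. This
reconstruction is reliable to roughly 10 % divergence; beyond that a
functional paralog may be conservatively reported as a pseudogene, which
is why the synthetic paralog analogue is planted at 8 % divergence (the
classification rule itself is exercised at 30 % divergence with
truth-constructed hits in the test suite).

## Assay design

Discriminating sites come from a star alignment: each homolog aligned
pairwise to the design template (stiff gaps, −12/−6, because the
projection wants colinear columns) and projected onto template
coordinates; insertions relative to the template are dropped, and
homologs whose exactly-matching columns cover < 50 % of the template are
excluded with a warning. A site is template-unique if every homolog
differs there.

Allele-specific primers enumerate every length (18–25 nt by default) and
strand whose 3′-terminal base lies on a discriminating site, filtered by
Tm (57–63 °C) and GC (35–65 %) windows and ranked by number of 3′-anchored
sites, then Tm proximity to 60 °C, then position. Junction assays place
one primer across an exon–exon junction with ≥ 4 bases on each side;
primary-transcript assays place the pair across an exon–intron boundary
or wholly inside one intron; products are 70–250 bp. Melting temperatures
use unified nearest-neighbor duplex thermodynamics with the entropic salt
correction 0.368·(N−1)·ln[Na⁺] at 50 mM Na⁺ and 500 nM primer, and the
Wallace rule 2(A+T)+4(G+C) below 14 nt. The synthetic workflow relaxes the
Tm/GC windows (50–70 °C, 25–75 %) because random sequence offers fewer
candidates at any given site.

When a junction assay is meant to measure the *total* homologous pool
(the commercial-assay situation), candidates may be screened against the
homolog templates and the pair with the fewest worst-case binding
mismatches wins — pan-transcript assays sit in conserved sequence, and
without this preference a strongly diverged copy can stochastically escape
the cross-amplification the assay class is defined by.

## In-silico PCR

Primer binding is a position-weight mismatch model, not thermodynamics: a
mismatch at 3′ offset 0 carries weight 0.9, offsets 1–2 carry 0.6, 3–4
carry 0.3, the body 0.1, and a site's score is Π(1 − w) over its
mismatches, so a perfect site scores 1 and a single 3′-terminal mismatch
scores 0.1 — the "leaky" signature of allele-specific primers. Sites with
more than 3 total mismatches are discarded; indels and degenerate bases
are not modelled. An amplification needs one primer on each strand, 3′
ends facing, product ≤ 2 kb and at least as long as either footprint; the
best pair by combined score min(forward, reverse) wins, ties to the
shortest product. Calls: robust ≥ 0.5 ≥ weak ≥ 0.05 > none. The weights
and thresholds are model choices exposed as arguments; only call-level
patterns, not band intensities, are claimed.

Poly-T genotyping is exact arithmetic: expected amplicon = 179 bp of
fixed flank + tract length; bins S ≤ 198 bp, L 199–208 bp, VL ≥ 209 bp;
sizing noise (±1 bp uniform) exists only in the synthetic generator, which
also flags bin-edge tract lengths (19/20, 29/30) as misclassification
risks.

## Quantification

C_T is the linear interpolation of the first crossing of a fixed
fluorescence threshold (default 0.15); curves that never cross are
censored at the last cycle and excluded from replicate means with a count.
Replicates aggregate by arithmetic mean with no outlier rejection.
ΔC_T = mean target − mean reference (lower = more transcript);
ΔΔC_T = group mean difference; FC = 2^(−ΔΔC_T). Standard-curve efficiency
E = 10^(−1/slope) − 1 is reported (with R²) but never used to correct FC —
the uncorrected Livak form is the method implemented. Digital PCR inverts
the Poisson occupancy model λ = −ln(negatives/total), copies/µL = λ/volume
(default 26 000 partitions of 0.00091 µL; the volume is this package's
documented assumption, not a vendor value), with a Clopper–Pearson 95 %
binomial interval on positives pushed through the same transform;
saturated plates are flagged rather than raised. Pool fractions are
copies/µL ratios. Group comparison is a two-sided independent-samples
t-test, equal-variance by default with Welch available.

## Phylogeny

Distances are p-distance or Jukes–Cantor −(3/4)·ln(1 − 4p/3) (undefined
at p ≥ 0.75) with pairwise deletion of gap columns. Neighbor joining
follows Saitou–Nei with a deterministic tie rule — the lexicographically
smallest label pair among Q-minimizers, cluster labels being the smallest
member leaf — and negative limb lengths clamp to zero with a warning.
Bootstrap support is the percentage of column-resampled NJ replicates
containing each internal bipartition of the full-data tree, reproducible
given the seed.

## The synthetic test bed

`generate_locus_set` builds a 1676-nt, 10-exon parent cDNA with a clean
ORF over ~90 % of its length, embeds it with 9 introns (250–500 bp) in
random flanks, and plants copies: by default five intronless pseudogenes
at the divergence band of a real processed-pseudogene family (4.1–12.7 %),
two of them 3′-truncated with a premature stop planted a quarter into the
CDS, one on the minus strand; optionally an 8 %-diverged paralog that
keeps introns and whose exonic mutations are reverted wherever they would
create an in-frame stop (a functional gene is under such selection).
Mutations are substitutions only by default so realized identity is
1 − divergence up to binomial noise; an indel mode exists behind a flag.

Cohort CT tables plant a group effect on the ΔC_T scale (default
−1.32 cycles ≈ 2.5-fold, 47 cases vs 20 controls, triplicates at
SD 0.15); only replicate-level noise is modelled, so recovered p-values
are far smaller than biological cohorts would give — the tests establish
the estimator arithmetic, not realistic power. dPCR partitions are drawn
as Binomial(26 000, 1 − e^(−cv)), distributionally identical to
per-partition Bernoulli draws. The treatment generator samples per-line
multipliers uniformly in 1.2–1.5× (RNA), 0.2–0.6× (mtDNA copy number) and
0.2–0.75× (membrane potential). All generators are pure functions of
config + seed (byte-identical reruns), and every truth table is
sufficient to score the downstream module without external data.

What passing tests do **not** show: performance on real genomes with
repeats and segmental duplications (repeat handling is out of scope), Tm
accuracy against melt experiments, primer thermodynamics beyond the
mismatch-weight model (no hairpin/dimer screening), amplification-curve
baseline correction, or efficiency-corrected quantification models.

## Problem sizes

The default suite runs in well under a minute of compute beyond the
one-off aligner jit compile: genomes are tens of kilobases, cohorts ≤ 67
samples, 100-replicate recovery loops, 200 random trees of ≤ 8 taxa, and
26 000-partition plates — sizes chosen so every statistical claim is
still resolved with comfortable margins.
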