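# Methods

This note documents the models behind `tagseq`, the parameters that matter,
the design choices made where more than one reasonable option existed, and
what the synthetic-data tests do and do not demonstrate about real data.

## The assay model

3′-tag sequencing reads a single fragment per captured RNA molecule, the
one adjacent to the poly(A) tail. Each raw read is structured as
`UMI (5 nt) + G-overhang (3 nt) + cDNA insert`: the UMI is a random tag
ligated before PCR, and the three G bases are the nontemplated cytosines
added by the reverse transcriptase during template switching, read back as
guanines. Preprocessing therefore moves the first `umi_len` (default 5)
bases into the read name, discards the next `discard_len` (default 3), and
keeps the remainder as the insert. Inserts shorter than `min_insert_len`
(default 8 nt) after optional adapter trimming are classified as primer
dimers: excluded from analysis but retained in the total read count, so
`kept + dimers + malformed = total` holds for any input stream.

Adapter trimming removes the longest insert suffix exactly matching a
prefix of the adapter, with a minimum overlap (default 3 nt). It is off by
default because demultiplexers usually perform it upstream; the option
exists for raw streams. UMI base qualities are discarded; UMI sequencing
errors surface downstream as ambiguous (non-ACGT) or novel UMIs and are
handled by the deduplication policy below.

## Collision-corrected duplicate estimation

At one (reference, strand, 5′ start) group with per-UMI read counts c_i
over the full UMI space of n = 4^umi_len tags, the nonduplicate read count
is estimated as

    E = (1/n) · Σ_i Σ_j min(c_j, c_i + 1),

a weighted average of per-count predictions: each observed count c (zero
counts included) predicts that reads beyond c + 1 on any UMI are PCR
duplicates, weighted by the number of UMIs carrying that count. Algebraic
properties, all enforced by tests: `classic ≤ E ≤ total reads`, where
classic is the traditional number of distinct observed UMIs; equality with
classic when every c_i ≤ 1; monotonicity in every c_i.

Implementation: the double sum is evaluated over the frequency-of-
frequencies table (how many UMIs carry each distinct count value), reducing
O(n²) to O(d²) for d distinct values — exactness against the literal
double loop is asserted, not assumed.

**Calibration envelope.** The estimator targets the number of distinct
molecules among the reads at a position. Numerical characterization (also
exercised in the test suite) shows it is well calibrated when every
molecule is represented and PCR duplication is bounded — roughly up to one
extra read per molecule, i.e. duplicate fractions up to about a third. With
no duplication at all (pure UMI collisions) it *under*-estimates at high
density (about −19% when true molecules = 2n), though far less than the
classic rule, which is hard-capped at n. With heavier duplication
(≥ 2 reads per molecule on average) it *over*-estimates, increasingly with
density. The saturation study in the acceptance suite therefore uses one
PCR cycle at 50% efficiency with the pool sequenced to completion (33%
duplicate reads): there the mean estimate tracks true molecule counts
within ~2% up to m = 500, ~4% at m = n = 1024, and ~10% at m = 2n — the
qualitative point being that it keeps counting where the classic rule
saturates, not that it is unbiased arbitrarily far past n.

**Policies.** Ambiguous UMIs (containing N or other non-ACGT characters)
are excluded from the count vector, never flagged as duplicates, and each
contributes one nonduplicate read — conservative and read-conserving.
Duplicate *marking* needs an integer target: classic mode keeps the
first-seen read per (group, UMI); corrected mode keeps
`round(E)` reads (round-half-up for determinism), allocating the
post-classic remainder one read at a time to UMIs in decreasing-count
order, ties broken lexicographically. The real-valued E is used directly
in corrected-mode gene counting, so rounding only affects flag labels. The
position key is the soft-clip-adjusted 5′-most aligned base on the read's
own strand; MAPQ < 10 alignments (posterior probability < 0.9) are
discarded before grouping; flags are written as the standard SAM 0x400 bit.

UMI-network error correction (edit-distance clustering) is deliberately
out of scope: the model treats UMIs as exact labels.

## Gene assignment and counting

Annotation is ingested from GTF (1-based closed) into 0-based half-open
transcript models; the transcription termination site (TTS) is the last
base of the last exon on +, the first base of the first exon on −. A read
is assigned by priority: **3′ end** if it overlaps the `end_window`
(default 500 nt, configurable and echoed in output metadata) ending at any
same-strand transcript's TTS — regardless of what else it overlaps;
else **exon**; else **intron** (within a same-strand transcript body); else
**intergenic**. Only sense-orientation features are considered; "overlap"
means ≥ 1 shared base. If two or more genes tie within the winning
category the read is gene-ambiguous: tallied, but counted to no gene. The
500-nt default covers typical tag fragment lengths; raising it can only
move reads into the 3′-end category (a tested monotonicity). End windows
are clipped to the transcript's genomic span.

Counting is gene-level (a per-transcript option is a straightforward
extension; multiple transcripts of one gene are not ambiguity). Classic
mode counts unflagged reads; corrected mode sums per-group estimates E
attributed to the group's category/gene, so counts are fractional.
Libraries with fewer than `min_gene_reads` (default 10,000) reads assigned
to genes are discarded as failed.

## Quantification

Tag data yield one read per molecule regardless of transcript length, so
TPM is a plain proportion scaled to 10^6; the length-normalized variant is
provided for whole-transcript comparisons. Standard curves against
spike-ins of known concentration are summarized by
r′ = Pearson corr(log10 A, log10(C+1)); the +1 admits zero counts, and
zero-abundance reference entries are excluded with a logged count (none
exist in spike-in layouts). r′ is invariant to positive rescaling of
either axis. Capture efficiency is nonduplicate reads / input molecules —
meaningful only for libraries sequenced to completion — reported as a
fraction and as a percent rounded to the nearest integer. Mole→molecule
conversion multiplies by Avogadro's number (6.02214076e23) and rounds.

## Copy-number blocks

Each gene maps to `floor(TTS / block_size)` (default 1 Mb) on its
chromosome, using the 3′-most transcript terminus among the gene's
transcripts (strand-aware) — the TTS anchors the tag signal, hence the
choice of key. Per block and sample the TPM sum is formed and expressed as
`log2((sum + pseudocount) / (reference mean + pseudocount))` with
pseudocount 1 against the mean of a designated reference sample group;
blocks with zero expression in every sample are flagged no-data. An
alternative per-gene-first ordering (log-ratio per gene, then block mean)
is available behind a flag; the per-block default is less sensitive to
single dominant genes. Because TPM is compositional, a 2× amplification of
k% of total expression depresses all other blocks by log2(1 + k/100) —
about −0.1 log2 units in the bundled amplicon simulation — so the readout
is qualitative locality, not calibrated copy number. Segmentation,
breakpoint calling, and amplification tests are out of scope.

## The simulator

The generator emulates a spike-in dilution experiment: abundances placed
at exactly even log10 spacing over the configured span (so max/min is
exactly 10^span); molecules drawn multinomially; capture as independent
Bernoulli thinning (default efficiency 0.3, the value implied by observed
nonduplicate yields in completion-sequenced low-input libraries); one
uniform UMI per captured founder; one fragment position per founder,
uniform over a 3′-proximal window (default 200 nt upstream of the poly(A)
junction) and fixed through PCR — tag chemistry captures the
poly(A)-adjacent fragment once; PCR as a branching process (each molecule
duplicated per cycle with probability `pcr_efficiency`); sequencing as
sampling without replacement from the amplified pool (an aliquot), with a
with-replacement flag; independent per-base substitution errors applied
after lineages are recorded, UMI bases included; optional injection of
sub-8-nt dimer inserts. All randomness flows from one seeded generator
recorded in the truth sidecar, making every output byte-reproducible.

What it does **not** model: instrument-specific quality profiles, indels,
RNA degradation or fragment-length bias, off-target priming, multimapping
(alignments are emitted directly from lineage truth at MAPQ 60,
forward-strand). Tests passing on these simulations therefore validate the
pipeline's arithmetic and bookkeeping under the stated generative model,
not robustness to alignment artifacts or chemistry biases in real
libraries.

## Problem sizes and numerical choices

The standard-curve study uses 92 transcripts over six orders of magnitude,
5×10^6 input molecules, and 6.4×10^5 reads — one tenth the aligned depth
of a full-scale reference experiment; at this depth the expected r′ is
≈ 0.987–0.990, and the acceptance threshold of 0.98 is the point where the
curve's low-abundance tail (expected counts ≪ 1) dominates the residual.
The dilution trend uses 2×10^4 reads against inputs of 10^6 → 10^3
molecules. The saturation study uses 200 replicates per density. Estimator
comparisons are exact to 1e-9 absolute; TPM columns sum to 10^6 within
1e-6 relative; correlation oracles agree to 1e-12. Degenerate inputs:
empty groups estimate 0; all-zero count columns error unless explicitly
allowed; reads shorter than UMI + overhang become empty-insert dimers
rather than errors.
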