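# Methods

## Assay model

The package models an RNA-based reporter MPRA that compares internal ribosome
entry (IRES) with cap-dependent initiation (CDI) for the same 5'UTR
sequences. Each construct exists as two co-transfected mRNA species: a G-cap
copy (functional m7G cap; translation measures CDI) and an A-cap copy
(non-functional cap before a stable stemloop; translation measures IRES
activity). Nascently translating mRNAs are enriched by immunoprecipitation,
and translation efficiency is the log2 ratio of reads-per-million between the
IP and input libraries, per construct and cap class.

TE from RPM ratios is *compositional*: multiplying every molecule's
recruitment by a constant leaves all RPM shares unchanged. Two consequences
run through the design:

* **Global shifts require an external anchor.** Stress comparisons use three
  G-cap spike-in reporters from one unstressed lysate added at a fixed
  fraction to every sample. Their ribosome loading is condition-independent,
  so any apparent between-condition change of their TE measures the global
  shift of everything else.
* **TE estimates carry a fixed offset.** The expectation of an RPM-ratio
  log2 TE is `log2 te − log2(Σ a·te / Σ a)` (abundances `a`, enrichments
  `te`). The simulator's truth object exposes this expectation
  (`expected_log2_te`), which is the correct comparator for recovery
  experiments; the offset is a property of relative normalization, not an
  estimator error.

## Read architecture and its abstraction

The exact primer geometry of the assay is not public, so the package fixes
one self-consistent layout and uses it for both simulation and processing
(all anchors are configurable in `ReadArchitecture`):

```
sense amplicon:  UMI(9-11) + umi-anchor(15) + cap adapter(17) + UTR + common adapter(15) + stagger Ns
mate 2 = sense strand          (UMI at the 5' end, cap adapter near the 5' end)
mate 1 = antisense strand      (stagger Ns, then CTTAATCACAGATCT = revcomp of the common adapter)
```

The two 17-nt cap-class adapters (`AGTCCGCATCCAAGCTT` for A-cap,
`TCCAAGCGATCAAGCTT` for G-cap, Hamming distance 9) and the common adapter
`AGATCTGTGATTAAG` are the assay's published constants; the 15-nt UMI anchor
is a synthetic stand-in for the constant RT-primer sequence next to the
molecular index. The stagger (0–6 random-length prefix added by the library
PCR primers) deliberately defeats naive duplicate collapsing, which is why
deduplication is two-staged (below).

## Processing pipeline

Per read pair: (1) locate the UMI as the 9–11 bases 5' of the UMI anchor on
mate 2 and the stagger as the offset of the 5' anchor on mate 1 (each anchor
tolerates one mismatch; missing anchors exclude the read); (2) merge the
trimmed mates at their best ungapped overlap (minimum overlap 10, mismatch
fraction ≤ 0.1, disagreements resolved toward the barcode-bearing mate; exact
seed probes find the overlap in O(n), with an exhaustive offset scan as
fallback); (3) split by cap class — merged reads require the common adapter
and exactly one cap adapter at 0 mismatches, unmerged pairs require the 5'
anchor on mate 1 and a cap adapter on mate 2 at up to floor(0.07 × length)
mismatches each, mirroring the single-read/paired adapter-error settings the
assay's own processing used; reads matching both adapters are conservatively
unassigned; (4) stage-one collapse on (insert, UMI, stagger) — duplicates
differing only in stagger survive, by design; (5) assignment to the construct
database by position-anchored 15-mer seeds plus Hamming verification with a
hard budget (default 2 substitutions); equally good best hits are *ambiguous*
and discarded, never tie-broken, because mis-mapping even a few reads can
fabricate weak IRES signal; (6) stage-two collapse: a count is the number of
distinct UMIs per (construct, cap class, sample). UMI matching is
exact-string; no 1-mismatch UMI networks.

Quantification: technical replicates are summed, then biological replicates
(after Pearson-correlation QC on per-replicate TEs, excluding constructs with
zero IP reads in either member of a pair); constructs with fewer than 10
counts in any input library are removed; IP zero counts are replaced by a
1e-6 pseudocount before RPM scaling and flagged (no display floor is imposed
— flags travel with the table); RPM denominators span the whole sequencing
sample across both cap classes, because A-cap and G-cap molecules come from
one pool split in silico and per-class normalization would erase the genuine
global IRES-vs-CDI difference.

## Spike-in normalization

The three spikes are serially diluted 1:10:100 and enter each lysate at 1% by
volume. The fitted factor per condition is a geometric mean over spikes of
`te_spike(condition)/te_spike(reference)` — the fold by which library
translation globally dropped (2 means a uniform 2× suppression); adjusted TE
is `te / factor`, and the reference condition has factor 1. By default each
spike's log ratio is weighted by its designed relative abundance: a spike's
TE sampling variance scales inversely with its molecule count, so designed
abundance is approximately inverse-variance weighting, and the unweighted
mean (`weights="equal"`) lets the 100×-diluted spike contribute a third of
the weight with ~100× the variance. A linearity check (r² of observed log
input RPM against designed log abundance) verifies the dilution series
survived the experiment. Because the spikes hold a share *s* of the IP mass,
the factor recovered for a uniform drop of 2 is `2/(1+s)` — negligible bias
at the designed 1%, which is why the stress benchmark runs at that fraction.

Spikes are G-capped; the single fitted factor is applied to both cap classes
(the global shift it measures is a property of the sample, not of one cap
class). TE is normalized directly, rather than normalizing input and IP
separately, since the spikes measure the composite IP-over-input shift.

## Structure–function statistics

Activity calls use the CrPV IRES's A-cap TE as an inclusive lower bound
("at least as much" translation is active). IRES-as-%-of-CDI is
`100 × te(a_cap)/te(g_cap)`. Scanning-mutagenesis fold changes
(variant/wildtype A-cap TE) map to each window's center nucleotide,
floor((start+end)/2), e.g. nt 2 for window 1–3. Helix rescue reports
`rescue_index = te_C/√(te_L·te_R)` and a restoration fraction that places
log2 te_C on the scale from the disrupted baseline (mean of log2 te_L and
te_R → 0) to wildtype (→ 1), clipped to [0, 1.5]; the baseline choice is this
package's own, as no standard formula exists. Strong-pair fractions count
G·C pairs (either orientation) over all pairs including pseudoknots; G·U
wobbles stay in the denominator. Group comparisons use the one-sided
Mann–Whitney rank-sum test (active > inactive) with the exact null for small
tie-free groups — chosen for robustness at the few-per-group sizes typical of
IRES subtype comparisons.

## Synthetic data: what it does and does not emulate

The generator draws per-(construct, cap class) input abundances from a
log-normal (σ = 1 by default, a realistic oligo-pool skew) and true TEs as
2^Uniform(−5, 5) (the ~1000-fold activity range such assays span); IP read
composition is multinomial with weights abundance × TE. Molecules get uniform
random UMIs of length 9–11 (equal weights) and i.i.d. geometric PCR copy
numbers (mean 1.5 — the real duplication distribution is unpublished); each
copy draws its stagger independently. Substitution errors are i.i.d. at rate
ε (default 0.001, Illumina-like). Spike-ins appear in both input and IP at
the designed dilution. Per-condition effects multiply true TEs of non-spike
constructs (optionally exempting designated stress-resistant constructs);
spikes are exempt by construction since their loading predates lysate
mixing.

Not modeled: indels, quality-score structure (qualities are constant and the
pipeline ignores them), optical duplicates, adapter dimers, UMI errors,
cross-contamination. Passing tests therefore demonstrate correctness of the
counting, normalization and inference logic under realistic sampling noise —
not robustness to artifacts the generator does not produce.

## Numerical choices and degenerate inputs

Ties in construct assignment and cap-class matching resolve to explicit
`ambiguous`/`unassigned` states, never randomly. Merge-offset ties prefer
lower mismatch fraction, then longer overlap, then leftmost placement.
Zero-pair structures make the G·C fraction undefined (error), as does a
zero-denominator luciferase ratio or a filtered spike-in. All randomness
flows from a single integer seed through named, per-sample seed derivations;
FASTQ output is byte-identical across reruns.

## Benchmark problem sizes

The recovery benchmarks run at: UMI-count oracle 10³–10⁵ reads; error-free
channel 2×10⁴ reads; TE recovery 500 constructs × 10⁶ read pairs per sample;
dilution recovery 10⁵ spike reads; global-shift recovery 8×10⁵ read pairs per
sample over four samples. At the TE-recovery conditions the RMSE of log2 TE
over constructs with ≥100 input UMIs is dominated by IP-side Poisson noise of
low-TE constructs (a te = 2⁻⁵ construct receives only a handful of IP
molecules); the benchmark therefore also reports the RMSE restricted to
constructs with ≥10 IP UMIs and the sampling floor implied by the realized
counts, which the ratio estimator attains.
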