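# Methods note

`pedscan` implements family-based homozygosity mapping for a fully
penetrant autosomal recessive trait observed in a single nuclear family,
followed by identity-by-descent (IBD) verification with microsatellites and
an in-silico restriction-fragment (RFLP) genotyping assay for a candidate
coding variant. This note records the model, the default parameters, what
the synthetic data generator does and does not cover, the numerical
choices, and the known limitations.

## Genetic model

- **Inheritance.** The trait is autosomal recessive with full penetrance:
  affected individuals carry two copies of the causal allele inherited
  identically by descent; unaffected individuals carry at most one.
- **Control-frequency bounds.** In a nuclear family with `p` obligate-carrier
  parents and `s` unaffected littermates, the risk-allele frequency among
  the `p + s` controls is bounded below by `p / (2(p + s))` (only the
  parents carry it) and above by `(p + s) / (2(p + s)) = 0.5` (every
  control heterozygous). For the bundled two-parent, five-littermate family
  this is (2/14, 7/14), printed as (0.14, 0.50) at two decimals.
  `derive_control_bounds` computes these from pedigree structure alone.
- **Marker filter.** A biallelic SNP is *consistent* with the model when
  (a) every affected is homozygous for one shared allele (case frequency
  1.0), and (b) the control frequency of that allele lies inside the closed
  bounds interval. Markers where any unaffected family member is homozygous
  for the case allele are additionally excluded (full penetrance forbids
  it). Bounds are compared unrounded; the two-decimal rounding is applied
  only for display.
- **IBD vs IBS.** Runs of consistent SNPs can arise by state rather than
  descent. Multiallelic microsatellites within the candidate span plus a
  1 Mb flank window on each side arbitrate: a marker is informative when at
  least two alleles are observed in the family; a heterozygous case — or
  two cases homozygous for *different* alleles — at an informative marker
  rules IBD out (`not_ibd`); all cases homozygous for one shared allele at
  every informative marker, together with an identical Mendelian-phased SNP
  haplotype across the region, is `ibd_consistent`; no informative marker
  yields `uninformative`. Two cases homozygous for different alleles cannot
  share one ancestral segment, so that configuration is classified
  `not_ibd` rather than left in the fall-through branch.
- **Phasing.** Offspring haplotypes are resolved per marker by trio logic
  only where transmission is uniquely determined (a homozygous parent or a
  homozygous child); ambiguous sites stay unresolved and are never guessed.
  Any marker with a Mendelian inconsistency in any trio is masked
  everywhere and logged as a possible genotyping error.

## Synthetic data generator

Real array genotypes for the mapped family are not deposited, so a
gene-drop simulator stands in for them, with complete founder-origin truth
labels for every allele.

- **Pedigree.** The bundled template mirrors the published family
  structure: two common ancestors whose descendants (first cousins) are
  mated, producing a litter of 7 with 2 affected; 15 individuals in all,
  9 of them the genotyped nuclear family.
- **Transmission.** Each meiosis draws crossover counts from
  Poisson(L/100) for a 100 cM chromosome under the Haldane model (no
  interference) and uniform crossover positions; genetic distance is scaled
  to physical coordinates at 1 cM = 1 Mb. Haplotypes are represented as
  founder-origin mosaics (half-open bp segments tagged with a founder
  haplotype id), which is what makes exact span-level IBD truth queries
  possible.
- **Markers.** Defaults: 6 chromosomes of 100 Mb, 150 SNPs and 4
  microsatellites per chromosome, founder SNP allele frequencies drawn
  uniformly from [0.05, 0.95], 6 equifrequent microsatellite alleles, and
  one causal biallelic locus at 50 Mb on chromosome "23". The pipeline
  replaces uniform microsatellite placement with *targeted* placement — two
  markers per flank of every candidate-gene window — mirroring the targeted
  microsatellite genotyping of candidate regions in the source study;
  uniform placement almost never puts a marker within the 1 Mb flank
  window of a narrow candidate run.
- **Conditioning.** The observed affection pattern (both affected
  homozygous IBD, no unaffected homozygous) has probability ~1e-3 per
  gene drop, and only the causal chromosome's meioses affect it, so the
  simulator rejection-resamples *only that chromosome* (chromosomes are
  independent under Haldane, making this exact), bounded at 10,000 rounds.
- **Errors.** Optional symmetric per-allele genotyping error; at the
  default rate 0 every emitted call equals the truth haplotype pair.
- **Determinism.** One global seed; per-stage substreams (map, founders,
  gene drop, errors) are spawned via `numpy.random.SeedSequence`, so any
  stage's output is reproducible independently of the others.

## Numerical and format choices

- Genotypes are PLINK text PED/MAP with a FAM pedigree dialect; candidate
  genes are BED (0-based half-open). All 1-based/0-based conversion happens
  in one place (`Region.contains_position`).
- Allele calls are stored as canonically sorted unordered pairs; "0" is the
  missing allele and half-missing calls are rejected at parse time.
- Frequencies use twice the number of fully called individuals as the
  denominator and are `NaN` (undefined), never 0, when no one is called.
- The restriction enzyme model is a recognition sequence plus a signed cut
  offset on the written strand, with the reverse-complement orientation cut
  at the reflected coordinate; fragment lengths always sum to the amplicon
  length. BtsI is `CACTGC` with offset −2 (cuts two bases 5' of the site).
- cDNA coordinate c.N maps to codon `ceil(N/3)`, position `(N−1) mod 3 + 1`;
  amino-acid changes are translated with Biopython's standard table.

## Default run-support choice (`min_run_length = 1`)

The filter originally required three consecutive passing SNPs before
reporting a region, to suppress single-marker identity-by-state noise. The
generator, however, draws founder alleles independently per marker — there
is deliberately no linkage disequilibrium — so markers inside the true IBD
segment pass only when their shared-haplotype allele happens to be rare
among controls (measured per-marker pass probability ~0.15–0.35). Three
consecutive passes inside the causal window are therefore uncommon
(~13–17% of runs at either 150 or 400 SNPs per chromosome), even though the
causal marker itself passes deterministically. With run support 1 the
causal gene region is reported in 200/200 default-condition runs, and
specificity is carried instead by the candidate-gene intersection and the
microsatellite IBD stage — the same division of labour as the published
workflow, where 3 of 18 genes survived the frequency filter and
microsatellites reduced them to one. The knob remains available
(`FilterParams(min_run_length=...)`) for dense, LD-bearing data.

## Known limitations

- **No linkage disequilibrium.** Founder haplotypes are drawn independently
  per marker. Consequences: candidate runs are much narrower than real SNP
  haplotype blocks, and the default run support is 1 (above).
- **End-to-end recovery is ~90%, not 100%.** Across seeds 0–199 the causal
  gene region is always reported by the scan stage, but in 20/200 runs the
  final gene list misses it: the candidate run is essentially the causal
  marker alone, and across the ~12 informative meioses the true IBD segment
  ends between the causal locus and a flanking microsatellite 0.2–1.8 Mb
  away (~0.8 cM per meiosis), so the microsatellite stage truthfully
  returns `not_ibd` for the sampled span. Every such verdict was verified
  against the generator's founder-origin truth (`TruthRecord.ibd_over_span`);
  the verdicts are correct for the span they test — the loss is a sampling
  artifact of the sparse, LD-free map, not a defect of the verdict rule.
- **`ibd_consistent` is consistency, not proof.** A region can match the
  IBD pattern by state at every informative marker; the rule-based verdict
  makes no probability statement.
- **Uniform genome.** Equal-length chromosomes, uniform marker spacing,
  uniform cM↔Mb scaling, no interference, no sex-specific maps.
- **Desk scale by design.** Single CPU, seconds per simulated run; the
  package is not an engine for biobank-scale scans.
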