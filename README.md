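# pedscan

Recessive-trait homozygosity mapping in a single linebred nuclear family:
a genome-wide segregation filter over SNP genotypes, identity-by-descent
(IBD) verification with flanking microsatellites, and an in-silico
restriction-digest (RFLP) genotyping assay for the resulting candidate
variant.

## The problem

A litter contains two puppies affected by a congenital myasthenic
syndrome; their parents are first cousins sharing two recent common
ancestors. Under autosomal recessive inheritance with full penetrance, the
affected animals must be homozygous for one causal allele inherited
identically by descent (IBD) from a common ancestor, while every unaffected
relative carries at most one copy. With only nine genotyped family members,
a classical linkage scan is hopeless — but the pedigree structure alone
constrains which markers *can* segregate with the trait:

- every affected individual must be homozygous for the same allele
  (case frequency 1.0);
- both parents are obligate carriers, so among the 7 unaffected controls
  (2 parents + 5 littermates) the risk-allele frequency must lie in
  **[2/14, 7/14] = [0.14, 0.50]**;
- no unaffected individual may be homozygous for the case allele.

Markers passing this filter inside a panel of candidate genes are then
tested for genuine IBD (as opposed to mere identity by state) using
multiallelic microsatellites flanking each region: a single heterozygous
case at an informative microsatellite rules IBD out, while shared
homozygosity plus an identical phased SNP haplotype is consistent with one
ancestral segment. Finally, a candidate coding variant (c.1010T>C, the
I337T substitution) is genotyped by restriction digest: the variant base
completes a BtsI site, cutting the 470-bp amplicon into 204 + 266 bp
fragments, so wild-type, carrier, and affected animals show 1-, 3-, and
2-band gel patterns.

Real array data for the family are not deposited, so `pedscan` ships a
gene-drop simulator that reproduces the family structure and transmission
model (Haldane crossovers, founder-origin mosaics) with complete truth
labels — every analysis claim in the test suite is checked against that
truth. See [docs/methods.md](docs/methods.md) for the model, parameter
choices, and limitations.

## Worked example

One command simulates the family, runs the scan, and verifies IBD:

```sh
pedscan --log-level WARNING run --seed 11 --output-dir out/
```

Abridged report (genuine output, reproducible with the same seed):

```json
{
  "control_bounds_rounded": [0.14, 0.5],
  "n_markers": 973,
  "n_passing_markers": 11,
  "candidate_regions": 1,
  "verdicts": [[["COLQ"], "ibd_consistent"]],
  "final_genes": ["COLQ"],
  "obligate_carriers": ["anc1", "dam", "gm2", "gp1", "sire"]
}
```

Of 973 simulated markers, 11 pass the recessive filter; one candidate
region intersects the 18-gene panel, and the microsatellite stage confirms
it as the only IBD-consistent region — the gene containing the planted
causal locus. `out/` holds the genotypes (PED/MAP/FAM), the per-marker
decision table (TSV, header carries the config hash), the candidate-gene
BED, the JSON report, and the simulation truth record.

Annotating the candidate variant and predicting the diagnostic digest:

```sh
pedscan annotate --cds-fasta cds.fa --position 1010 --ref T --alt C
```
```json
{
  "cdna": "c.1010T>C",
  "codon_index": 337,
  "codon_position": 2,
  "ref_aa": "I",
  "alt_aa": "T",
  "label": "I337T",
  "synonymous": false
}
```

```sh
pedscan digest --builtin-fixture
```
```json
[
  {"allele": "wild_type", "enzyme": "BtsI", "fragments_bp": [470]},
  {"allele": "variant",   "enzyme": "BtsI", "fragments_bp": [204, 266]}
]
```

The same steps are available as library calls
(`pedscan.simulate`, `recessive_marker_filter`, `verify_ibd`,
`predict_aa_change`, `digest`, `run_pipeline`) and as separate subcommands
(`simulate`, `scan`, `ibd-check`) operating on PLINK text files.

## Layout

```
src/pedscan/
  pedigree_io.py       pedigrees, markers, genotypes, regions; PED/MAP/FAM/BED I/O
  synthetic_family.py  gene-drop simulator with founder-origin truth labels
  segregation_scan.py  recessive filter, control bounds, candidate regions
  ibd_verify.py        trio phasing, microsatellite IBD verdicts
  variant_assay.py     cDNA→codon annotation, restriction digest, RFLP calls
  fixtures.py          deterministic synthetic sequences and gene panels
  pipeline.py, cli.py  orchestration, YAML config, `pedscan` CLI
tests/                 unit, property (hypothesis), and acceptance tests
scripts/acceptance.py  recomputes the acceptance-target values
docs/methods.md        model, parameters, numerical choices, limitations
```
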