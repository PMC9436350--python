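# edu-xrseq

Analysis toolkit for **XR-seq of EdU excision repair**: from raw
excised-oligomer sequencing reads to excision-product length/composition
profiles, transcribed- versus nontranscribed-strand repair quantification,
unit-gene metaprofiles, and chromatin-context enrichment — together with a
ground-truthed read simulator so every stage can be verified without any
external data.

## The scientific problem

5-ethynyl-2′-deoxyuridine (EdU) is a thymidine analog incorporated into DNA
during replication. It turns out to be a substrate for nucleotide excision
repair (NER): the dual-incision excision nuclease releases EdU-containing
oligomers of 22–30 nt (nominal 26-mer) with the lesion located 19–21 nt from
the product's 5′ end. XR-seq captures, amplifies and sequences these excised
oligomers, mapping repair genome-wide at single-nucleotide resolution.
Because RNA polymerase II recruits repair to the template strand,
transcription-coupled repair (TCR) produces an excess of transcribed-strand
(TS) reads over nontranscribed-strand (NTS) reads in active genes, and
repair is further modulated by chromatin accessibility.

This package is aimed at researchers analyzing (or modeling) XR-seq
libraries of EdU repair. It provides:

- **`synthetic_data`** — a simulator for the full data-generating process:
  per-thymidine EdU incorporation (probability `p_edu` per T, both strands),
  dual-incision geometry parameterized as a 5′ offset `d` (lesion position
  from the 5′ end, pmf over {19, 20, 21}) plus a 3′ tail `k` (pmf over
  {3..9}) so product length `L = d + k` spans 22–30 with mode 26, a
  transcribed-strand excision enhancement α inside expressed gene bodies,
  chromatin-state rate multipliers, and library artifacts (3′-adapter
  read-through, PCR duplicates). Every read carries a truth record
  (chromosome, strand, lesion coordinate, 5′ offset).
- **`preprocess`** — cutadapt-style 3′-adapter trimming, exact-sequence
  deduplication, and a k-mer-seeded exact aligner that keeps only uniquely
  mapping reads, with an exactly balanced count ledger per stage.
- **`damage_profiles`** — length histograms, positional base composition
  (5′→3′ along the excised strand), and the lesion-signature filter that
  keeps 26-mers with T at position 19 and 27-mers with T at position 20.
- **`repair_landscape`** — analysis-gene selection (length > 5 kb,
  inter-gene distance ≥ 5 kb, no overlaps), TS/NTS assignment (a fragment is
  TS when its strand is opposite the gene's annotated strand), RPKM,
  unit-gene metaprofiles (2-kb flanks in 100-bp bins, body rescaled to 60
  bins), TS:NTS ratios and time-course tables, strand-specific bedGraph
  tracks.
- **`chromatin_context`** — read density per chromatin state (normalized per
  million mapped reads per kilobase of interval) and aggregate profiles
  around DNase-hypersensitivity peak summits, split genic/intergenic.

## Worked example

```python
from edu_xrseq.models import SimulationConfig
from edu_xrseq.pipeline import build_fixture, preprocess_bundle
from edu_xrseq.damage_profiles import (
    damage_signature_filter, length_histogram, modal_length,
    positional_base_composition,
)
from edu_xrseq.repair_landscape import (
    select_analysis_genes, ts_nts_ratio, unit_gene_metaprofile,
)

# 2-Mb genome, 40 genes, 50k reads, default excision geometry, alpha = 2.5
bundle = build_fixture(seed=1, config=SimulationConfig(n_reads=50_000))
result = preprocess_bundle(bundle)
ledger = result.ledger
print(f"aligned {ledger.n_aligned} of {ledger.n_input} raw reads "
      f"({ledger.n_duplicates} duplicates removed)")

hist = length_histogram(result.fragments)
print("modal product length:", modal_length(hist), "nt")

comp = positional_base_composition(result.fragments, bundle.genome, 26)
print("T-frequency argmax (26-mers): position", comp.argmax_position("T"))

kept, _ = damage_signature_filter(result.fragments, bundle.genome)
genes = select_analysis_genes([g for g in bundle.genes if g.expressed])
profile = unit_gene_metaprofile(kept, genes, total_mapped=ledger.n_aligned)
print(f"genome-wide TS:NTS ratio: {ts_nts_ratio(profile):.2f} "
      f"({len(genes)} analysis genes)")
```

Output:

```
aligned 49479 of 54948 raw reads (5469 duplicates removed)
modal product length: 26 nt
T-frequency argmax (26-mers): position 20
genome-wide TS:NTS ratio: 2.32 (29 analysis genes)
```

The modal length (26 nt) and the thymine peak at position 20 are the
excision-product fingerprint of EdU repair; the TS:NTS ratio estimates the
simulated transcription-coupled enhancement (α = 2.5 here; the estimate is
stochastic at 50k reads and tightens at higher depth).

A command-line interface mirrors the library
(`edu-xrseq simulate | preprocess | profile | tcr | chromatin`); run any
subcommand with `--help`.

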