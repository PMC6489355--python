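# cdekit

Computational toolkit for CRISPR/Cas-directed evolution of coding genes:
exhaustive sgRNA tiling of a CDS, cloning-construct design (BsaI-overhang
oligo pairs and polycistronic tRNA-gRNA assemblies), domain-focused guide
selection, and amplicon genotyping that converts mutant allele sequences
into normalized DNA- and protein-level variant calls (in-frame deletions,
substitution runs, compound edits, frameshift flags).

## Modules

| module | what it does |
|---|---|
| `cdekit.seqcore` | FASTA I/O, reverse complement, translation, exon-aware gene models, residue/codon coordinate mapping |
| `cdekit.guide_design` | enumerate every NGG-adjacent 20-nt protospacer on both strands; domain-focused subsetting; library TSV |
| `cdekit.construct_design` | annealing-ready oligo pairs with GGCA/AAAC overhangs; PTG (tRNA-spacer-scaffold) assembly; BsaI-site checks |
| `cdekit.genotyping` | affine-gap global alignment (Gotoh, numba-accelerated), DNA variant calling, 3'-shifting indel normalization |
| `cdekit.consequence` | frame classification, residue-level decomposition of in-frame edits (e.g. `Q157del`, `K1049R`, `H1048Q` + `K1049del`), domain annotation |
| `cdekit.nhej_sim` | synthetic cut-and-repair alleles with recorded ground truth (truncated-geometric size laws) |
| `cdekit.cli` | `cdekit` command wiring the whole pipeline |
| `cdekit.demo` | deterministic synthetic reference with pinned residue anchors plus the worked-example mutant alleles |

## CLI

```sh
# enumerate all PAM-adjacent guides on a CDS (or genomic + exon model)
cdekit design --ref cds.fa --out library.tsv
cdekit design --ref genomic.fa --exons exons.gff3 --out library.tsv
cdekit design --ref cds.fa --domain 1030-1090 --out hr-guides.tsv

# cloning artifacts
cdekit oligos --library library.tsv --out oligos.tsv
cdekit ptg --library library.tsv --guides sg-092,sg-119 \
    --trna trna.fa --scaffold scaffold.fa --out ptg.fa

# synthetic alleles with ground truth
cdekit simulate --ref cds.fa --guide sg-007 --n 100 --seed 42 --out sim

# genotyping + protein consequences
cdekit genotype --ref cds.fa --alleles sim.alleles.fa --out calls
cdekit genotype --ref cds.fa --alleles alleles.fa --dna-only --out calls

# regenerate the worked examples end to end
cdekit demo --out demo-out --seed 1
```

Global flags: `--config defaults.yaml` (YAML of option defaults, overridden
by explicit flags), `--log-level`. Exit codes: 0 success, 1 data error,
2 usage error. Outputs are plain TSV/JSON/FASTA and byte-stable for fixed
inputs and seed.

## Conventions

- Internal coordinates are 0-based half-open; all files and labels use
  1-based inclusive positions.
- SpCas9 blunt cut between protospacer positions 17|18 (3 nt 5' of the PAM).
- Alignment scoring: match +2, mismatch -3, gap open -10, gap extend -1;
  a gap of length L costs `open + L * extend`.
- Indels are normalized to their 3'-most equivalent placement, so a
  one-residue deletion inside a repeat run is reported at the highest
  residue number (e.g. `K1050del` from an AAG-AAG run).
- Frameshift alleles are reported as `<aa><pos>fs` with the downstream
  peptide in metadata and flagged as knockout candidates.

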