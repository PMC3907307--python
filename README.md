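# foldback

Simulation and breakpoint-junction analysis of **fold-back inverted
duplications** — the rearrangements that pair a terminal chromosome deletion
with an adjacent inverted duplication.

## The mechanism and what this package does

When a chromosome loses its terminal segment, the broken end can be healed
several ways. One of them leaves a characteristic scar: 5'→3' resection
exposes a single-stranded 3' overhang, which folds back and anneals
intrastrand at a short **inverted microhomology** a few hundred bases to a
few tens of kilobases more proximal. After fill-in and replication this
yields a **dicentric** chromosome that breaks during a
breakage-fusion-bridge cycle, producing a monocentric derivative with three
diagnostic features in reference coordinates:

- a **duplication** `[p, d)` present in two copies (one inverted),
- a short single-copy **disomic spacer** `[d, e)` — the fold-back loop,
- a **terminal deletion** `[e, L)`.

The new free end is stabilized by telomere healing (`(TTAGGG)n` addition),
by capture of another chromosome's terminus (translocation), or by ring
formation, each leaving a distinct second junction.

The package provides:

- `foldback.sequence` — microhomology operators, telomere-repeat detection,
  FASTA I/O;
- `foldback.genome` — deterministic synthetic reference genomes with
  telomere caps, centromeres, diverged repeat pairs, and a circular
  mitochondrial-like donor;
- `foldback.simulate` — the mechanistic simulator: fold-back event →
  dicentric → break → resolved derivative, with truth records, junction
  amplicons, paired-end reads and array-CGH profiles;
- `foldback.analyze` — the reverse direction: split alignment of junction
  amplicons, junction classification, microhomology/insertion/spacer
  measurement, CGH segmentation, discordant-pair clustering, and
  microsatellite parent-of-origin inference;
- `foldback.nullmodel` — the inverted-microhomology enrichment test: a
  simulated spacer null and a combinatorial empirical p-value
  `C(c, m) / C(n, m)`, plus a packaged cohort table of sequenced junctions.

## Worked example

Simulate a 2-Mb chromosome, plant a fold-back event with a 2,047-bp spacer
and 4-bp junction microhomology, and recover it with the analyzer:

```sh
$ foldback simulate-genome --chrom chr18:2000000 --seed 42 --out-dir demo/genome
wrote 1 chromosome(s) to demo/genome

$ foldback simulate-rearrangement --genome-dir demo/genome --chrom chr18 \
    --deletion 300000 --duplication 900000 --spacer 2047 --mh 4 \
    --seed 42 --out-dir demo/run
spacer=2047 mh=4 deletion=300000 duplication=900000

$ foldback analyze-junctions --genome-dir demo/run \
    --amplicons demo/run/amplicons.fa --truth demo/run/truth.json \
    --out-dir demo/run
{"n_calls": 2, "n_disomy_inversion": 1, "e_exact": true, "d_exact": true, "spacer_exact": true, "mh_exact": true}

$ cat demo/run/junction_calls.tsv
amplicon	junction_type	chrom_forward	chrom_reverse	e	d	spacer_size	mh_len	...
junction_0_disomy_inversion	disomy_inversion	chr18	chr18	1700000	1697953	2047	4
junction_1_inversion_telomere_truncated	inversion_telomere	chr18		797953		0
```

The same pipeline is available as a Python API:

```python
from foldback import (generate_reference, design_foldback_event, form_dicentric,
                      break_dicentric, resolve_derivative, emit_amplicon,
                      SeedIndex, split_align, call_junction)
from foldback.simulate import RearrangementTruth

g = generate_reference({"chr18": 2_000_000}, seed=42)
g, event, p = design_foldback_event(g, "chr18", deletion=300_000,
                                    duplication=900_000, spacer=2_047, mh=4)
invdup, sibling = break_dicentric(g, form_dicentric(g, event), p)
truth = RearrangementTruth(event, p, "telomere", g.length("chr18"))
derivative, truth = resolve_derivative(g, invdup, truth, "telomere")
amplicon, _ = emit_amplicon(g, derivative, truth.junctions[0])
call = call_junction(split_align(amplicon, SeedIndex(g)), g)
assert call.spacer_size == 2_047 and call.mh_len == 4
```

Other subcommands: `foldback cgh` (segment a log2-ratio profile and call the
spacer), `foldback null-test` (microhomology enrichment against a simulated
null), `foldback cohort-stats` (summary of the packaged junction cohort),
`foldback report` (aggregate a run directory). All randomness flows from a
single `--seed`; every run directory gets a `manifest.json` with SHA-256
digests of its outputs.

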