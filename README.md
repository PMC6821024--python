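# dmnlkit

Gene-rearrangement analysis of bothid flatfish mitochondrial genomes
under the **Dimer-Mitogenome and Non-Random Loss (DMNL)** model.

Most vertebrate mitogenomes share one conserved 37-gene order. The
lefteye flounders (Bothidae) instead show genomic-scale rearrangement:
the nine light-strand genes regroup into a contiguous 8-gene cluster
(Q-A-C-Y-S1-ND6-E-P) that notably *excludes* tRNA-N, and the control
region(s) and tRNA-D occupy type-specific positions. `dmnlkit` models
the mechanism that explains this in one step:

1. two monomer genomes fuse head-to-tail into a **dimer** (74 genes,
   two control regions);
2. transcription runs from the four promoters (HSP/LSP in each CR);
   H-strand transcripts stop at the next CR's TAS, L-strand
   transcripts at the first tRNA-L1;
3. one CR's promoter pair **loses function**, so the genes only it
   transcribed are silenced;
4. every silenced gene **degenerates** to a short intergenic spacer
   (or disappears), leaving a rearranged 37-gene monomer;
5. exception: the tRNA-N copy adjacent to the surviving COI is
   retained instead of the transcription-expected copy, because the
   light-strand replication origin (O~L~) must refold at that spot.

The package simulates this process, classifies observed gene orders
into the four rearrangement types, decides by parsimony whether the
tRNA-D translocation happened before or after the loss step, traces
every intergenic spacer back to the gene it degenerated from, and
generates fully annotated synthetic genomes (with planted O~L~
hairpins, TAS cores and control-region tandem repeats) whose recorded
ground truth makes every detector testable.

## Worked example

Simulate the Type III variant and check it against a real species
order, all from Python:

```python
>>> from dmnlkit import (canonical_teleost_order, bothid_fixture,
...                      config_for_type, run_dmnl, arrangements_equal)
>>> res = run_dmnl(canonical_teleost_order(), config_for_type("III"))
>>> len(res.final.genes())
37
>>> arrangements_equal(res.final, bothid_fixture("G.p"))
True
```

The same from the command line:

```console
$ dmnlkit classify --fixtures | head -5
species	type	d_inside_cluster	cr_count	v_shuffled	l_cluster
C.az	I	False	1	False	D-Q-A-C-Y-S1-ND6-E-P
C.ko	I	False	1	False	D-Q-A-C-Y-S1-ND6-E-P
C.va	I	False	1	False	D-Q-A-C-Y-S1-ND6-E-P
B.my	II	True	1	False	Q-A-C-Y-S1-D-ND6-E-P

$ dmnlkit parsimony --all-fixtures | tail -4
L.l	III	1	2	after
P.i	III	1	2	after
B.pa	IV	1	2	after
A.in	IV	1	2	after

$ dmnlkit generate --arrangement G.p --seed 7 --out-prefix gp
$ dmnlkit find-ol gp.fasta --gff gp.gff3
field	value
mode	spacer_plus_trnaN_3prime
start	5158
end	5178
stem_bp	8
loop_nt	4
mismatches	0
gu_pairs	0
trnaN_bases_used	4
motif5	GGTGG
motif3	TAGA
structure	((((((((....))))))))
```

Subcommands: `simulate`, `classify`, `parsimony`, `trace`, `find-ol`,
`scan-cr`, `generate`. All stochastic commands require `--seed`;
machine output goes to stdout or `--out`, diagnostics to stderr.

## Package layout

| module | contents |
|--------|----------|
| `dmnlkit.model` | `GeneFeature`, `GenomeArrangement`, canonical order, the 13 species fixtures, rotation-invariant equality, tabular I/O |
| `dmnlkit.dmnl` | dimerization, promoters/transcription units, non-random loss, `run_dmnl`, variant configs + config-file I/O |
| `dmnlkit.rearrange` | `translocate`, `shuffle_v`, before/after scenario search, parsimony verdicts |
| `dmnlkit.classify` | Type I–IV classifier and cohort tables |
| `dmnlkit.spacers` | spacer-locus prediction, observed-gap matching, unique-spacer census |
| `dmnlkit.seqfeatures` | O~L~ hairpin search and mode cascade, flank motifs, TAS scan, tandem-repeat finder |
| `dmnlkit.synth` | seeded synthetic genomes, sequence-level DMNL degeneration, ground-truth records |
| `dmnlkit.genbank` | optional GenBank feature-table reader (synonym table) |
| `dmnlkit.cli` | the `dmnlkit` command |

See `docs/methods.md` for the scientific model, parameter defaults and
numerical choices.
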