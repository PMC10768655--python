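# domrep — protein domain repertoire evolution on phylogenies

`domrep` traces how a genome's repertoire of protein domain families —
which families it encodes, and in how many copies — changes along a rooted,
time-calibrated species tree. It was built around a concrete question in
molecular immunology: the history of the calcium homeostasis modulator
channel CALHM6, whose single Pfam domain `Ca_hom_mod` shows a striking mix
of losses and duplications across eukaryotes. The machinery is generic,
though: it applies to any domain family and any set of genomes.

The pipeline has five stages, each usable on its own:

1. **ORF extraction** (`genome_orf`) — all ATG-initiated, stop-terminated
   open reading frames in all six reading frames of a genomic FASTA,
   translated with the standard genetic code.
2. **Domain annotation** (`domain_annotation`) — parse HMMER3
   `--domtblout` tables (from `hmmscan` against Pfam-A), keep hits whose
   full-sequence E-value and per-domain conditional E-value (c-Evalue) are
   both ≤ 10⁻³, and count kept hits per family into a per-organism
   *domain repertoire*.
3. **Count matrix** (`repertoire_matrix`) — assemble repertoires into a
   taxa × domain matrix of non-negative copy counts, the character data.
4. **Ancestral reconstruction** (`phylo_parsimony`) — Wagner (linear)
   parsimony: copy counts are additive characters and a change from *i* to
   *j* on a branch costs |i − j|. Minimum-cost ancestral counts come from
   the Farris-interval down-pass (binary trees) or an equivalent
   Sankoff-style dynamic programme (any multifurcating tree), with a
   documented tie-break among equally parsimonious reconstructions.
5. **Event calling** (`event_calling`) — branch-wise decomposition of
   count changes into **gain** (appearance from zero), **duplication**
   (extra copy of an existing family), and **loss** (one unit decrement
   each), with totals and an iTOL `DATASET_SYMBOL` export for drawing the
   events as colored boxes along the tree.

A sixth module, `synthetic_data`, generates Yule trees, evolving
repertoires with a replayable ground-truth event log, genomes with planted
ORFs, and domtblout fixtures, so the whole pipeline is testable offline.

## Worked example: CALHM6 / Ca_hom_mod

The package ships the published 20-taxon Ca_hom_mod event log as a worked
example (`domrep.examples`). Summarizing it:

```python
>>> from domrep.examples import calhm6_event_log
>>> from domrep.event_calling import summarize_events, classify_branch
>>> s = summarize_events(calhm6_event_log())
>>> print(f"{s.gains} gain, {s.duplications} duplications, {s.losses} losses")
1 gain, 6 duplications, 14 losses
```

Branch-level classification from reconstructed ancestral counts: the
branch whose ancestor carried 1 copy and whose descendant carries 4 is one
gain-free triple duplication, and the branch into Atlantic salmon
(ancestor 4, descendant 0) is four unit losses:

```python
>>> classify_branch(1, 4), classify_branch(4, 0)
((0, 3, 0), (0, 0, 4))
```

(Triples are `(gains, duplications, losses)`.)

## End-to-end on synthetic data

```bash
domrep simulate --leaves 6 --seed 42 --out-dir demo
domrep run --config demo.yaml     # domtblout list + tree.nwk + out_dir
```

prints the per-stage counts:

```json
{
  "hits_kept": 168,
  "hits_dropped": 30,
  "matrix_shape": [6, 12],
  "asr_total_cost": 33,
  "events": {"gains": 2, "duplications": 21, "losses": 10, "total": 33}
}
```

168 of 198 simulated hits pass the double 10⁻³ E-value filter (the 30
planted decoys fail it), giving a 6 × 12 count matrix; linear parsimony
needs 33 unit changes over the tree, and every unit change is exactly one
called event — gains + duplications + losses always equals the total
parsimony cost. `demo_out/` then contains the matrix, the ancestral-state
report, the per-branch events TSV, an iTOL annotation file, and a
`manifest.json` with a checksum per output (two runs of the same config
are byte-identical).

Subcommands `orfs`, `annotate`, `matrix`, `asr`, `events`, `itol` expose
the individual stages; `hmmscan` and tree inference are never invoked by
default — their outputs (domtblout text, newick) are consumed as inputs
(`--run-hmmscan` is available as an opt-in passthrough).

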