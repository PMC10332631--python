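# lipomap

Comparative genomics of lipoate assembly systems in bacteria and
archaea: per-genome annotation of lipoate-pathway enzymes from
profile-HMM hits, genomic-context classification of ligase subtypes,
pathway-system calling, taxon-normalized co-occurrence statistics, and
construction of phylogenetic sequence datasets — with a synthetic-genome
generator so the whole pipeline is testable without downloads.

## The problem

Lipoic acid is built on its acceptor proteins, not free in solution.
Two routes exist: transfer of ACP-bound octanoate by an
octanoyltransferase (LipB or LipM) followed by sulfur insertion by the
lipoyl synthase LipA, or ligation of free octanoate/lipoate by an
ATP-dependent lipoate:protein ligase (Lpl) followed by LipA — or by the
two-subunit synthase pair LipS1/LipS2 that works with the
oxidoreductase LipT and marks a distinct, sulfur-oxidizer-associated
pathway. Profile HMMs detect the catalytic ligase domain reliably but
cannot tell the subtypes apart (fused Lpl(AB), circularly permuted
Lpl(BA), bipartite LplA+LplB, or the sLpl(AB) form); the distinguishing
evidence is **genomic context**: domain architecture, gene
neighborhood, and which synthase the genome carries. `lipomap`
implements exactly that decision logic:

* `annotate` — one label per protein by the best hit at or above each
  model's trusted cutoff; PF10437 accessory-domain screening resolves
  fused vs permuted vs single-domain ligases.
* `context` — strand-aware gene clusters with canonical arrangement
  strings (`lipS1-lpl(AB)-lipT-lipS2`), synteny queries.
* `profiles` — presence/absence profiles, ligase subtype calls,
  pathway-system calls (LipB/LipA, LipM/LipA, Lpl/LipA, sLpl/LipS1S2,
  LipM/LipS1S2, scavenging-only).
* `stats` — Venn-region counts, conditional co-occurrence percentages,
  per-phylum tables normalized to phylum size.
* `phyloprep` — ligase/transferase and LipS1/S2 datasets: syntenic
  LplA+LplB concatenation, circular-permutation normalization,
  single-copy LipS1+LipS2 concatenation, greedy similarity clustering,
  outgroup rooting sets (BirA, BioB), and command manifests for the
  external align/trim/tree steps.
* `simulate` — synthetic genomes with planted pathway types,
  arrangements, architectures, noise, and a ground-truth manifest.
* `pipeline` / `lipomap` CLI — end-to-end runs with reproducible,
  checksummed outputs.

## Worked example

```sh
lipomap simulate --seed 7 --out runs/sim
cat > runs/config.json <<EOF
{"faa": "runs/sim/proteins.faa", "domtbl": "runs/sim/hits.domtbl",
 "gff": "runs/sim/genes.gff3", "taxonomy": "runs/sim/taxonomy.tsv",
 "out_dir": "runs/out", "catalog": null, "max_gap": 3,
 "identity_threshold": 0.7, "seed": 7, "syntenic_whitelist": [],
 "tool_config": {}}
EOF
lipomap run-all --config runs/config.json
```

prints

```
wrote 150 genomes to runs/sim
pipeline outputs in runs/out
```

and `runs/out/` then contains `annotations.tsv` (per-protein labels and
architecture flags), `clusters.tsv` (arrangements such as
`lipS1-lpl(AB)-lipT-lipS2`), `profiles.tsv` (the presence/absence
matrix), `pathway_calls.tsv`, `ligase_calls.tsv`, per-domain
`venn_*.tsv` and `phylum_*.tsv`, `cooccurrence.json`, and
`datasets/*.faa` with per-record manifests and ready-to-run
`*.commands.sh` for MAFFT / BMGE / IQ-TREE. For the simulated bacteria,
`cooccurrence.json` reports, e.g.:

```json
"Bacteria": {
  "lipT_given_lipS1S2": 71.4,
  "lpl_and_lipA_pct": 14.0,
  "n_genomes": 100,
  ...
}
```

meaning 71.4 % of the simulated LipS1/S2-containing bacteria also
encode LipT, and 14 % of all simulated bacterial genomes carry the
Lpl + LipA combination — percentages computed per domain, never pooled.

Real data enters through the same interfaces: protein FASTA + HMMER
`--domtblout` tables (or a pyhmmer live search), GFF3 gene coordinates,
and a GTDB-style metadata TSV; published presence/absence spreadsheets
load via `stats.load_presence_absence_table` with a column map.

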