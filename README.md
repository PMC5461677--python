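# mummyweb

Forensic DNA profiling of psyllid–parasitoid food webs: a reusable pipeline
for

* **seqdiv** — aligned-FASTA I/O, percent p-distances (pairwise deletion of
  gaps/Ns) and between-population divergence matrices;
* **delimit** — putative species delimitation by single-linkage divergence
  thresholding, grouping of sex-separated morphotypes into morphospecies by
  genotype matching, and thelytoky flagging;
* **primers** — design of morphospecies-specific primer pairs (≥2 diagnostic
  sites in each 3′ pentamer, 145–400 bp amplicons, matched Wallace-rule Tm),
  minimal multiplex staging, and in-silico single/multiplex PCR;
* **trophic** — informative-mummy filtering, detection-success tables, and
  trophic-role classification (primary / hyperparasitoid / heteronomous
  hyperparasitoid) from post-emergence mummy DNA-detection patterns;
* **cophylo** — patristic distances, a global permutation congruence test on
  principal coordinates, a patristic-distance correlation test, and
  exhaustive event-based reconciliation (codivergence / duplication / loss /
  host switch) for small rooted trees;
* **synth** — seeded generators: Yule host trees, host-tracking parasite
  evolution with losses and host switches, Jukes–Cantor sequences, and mummy
  tables with species-specific detection probabilities;
* **data** — a bundled eight-host survey dataset (emergence counts,
  between-population cytb divergences, multiplex-PCR mummy screen).

## Command line

```bash
mummyweb simulate --seed 5 --outdir fixture/          # synthetic system
mummyweb distances --fasta fixture/P1_cytb.fasta --out D.csv
mummyweb delimit --matrix D.csv --threshold 5.0 --name P1 --out partition.csv
mummyweb trophic --mummies fixture/mummies.csv --out roles.csv
mummyweb cophylo --host-tree fixture/host.nwk \
    --parasite-tree fixture/P1_parasite.nwk --assoc fixture/P1_assoc.csv \
    --n-perm 9999 --seed 0 --out cophylo.json
mummyweb run --config pipeline.yaml --outdir out/     # full pipeline
```

`run` consumes a YAML config (keys: `seed`, `alignments`, `delimit`,
`mummies`, `trophic`, `cophylo`, optional `primers`) and writes CSV/JSON
artifacts plus a machine-readable `summary.json` stamping the package
version, config hash and seed.  Identical config + seed reruns are
byte-identical.

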