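# fusionbreak

Desk-scale toolkit for analyzing t(1;19)(q23;p13) / TCF3::PBX1 chromosomal
breakpoints in acute lymphoblastic leukemia: breakpoint-catalog statistics,
cluster analysis, annotation-track overlap, in-silico long range-inverse PCR
(LRI-PCR) and multiplex long-range PCR simulation, fusion-junction
characterization (microhomology / non-template insertions / inversions /
foreign inserts), breakpoint-specific qPCR design and standard-curve
quantification, and a synthetic fusion-genome generator with truth tables
for end-to-end round-trip validation.

## Package layout

| module | contents |
| --- | --- |
| `fusionbreak.catalog` | breakpoint catalog loading/validation, intron/genomic coordinate conversion, cohort summaries, BED export |
| `fusionbreak.clusters` | maximum-coverage sliding window, fixed-region membership counts, gap-based clustering, half-away-from-zero percentages |
| `fusionbreak.annotation` | interval-track overlap with symmetric or asymmetric vicinity margins, merged track coverage |
| `fusionbreak.assay` | restriction enzymes, in-silico digestion (linear/circular), enzyme screening, inverse-PCR and multiplex product prediction, per-junction detectability |
| `fusionbreak.junctions` | junction calls from derivative + parental references (microhomology, insert classification) |
| `fusionbreak.qpcr` | standard-curve fitting, efficiency from slope, successive delta-Ct, patient-specific reverse-primer design, melting temperatures |
| `fusionbreak.simulate` | random references, breakpoint/junction mixture models, single-event and cohort simulation with truth tables |
| `fusionbreak.pipeline` / `fusionbreak.cli` | validated YAML run configs and the `fusionbreak` command-line entry point |

A 49-patient breakpoint catalog (129 break events), the LRI-PCR/multiplex/
qPCR oligonucleotide set, the restriction-enzyme definitions and the
published per-patient standard-curve statistics ship as plain-text fixtures
under `src/fusionbreak/data/`.

## Command line

```bash
fusionbreak catalog-stats                     # cohort summary JSON
fusionbreak clusters --gene TCF3 --width 40   # 40-bp hotspot scan
fusionbreak clusters --gene PBX1 --regions '[{"start":220000,"end":229182,"label":"c1"},{"start":119000,"end":155100,"label":"c2"}]'
fusionbreak overlap --track repeats.tsv --gene PBX1 --vicinity 30
fusionbreak assay-screen --fasta region.fa --region-start 500 --region-end 1000
fusionbreak insilico-pcr --fasta region.fa --enzyme BamHI --forward TCF3-F2 --reverse TCF3-R4
fusionbreak multiplex --fasta der19.fa --junction 123456 --panel panel2
fusionbreak junction-call --der ders.fa --donor tcf3.fa --acceptor pbx1.fa
fusionbreak qpcr-curve --csv cts.csv
fusionbreak design-qpcr --fusion fusion.fa --junction 1180 --donor tcf3.fa --acceptor pbx1.fa
fusionbreak simulate --n 100 --seed 7 --out sim/
fusionbreak run --config config.yaml --stages catalog,clusters
```

## Tests

```bash
python -m pytest -q
```

One acceptance test (`TestCriterion5ControlBand`) validates the predicted
BamHI TCF3-F2/TCF3-R4 control band (3308 bp) against the real GRCh38 TCF3
region. That reference cannot be bundled; fetch it once with network access:

```bash
python scripts/fetch_reference.py   # writes src/fusionbreak/data/external/grch38_tcf3_region.fa
```

Without the reference the test fails with instructions, and the acceptance
report omits target `t11`. Everything else runs fully offline.

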