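# memtopo

Census analysis of membrane-protein topology for proteomes made at the
endoplasmic reticulum.

Integral membrane proteins are described here by their topology: the ordered
transmembrane domains (TMDs), the membrane side faced by the N terminus
(N<sub>cyt</sub> = cytosolic "inside", N<sub>exo</sub> = exoplasmic
"outside"), and the loops and tails in between, whose sides alternate with
every membrane crossing. From a curated topology table — one row per protein
with sequence, signal-peptide and TMD coordinates, and orientation — this
package:

- deduces loop/tail coordinates and membrane sides (`deduce_segments`,
  `assign_locations`), validating every record;
- scores TMD hydrophobicity with the position-dependent **biological
  hydrophobicity scale**: the apparent free energy of translocon-mediated
  membrane insertion, ΔG<sub>app</sub> (kcal/mol), with minimal-ΔG window
  scanning for long segments (`dg_app`, `dg_scan`);
- classifies each protein into the single-pass Types I–IV or the multipass
  classes, each signal anchor (SA) into N<sub>exo</sub>, N<sub>cyt</sub>-long
  or N<sub>cyt</sub>-pair, detects **TMD pairs** (two TMDs separated by a
  ≤50 aa exoplasmic loop), and labels every TMD with one of six core
  membrane-insertion reactions (Sec61-dependent R1/R2/R5 vs insertase-mediated
  R3/R4/R6);
- computes **positive-inside rule** charge statistics: five-zone TMD
  partitions (20/15/30/15/20% of length), charge depth maps, net flanking
  charges over 5/10/15-aa windows, and pair-level charge biases;
- aggregates the proteome-wide census (class counts, length/ΔG
  distributions, amino-acid frequencies, N-glycosylation sequon census) into
  a deterministic JSON report;
- ships a **synthetic-proteome generator** that emulates the census'
  statistical structure with full truth bookkeeping, so the entire pipeline
  is testable without any external download.

## Worked example

```python
>>> import memtopo as mt
>>> mt.dg_app("L" * 19)                      # 19-mer poly-leucine
-7.496562...
>>> res = mt.dg_scan("S"*30 + "L"*19 + "S"*30)   # minimal-ΔG window, 19-23 aa
>>> res.window_start, res.window_end, round(res.dg_app, 3)
(31, 49, -7.497)
```

A synthetic census end to end:

```python
>>> config = mt.default_config(n_proteins=300, seed=11)
>>> proteome = mt.generate_proteome(config)
>>> summary = mt.census_report(proteome.table)
>>> summary.class_counts
{'SP-I': 73, 'SP-II': 30, 'SP-III': 14, 'SP-IV': 13, 'MP-SS': 15,
 'MP-Nexo': 65, 'MP-Ncyt': 90, 'single_pass': 130, 'multipass': 170}
>>> summary.pair_counts["total"], round(summary.pair_bias["loop_length"]["mean"], 1)
(462, 12.6)
>>> rep = mt.recovery_check(proteome)
>>> rep.class_agreement, rep.pair_agreement
(1.0, 1.0)
```

The class counts split ~46/54 between single-pass and multipass proteins;
TMD pairs dominate the multipass records with exoplasmic pair loops of
~13 aa on average, and every generated record's topology class and pair list
is recovered exactly by the classifier.

The same pipeline is available from the shell:

```bash
memtopo simulate --n 5000 --seed 7 --out census.csv --truth truth.json
memtopo classify --table census.csv --out labels.csv
memtopo charges  --table census.csv --windows 5,10,15 --out charges.csv
memtopo report   --table census.csv --out report.json
memtopo dg --fasta proteins.fa --min-len 19 --max-len 23
```

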