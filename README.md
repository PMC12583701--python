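# splicetime

Timing analysis of developmental alternative splicing. `splicetime` asks
*when* each cassette exon switches its inclusion preference during neuronal
maturation, and how a perturbation (e.g. an RNA-binding-protein or
splicing-regulator knockdown) shifts that moment — rather than only asking
whether inclusion levels differ. It is aimed at transcriptomics analysts
working with rMATS-style skipped-exon output from time-course RNA-seq of
developing neurons (or any staged system with an inclusion switch).

## The method

For each cassette exon and condition, replicate junction counts give a
length-normalised percent-spliced-in value per timepoint,

    PSI = (I/lI) / (I/lI + S/lS),

averaged over replicates with at least `min_total_reads` junction reads.
The trajectory is z-scored into the **relative inclusion rate**

    z_t = (PSI_t − PSI_μ) / PSI_σ ,

where PSI_μ and PSI_σ are the trajectory's own mean and (population) SD.
The **switching time** is the first timepoint at which the sign of z
reverses relative to the last non-zero sign before it; values inside a
small tolerance band around zero inherit the preceding sign so that a
trajectory passing through its mean does not register a double reversal.

Comparing the control and perturbed calls per exon yields four categories:

| category   | meaning                                                        |
|------------|----------------------------------------------------------------|
| Early      | perturbed switch precedes the control switch                   |
| Late       | perturbed switch follows it, or never arrives in the window    |
| Reversed   | both switch, in opposite directions                            |
| Unaffected | neither switches, or same index and direction                  |

Exons whose switch timing is altered (Early + Late + Reversed) are then
tested for RNA-binding-protein (RBP) cis-element enrichment: each exon body
plus up to 200 nt of each adjacent intron (transcript-sense) is scanned for
the IUPAC consensus elements of 46 RBPs with public eCLIP-derived motif
classes, and per-RBP presence is compared between affected and Unaffected
exons with a two-sided Fisher's exact test and Benjamini–Hochberg FDR
correction. Candidates are refined by cross-referencing an IP-MS
interactome, itself defined by an abundance-ratio filter (kept when
blocked+stimulated / stimulated ≤ 0.78). A companion module quantifies
mutually exclusive exon usage (Snap25 exon 5a/5b archetype) from isoform
counts and RT-qPCR Ct values via 2^−ΔΔCt.

A fully ground-truthed synthetic-data generator (logistic switch
trajectories, Poisson–Binomial junction counts, scrub-and-plant motif
sequences) makes every stage testable without any external download.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_run_pipeline.py
```

simulates the default study (300 exons, timepoints DIV0/DIV3/DIV5/DIV10,
3 replicates, ~100 junction reads per event; 30 Early / 100 Late /
35 Reversed / 135 Unaffected planted) and runs the full pipeline over it.
The second command prints

```
category counts: {'total': 300, 'included': 300, 'excluded': 0,
                  'Early': 34, 'Late': 91, 'Reversed': 40,
                  'Unaffected': 135, 'altered': 165}
refined RBP candidates (q<=0.05 and in IP-MS interactome): ['RBFOX2', 'U2AF2']
```

Under count noise a handful of planted Late exons whose delayed switch sits
near the window edge are read as Early/Reversed (93% of planted
non-Unaffected exons recover their category; the noise-free limit recovers
100%, see `analysis/03_recovery_check.py`). The two refined candidates are
exactly the RBPs whose motifs were planted at 0.6 vs 0.1 presence *and*
which appear in the interactome list — the third planted RBP (CELF1) is
significant but correctly dropped by the interactome cross-reference.

The same stages are available as a CLI (`splicetime simulate|psi|switch|
enrich|run|report`) driven by a YAML config; `analysis/04–06` demonstrate
the interactome filter, the mutually-exclusive-exon/2^−ΔΔCt module and the
calibration/power simulations of the enrichment stage.

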