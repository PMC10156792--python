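# pdcore

Quantitative analysis of the icosahedral pyruvate dehydrogenase (PDC)
E2 core and its E3-binding protein (E3BP), for structural biologists
working on 2-oxoacid dehydrogenase assemblies: occupancy counting of
E3BP core-binding-domain (CBD) trimers inside the core via point-group
symmetry expansion, an exact steric model of how many trimers fit, a
reach analysis of the disordered M3-containing loop, and sequence-level
discrimination of E3BP from its catalytically active paralog E2.

## The model in brief

The E2 core is a 60-mer with icosahedral symmetry; its 20 CTD trimers
sit on dodecahedral vertex directions, each a 3-fold axis. Symmetry
expansion replaces every particle orientation A by the 60 composed
orientations A·G (G over the icosahedral group), so each physical
3-fold site appears in exactly |stabilizer| = 3 expanded sub-particles.
A core with k bound CBD trimers and perfect detection therefore shows
d = 3k occupied regions out of 60, and detection counts are binned back
to trimer numbers by

    t = floor((d + 1) / 3)        # {3t-1, 3t, 3t+1} -> t

so d = 8, 9 or 10 all signify t = 3 trimers. Geometrically, a bound
trimer excludes neighbouring sites; with an angular exclusion of 71°
(just above the 70.53° next-neighbour separation) the exact maximum
packing is 4 trimers — the tetrahedral vertex quadruples — capping
E3BP at 4 × 3 = 12 monomers, versus 30 (one per dimeric interface) or
15 (two interfaces per monomer) for non-trimerizing architectures. The
M3 motif, flanked by 12 and 25 loop residues at 3.4 Å per extended
residue, has a limiting reach of 12 × 3.4 = 40.8 Å — short of the
45–50 Å to the nearest unoccupied interfaces. On the sequence side,
E3BP is flagged by loss of the catalytic triad His and by conserved
PSBD motifs ('EKG' marks E2; the Asp–Leu–hydrophobic and 'GxI' helix-2
motifs mark E3BP), combined into a four-criteria classifier.

## Worked example

Simulate 1000 cores under the default study-like scenario (trimer
counts concentrated at 3–4, detection noise p = 0.01 / q = 0.05), count
detections and summarize:

```sh
$ pdcore simulate cores --n 1000 --seed 7 --out det.csv
simulated 1000 cores (seed 7) -> det.csv
$ pdcore summarize --in det.csv --ge 1 --ge 5 --out summary.json
note: 21 core(s) binned above the plausibility ceiling of 4 trimers; attributed to false-positive identification, retained in all histograms
summarized 1000 cores -> summary.json
```

`summary.json` then contains (abridged):

```json
{
  "trimer_histogram": {"0": 48, "1": 98, "2": 218, "3": 348, "4": 267, "5": 21},
  "percent_at_least": {"1": 95.0, "5": 2.0}
}
```

The majority of cores are assigned 3–4 trimers; the 21 cores binned at
5 exceed the steric ceiling of 4 and are annotated as probable false
positives of the detection noise, not dropped. The steric and reach
analyses print their closed-form results directly:

```sh
$ pdcore placement
maximum 4 trimers at 71.0 deg exclusion (10 optimal site subsets)
$ pdcore capacity --mode trimer_steric
trimer_steric: capacity 12 E3BP monomers
$ pdcore reach
upstream reach 40.8 A, downstream 85.0 A; limiting 40.8 A vs target >= 45.0 A -> requires_unfolding (margin -4.2 A)
```

i.e. at most 4 CBD trimers (12 E3BP copies) fit the core interior, and
the M3 motif falls 4.2 Å short of the nearest unoccupied interface
unless the CBD partially unfolds. Sequence workflows
(`pdcore seqclass`, `pdcore logo`, `pdcore simulate seqs`) follow the
same pattern; every output gets a `.provenance.json` sidecar with the
configuration, seed and input digests.

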