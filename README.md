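# polyctx

Sequence-context analysis of poly-alanine (polyA) homorepeats in protein
sequences.

PolyA tracts are protein stretches composed exclusively (*pure*) or
predominantly (*impure*) of alanine.  They are abundant in eukaryotic
proteomes, intrinsically helix-prone, and pathogenic when expanded — yet what
they do depends strongly on the residues around them.  `polyctx` is a toolkit
for quantifying that sequence context proteome-wide:

* **Detection** — pure polyA as maximal runs of ≥ 4 alanines; impure polyA by
  a sliding-window search (≥ 4 alanines in a window of 6, qualifying windows
  unioned, merged spans trimmed to alanine termini, minimum final length 5).
  The target residue is a parameter, so any homorepeat (polyQ, polyL, …) can
  be scanned the same way.
* **Impurity statistics** — for the non-alanine residues inside impure
  regions: frequency per length class (5, 6, >6), enrichment ratio against
  the proteome background (freq<sub>impurity</sub> / freq<sub>Bg</sub>), and
  relative position within the region ((k − ½)/L for offset k in a region of
  length L).
* **Flank context** — per-position amino-acid composition of the −10…−1 and
  +1…+10 flanks, enrichment against background, and the marker summary
  (G+1, M−1, S±1, V±1, and the mean P / G enrichment across all 20 flank
  positions).
* **Position in the protein** — relative position (midpoint/L or start/L),
  stratification by subcellular location with pairwise Mann–Whitney U tests
  (exact null for small untied samples, tie-corrected normal approximation
  otherwise), and the transit-peptide table: proteins classed by the start of
  their most N-terminal repeat (2; 3–20; >20) against mTP/SP calls.
* **Structural propensity** — tripeptide-based secondary-structure profiles:
  a pluggable table maps each tripeptide to probabilities over 27 classes
  (triples over the α/β/γ regions of Ramachandran space); each residue
  averages the tripeptides centred at i−2…i+2 (weights 1,2,4,2,1,
  renormalised at ends) and is reduced to (ααα, βββ, Others); profiles are
  aggregated over repeats (position 0) and flanks (±1…±10).
* **Emergence** — given an alignment with an ortholog, the fraction of a
  repeat's columns that are gapped in the ortholog classifies it as having
  emerged by *insertion* (≥ 0.8 gapped), *substitution* (≤ 0.2), or *mixed*.
* **Synthetic proteomes** — a generator that plants regions, impurity
  compositions, flank biases and annotation couplings with known values and
  emits a ground-truth ledger, so every statistic above can be validated by
  planted-parameter recovery.

## Worked example

Generate a synthetic proteome under the package's study conditions (1000
proteins, 300 pure + 400 impure planted regions, proline-enriched impurities,
G planted at flank +1 with probability 0.4), then detect and profile:

```bash
polyctx simulate --seed 7 --out-dir demo/
polyctx detect --fasta demo/proteome.fasta --out demo/regions.tsv
```

```
purity length_class  regions  proteins
  pure            4      150       150
  pure           >4      150       150
  pure        total      300       300
impure            5      100       100
impure            6      100       100
impure           >6      200       200
impure        total      400       400
```

Detection recovers exactly the planted plan (150 pure regions of length 4,
150 longer; 100 impure of length 5, 100 of 6, 200 longer).  The flank
enrichment markers:

```bash
polyctx context --regions demo/regions.tsv --fasta demo/proteome.fasta --out demo/context.tsv
```

```
G+1	8.119
M-1	6.438
S-1	0.660
S+1	0.718
V-1	0.693
V+1	0.838
P	1.009
G	1.363
```

G+1 ≈ 8.1 is the planted +1 glycine bias (frequency 0.4 over a ≈ 0.05
background); M−1 ≈ 6.4 reflects the forced initial methionine of the 30% of
regions starting at position 2; the windowed P marker sits at ≈ 1 (no planted
proline bias in the flanks) and G ≈ 1.4 is the single +1 column averaged over
20 positions.  `polyctx impurities`, `polyctx position`, `polyctx propensity`
and `polyctx emergence` continue the chain; every command is a thin wrapper
over functions in `polyctx.*` that can be composed directly in Python.

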