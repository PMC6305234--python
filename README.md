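# demotif

Tooling for asking whether the local context of the diacidic **DE**
dipeptide — flanking charge, flanking hydrophobicity, structural order,
phosphorylatable insertions, LIR proximity and co-evolutionary coupling —
separates unconventionally secreted proteins from non-secreted ones.

The package provides:

- **core_model** — dataset schema (TSV table + FASTA sequences + optional
  FASTA-formatted 3-state structure strings), MSA readers (aligned FASTA /
  Stockholm) and motif-table I/O. Proteins without a DE dipeptide are
  excluded from the analysis set (counted, never silent).
- **motif_scan** — scanners for DE, the six phospho-context variants
  (XDE, DXE, DEX, XED, EXD, EDX with X ∈ {S,T,Y,H,R,K}), LIR motifs
  (core `[WFY]..[LIV]` and the extended 6-residue consensus), and
  DE–LIR contiguity.
- **context_features** — per-DE flanking hydrophobicity (Kyte–Doolittle,
  3 residues per side by default), flanking formal charge, and the
  ordered / disordered / border (O/D/B) classification.
- **hypothesis_engine** — the 16 "most relevant DE" selection rules
  (order preference × charge extreme × hydrophobicity extreme × border
  regrouping), per-case design matrices, and per-protein extreme
  features.
- **stats_inference** — hand-implemented IRLS logistic regression with
  Wald and likelihood-ratio p-values, odds ratios with Haldane–Anscombe
  correction, and Fisher's exact test.
- **coevolution** — per-sequence gap filtering (default max gap 0.2),
  consensus building, MSA binarization, pairwise coupling matrices
  (plain co-occurrence deviation or SCA-frequency-weighted) and
  per-position partner ranking.
- **synthetic_data** — seeded generators for labelled protein datasets
  (logistic labels planted on one signal DE) and MSAs with planted
  covarying column pairs, plus ground-truth reports.
- **pipeline / cli** — end-to-end orchestration with a-posteriori case
  ranking by model LRT p-value.

## CLI

```sh
# generate a synthetic labelled dataset with planted effects
demotif simulate proteins --config sim.yaml --seed 7 --out-dir sim/

# scan motifs / compute DE contexts
demotif scan --fasta sim/proteins.fasta --kinds de,phospho,lir --out hits.tsv
demotif features --fasta sim/proteins.fasta --ss sim/proteins.ss.fasta \
    --window 3 --out contexts.tsv

# 16 design matrices, full analysis, co-evolution
demotif hypotheses --contexts contexts.tsv --table sim/proteins.tsv --out-dir cases/
demotif run-all --table sim/proteins.tsv --fasta sim/proteins.fasta \
    --ss sim/proteins.ss.fasta --out-dir report/
demotif coevolve --msa family.afa --max-gap 0.2 --mode plain --out couplings.tsv
```

`run-all` writes `report.json`, `per_case_results.tsv` and
`extremes.tsv`; re-running on the same inputs reproduces them
byte-for-byte.

## Conventions

- Coordinates are 0-based half-open internally, 1-based inclusive in all
  emitted tables.
- Flanking windows exclude the D and E of the motif and truncate at the
  termini (recorded per motif); both behaviours are switchable.
- Histidine carries charge 0 by default (configurable).
- Unknown residues `X` are imputed neutral for both scales.
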