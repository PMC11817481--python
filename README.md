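# wdpscan

Proteome-scale screening and characterization of **wholly disordered
proteins (WDPs)** — proteins whose intrinsically disordered regions
cover essentially the whole chain, as opposed to the far better
studied proteins with only partial disordered regions. WDPs (LEA
proteins, dehydrins, SPIRAL1-like and similar families in plants) are
hydrophilic, charge-enriched, conformationally plastic, and prone to
liquid–liquid phase separation; finding and profiling them across a
proteome is the first step in studying them.

`wdpscan` is a library + CLI for bioinformaticians who have a
proteome FASTA and per-protein disorder evidence (UniProt-style
`Region: Disordered` intervals, or exported per-residue scores such as
AlphaFold pLDDT) and want, reproducibly:

1. **Screening** — a protein is called a WDP when it has ≥ 50 residues
   and its disordered regions cover ≥ 90% of its length (both
   boundaries inclusive; interval unions are never double-counted).
2. **Physicochemical profiling** — four classical sequence indices:
   theoretical isoelectric point (pI, Bjellqvist pKa set, bisection on
   the Henderson–Hasselbalch net charge), GRAVY (mean Kyte–Doolittle
   hydropathy; negative ⇒ hydrophilic), Guruprasad's instability
   index II = (10/N) Σᵢ DIWV(rᵢ, rᵢ₊₁) (II > 40 ⇒ predicted unstable),
   and the aliphatic index AI = X(A) + 2.9·X(V) + 3.9·(X(I)+X(L)).
3. **Diagram-of-states classification** — with f₊ = (K+R)/N,
   f₋ = (D+E)/N, FCR = f₊+f₋ and NCPR = |f₊−f₋|, each protein lands in
   one of the Das–Pappu conformational classes:
   R1 (FCR < 0.25, weak polyampholytes: globules/tadpoles),
   R2 (0.25 ≤ FCR ≤ 0.35, boundary sequences),
   R3 (FCR > 0.35, NCPR ≤ 0.35, strong polyampholytes: coils/hairpins),
   R4/R5 (FCR > 0.35, NCPR > 0.35, strong polyelectrolytes, split by
   net-charge sign). Boundary ties are resolved exactly (rational
   arithmetic, no float rounding at 7/20).
4. **Family grouping** — single-linkage clustering of a BLASTP
   tabular hit table (E ≤ 1e-4, top 20 hits per query): families are
   the connected components of the filtered hit graph.
5. **Comparison** — Welch *t* and two-sided Mann–Whitney *U* (exact
   enumeration for small tie-free groups) for every metric, WDP set
   vs a background set.

A seeded synthetic-proteome generator (`wdpscan simulate`) produces
FASTA + disorder tracks + hit tables with known ground truth, so the
whole pipeline is testable end to end without any database download.

## Worked example

```sh
wdpscan simulate --seed 7 -o demo/            # synthetic proteome, n=100
cat > demo/run.yaml <<EOF
proteome: demo/proteome.fasta
intervals: demo/disorder.tsv
hits: demo/hits.tsv
outdir: demo/out
EOF
wdpscan run --config demo/run.yaml
```

prints

```
WDPs: 10/100  regions: {'R1': 4, 'R2': 2, 'R3': 4, 'R4': 0, 'R5': 0}  families: 10
```

— the screen recovered the 10 planted disordered-like proteins out of
100 (the generator's default plants 10%), the diagram of states
spread them over the weak-polyampholyte (R1), boundary (R2) and
strong-polyampholyte (R3) classes with none in the polyelectrolyte
corner, and with no families planted every passer is a singleton.
`demo/out/` then holds one TSV per stage plus a `manifest.json` with
input/output checksums. The per-protein tables look like:

```
id      n    f_plus    f_minus   fcr      ncpr      region
SYN001  385  0.181818  0.254545  0.436364 0.0727273 R3
SYN002  259  0.0733591 0.127413  0.200772 0.0540541 R1

id      length  pi       gravy    ii       ai       stability_class
SYN001  385     4.78146  -2.4039  59.7782  9.37662  unstable
```

A strongly negative GRAVY and a low AI are the hydrophilic,
non-thermostable signature expected of disordered chains; II above 40
classes them as unstable in vivo.

Each stage is also individually addressable (`wdpscan screen`,
`physchem`, `charge`, `cluster`, `compare`); `wdpscan physchem
--show-constants` dumps the pinned constant tables (Kyte–Doolittle
scale, DIWV dipeptide weights, Ikai coefficients, Bjellqvist pKas).

For real data, `wdpscan.datasets` ships the 56 UniProt accessions of
the published Arabidopsis WDP set and a fetch helper
(`fetch_uniprot_fasta`, network required) to rebuild that FASTA and
reproduce its characterization.

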