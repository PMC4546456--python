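# Provenance of the bundled node registry

`registry.tsv` transcribes the published 24-row interventional-node table
(24 drug-actionable nodes for NSCLC, each defined by a set of member genes
and annotated with example drugs). The published table contains several
typographic irregularities; this file records every transcription decision
so the registry is auditable.

## Global rules

- Gene symbols are upper-cased (`mTor` → `MTOR`, `Kit` → `KIT`,
  `BAk` → `BAK`, `Adam17` → `ADAM17`, `FtAD52` → `FTAD52`).
- Symbols are otherwise transcribed **verbatim**, including tokens that are
  almost certainly misprints of standard HGNC symbols. They are kept because
  correcting them silently would make the registry impossible to audit
  against the printed table. Suspected misprints:
  `HUGE` (HER row; likely HBEGF), `COKN2A` (CDK4,6 row; likely CDKN2A),
  `CCNE3` (no such cyclin; printed as such), `P13X`-style drug strings,
  `TEPI` (likely TEP1), `HSP9OAA1` (letter O; likely HSP90AA1),
  `FZDS` (likely FZD5), `HDACS` (likely HDAC5), `FTAD52` (likely RAD52),
  `UB1` (Others row), `VEGFR1/2/3` (aliases of FLT1/KDR/FLT4).
- Duplicate symbols within one row are de-duplicated
  (the PI3K row prints `PRKCB` twice; kept once).

## Row-specific decisions

- **PLK/AURK**: printed `BORA ILK` (missing comma) split into the two genes
  `BORA` and `ILK`.
- **Immune modulator**: printed `PD1L` transcribed as `PDL1`, the spelling
  used everywhere else in the source (activation tables, prose).
- **FGF**: printed `FGF1 to FGF18` expanded to the 18 enumerated symbols
  FGF1 … FGF18.
- **Wnt**: printed `WNT5A, B` expanded to `WNT5A`, `WNT5B`.
- **Antiapoptosis drugs**: the printed drug string contains an internal
  semicolon ("Wee-1 inhibitor; p53"); rewritten with a comma because `;`
  is the field separator in this file.
- **Wnt drugs**: `PRI-274` kept as printed (likely PRI-724).

## Counts

The published table header claims 183 genes in total. A literal enumeration
of the transcription above yields **192 gene memberships** across the 24
nodes and **191 unique symbols** (BRCA1 belongs to both PARP and DNA
Repair). The printed total is not recoverable from the printed rows under
any obvious reading; the registry therefore documents its own count rather
than forcing the headline number.
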