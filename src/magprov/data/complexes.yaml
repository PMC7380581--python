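# Default complex catalog for presence/absence calling.
#
# Multi-subunit entries use the 75% detection rule (inclusive); single-gene
# entries require the gene itself (threshold 1.0, applied automatically when
# omitted). Categories drive column ordering and coloring of exports.
# Edit or replace freely; this file is configuration, not code.

synonyms:
  # acyl-CoA dehydrogenase alternates
  bcd: acd
  acox: acd
  fadE: acd
  # enoyl-CoA hydratase alternates
  crt: ech
  paaF: ech
  # 3-hydroxyacyl-CoA dehydrogenase alternates
  fadN: paaH
  fadJ: paaH
  # phosphate acetyltransferase
  pta: pka
  # acetyl-CoA C-acetyltransferase
  atoB: fadA

complexes:
  - name: mcr
    category: methanogenesis
    subunits: [mcrA, mcrB, mcrG]
  - name: mtr
    category: methanogenesis
    subunits: [mtrA, mtrB, mtrC, mtrD, mtrE, mtrF, mtrG, mtrH]
  - name: fwd
    category: methanogenesis
    subunits: [fwdA, fwdB, fwdD, fwdE, fwdF, fwdG]
  - name: ftr
    category: methanogenesis
    subunits: [ftr]
  - name: mch
    category: methanogenesis
    subunits: [mch]
  - name: mtd
    category: methanogenesis
    subunits: [mtd]
  - name: mer
    category: methanogenesis
    subunits: [mer]
  - name: fae
    category: methanogenesis
    subunits: [fae]
  - name: mta
    category: methanogenesis
    subunits: [mtaA, mtaB, mtaC]
  - name: mvh
    category: methanogenesis
    subunits: [mvhA, mvhD, mvhG]
  - name: hdr
    category: methanogenesis
    subunits: [hdrA, hdrB, hdrC]
  - name: frh
    category: methanogenesis
    subunits: [frhA, frhB, frhG]
  - name: fqo
    category: methanogenesis
    subunits: [fqoF, fqoB, fqoC, fqoD, fqoI]
  - name: eha
    category: methanogenesis
    subunits: [ehaA, ehaB, ehaC, ehaD]
  - name: ehb
    category: methanogenesis
    subunits: [ehbA, ehbB, ehbC, ehbD]
  - name: rnf
    category: methanogenesis
    subunits: [rnfA, rnfB, rnfC, rnfD, rnfE, rnfG]
  - name: sat
    category: sulfate
    subunits: [sat]
  - name: apr
    category: sulfate
    subunits: [aprA, aprB]
  - name: dsr
    category: sulfate
    subunits: [dsrA, dsrB]
  - name: qmo
    category: sulfate
    subunits: [qmoA, qmoB, qmoC]
  - name: dsrMKJOP
    category: sulfate
    subunits: [dsrM, dsrK, dsrJ, dsrO, dsrP]
  - name: nar
    category: nitrate
    subunits: [narG, narH, narI]
  - name: nap
    category: nitrate
    subunits: [napA, napB]
  - name: nir
    category: nitrate
    subunits: [nirK]
  - name: nor
    category: nitrate
    subunits: [norB, norC]
  - name: MHC
    category: iron
    subunits: [mhc]
  - name: fadD
    category: beta_oxidation
    subunits: [fadD]
  - name: acd
    category: beta_oxidation
    subunits: [acd]
  - name: ech
    category: beta_oxidation
    subunits: [ech]
  - name: paaH
    category: beta_oxidation
    subunits: [paaH]
  - name: fadA
    category: beta_oxidation
    subunits: [fadA]
  - name: acs
    category: other
    subunits: [acs]
  - name: pka
    category: other
    subunits: [pka]
  - name: ack
    category: other
    subunits: [ack]
  - name: cdh
    category: other
    subunits: [cdhA, cdhB, cdhC, cdhD, cdhE]
  - name: mnq
    category: biosynthesis
    subunits: [menA, menB, menD]
  - name: mpt
    category: biosynthesis
    subunits: [mptA, mptB]
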