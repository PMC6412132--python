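# Default word sets for the term-frequency table. Similar words are grouped
# into one set; a gene counts at most once per set no matter how many member
# words or features match.
word_sets:
  - {label: "peptide/polypeptide/protein(s)", words: [peptide, polypeptide, protein, proteins]}
  - {label: "inner/outer/membrane/transmembrane", words: [inner, outer, membrane, transmembrane]}
  - {label: "binds/binding", words: [binds, binding]}
  - {label: "regulate(s)/regulated/regulator(y)/regulation/regulon", words: [regulate, regulates, regulated, regulator, regulatory, regulation, regulon]}
  - {label: "transport/transporter/export/import", words: [transport, transporter, export, import]}
  - {label: "enzyme", words: [enzyme]}
  - {label: "signal", words: [signal]}
  - {label: "initiation", words: [initiation]}
  - {label: "phage/prophage", words: [phage, prophage]}
  - {label: "oxidoreductase/reductase/reduce", words: [oxidoreductase, reductase, reduce]}
  - {label: "transcription/transcriptional", words: [transcription, transcriptional]}
  - {label: "promoter", words: [promoter]}
  - {label: "periplasm/periplasmic", words: [periplasm, periplasmic]}
  - {label: "lipoprotein", words: [lipoprotein]}
  - {label: "transferase", words: [transferase]}
  - {label: "resistance", words: [resistance]}
  - {label: "structures/structural", words: [structures, structural]}
  - {label: "cryptic", words: [cryptic]}
  - {label: "lysis", words: [lysis]}
  - {label: "synthesis", words: [synthesis]}
  - {label: "biofilm", words: [biofilm]}
  - {label: "phosphate", words: [phosphate]}
  - {label: "metabolism", words: [metabolism]}
  - {label: "codon", words: [codon]}
  - {label: "sugar", words: [sugar]}
  - {label: "stress", words: [stress]}
  - {label: "production", words: [production]}
  - {label: "aerobic", words: [aerobic]}
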