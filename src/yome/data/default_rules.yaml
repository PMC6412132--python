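# Default categorization rule set.
#
# Keyword rules fire on a single KB feature; structured rules fire on a
# gene's full feature set within one KB. The shipped keywords cover the
# documented per-KB indicator phrases; real knowledge-base releases use many
# more, so deployments are expected to extend this file.
#
# `tag` marks rules that the consensus layer treats as high-trust exceptions.
keyword_rules:
  # EcoCyc: low-annotation indicators in the description field.
  - {kb: ecocyc, feature_type: description, pattern: possibly, target: yome, match_mode: substring}
  - {kb: ecocyc, feature_type: description, pattern: predicted, target: yome, match_mode: substring}
  - {kb: ecocyc, feature_type: description, pattern: hypothetical, target: yome, match_mode: substring}
  # EcoCyc: curated functional-evidence ontology terms (high trust).
  - {kb: ecocyc, feature_type: evidence, pattern: assay, target: well_annotated, match_mode: substring, tag: ecocyc_evidence}
  - {kb: ecocyc, feature_type: evidence, pattern: reaction blocked in mutant, target: well_annotated, match_mode: substring, tag: ecocyc_evidence}
  - {kb: ecocyc, feature_type: evidence, pattern: traceable author statement to experimental support, target: well_annotated, match_mode: substring, tag: ecocyc_evidence}
  # EcoGene / UniProt low-annotation description phrases.
  - {kb: ecogene, feature_type: description, pattern: hypothetical, target: yome, match_mode: substring}
  - {kb: ecogene, feature_type: description, pattern: predicted, target: yome, match_mode: substring}
  - {kb: uniprot, feature_type: description, pattern: putative uncharacterized, target: yome, match_mode: substring}
  # RegulonDB: experimentally validated transcription-factor annotations.
  - {kb: regulondb, feature_type: tf_evidence, pattern: strong, target: well_annotated, match_mode: word, tag: regulondb_strong}

structured_rules:
  reaction_equation_well_annotated: true   # EcoCyc reaction equations
  complex_well_annotated: true             # EcoCyc gene-complex annotations
  insertion_well_annotated: true           # insertion elements ("ins*" names)
  pseudogene_excluded: true
  phantom_excluded: true
  ecogene_apostrophe_excluded: true        # EcoGene pseudogene naming

# Phrases marking knowledge-base entries that carry no functional
# information at all; matched as lowercase prefixes/substrings against
# description and summary features.
no_info_phrases:
  - no information about this
  - putative uncharacterized
  - uncharacterized protein
  - conserved protein of unknown function
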