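# Default EPIPHANY decision tree (reconstruction).
#
# The index is published as a figure; the flowchart itself is not reproduced in
# the accompanying text, which lists only the split variables (adapted Hestia
# status, PE presentation/symptoms, RECIST response grouped {PD, UK, NE} vs
# {CR, PR, SD, NED}, previous primary-tumor resection, SpO2, ECOG-PS).  This
# file is a reconstruction consistent with that variable list and with two
# structural guarantees of the index: an episode meeting at least one adapted
# Hestia criterion is never low-risk, and turning any Hestia flag on never
# lowers the risk category.  The SpO2 cutpoint (93%) and the ECOG-PS cutpoint
# (<=2) inside the Hestia-positive incidental branch are reconstruction
# choices; replace this file to use a verbatim transcription of the figure.
#
# Features available to predicates: hestia_any (bool), presentation
# (suspected | unsuspected_symptomatic | unsuspected_asymptomatic),
# recist_group (controlled | progressing), primary_resected (bool),
# spo2 (percent), ecog_ps (0-4).
name: epiphany-default-reconstruction
root: hestia
nodes:
  hestia:
    test: {feature: hestia_any, op: eq, value: true}
    if_true: pos_presentation
    if_false: neg_presentation
  neg_presentation:
    test: {feature: presentation, op: eq, value: unsuspected_asymptomatic}
    if_true: neg_asym_recist
    if_false: neg_sym_recist
  neg_asym_recist:
    test: {feature: recist_group, op: eq, value: controlled}
    if_true: leaf_low_incidental_controlled
    if_false: neg_asym_prog_resected
  neg_asym_prog_resected:
    test: {feature: primary_resected, op: eq, value: true}
    if_true: leaf_low_incidental_resected
    if_false: leaf_int_incidental_progressing
  neg_sym_recist:
    test: {feature: recist_group, op: eq, value: controlled}
    if_true: neg_sym_resected
    if_false: leaf_int_symptomatic_progressing
  neg_sym_resected:
    test: {feature: primary_resected, op: eq, value: true}
    if_true: leaf_low_symptomatic_controlled
    if_false: leaf_int_symptomatic_unresected
  pos_presentation:
    test: {feature: presentation, op: eq, value: unsuspected_asymptomatic}
    if_true: pos_asym_spo2
    if_false: leaf_high_symptomatic
  pos_asym_spo2:
    test: {feature: spo2, op: ge, value: 93}
    if_true: pos_asym_ecog
    if_false: leaf_high_hypoxemic
  pos_asym_ecog:
    test: {feature: ecog_ps, op: le, value: 2}
    if_true: leaf_int_incidental_hestia
    if_false: leaf_high_poor_ps
leaves:
  leaf_low_incidental_controlled: low
  leaf_low_incidental_resected: low
  leaf_low_symptomatic_controlled: low
  leaf_int_incidental_progressing: intermediate
  leaf_int_symptomatic_progressing: intermediate
  leaf_int_symptomatic_unresected: intermediate
  leaf_int_incidental_hestia: intermediate
  leaf_high_symptomatic: high
  leaf_high_hypoxemic: high
  leaf_high_poor_ps: high
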