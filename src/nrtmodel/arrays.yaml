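# Electrode-array contact layouts (placeholder geometry).
#
# Offsets are arc distances in mm from electrode 1, the most apical contact.
# True manufacturer inter-contact spacings are proprietary and not published
# with the study; the spans below are plausible nominal active lengths with
# uniform contact spacing, and can be overridden with a user registry file
# of the same shape (either `span_mm` + `n_contacts`, or an explicit
# `spacings_mm` list starting at 0).
# Spans are kept short enough that a fully inserted array fits inside even
# the smallest cochleae of the simulated population under the Escudé
# arc-length model.
PMA:          # perimodiolar curved array
  span_mm: 13.0
  n_contacts: 22
SA:           # straight array
  span_mm: 13.5
  n_contacts: 22
SSA:          # slim straight array
  span_mm: 14.0
  n_contacts: 22
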