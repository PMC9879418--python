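# Default age-class scheme: Grant mandible wear stages (MWS) mapped onto
# labelled age classes with absolute month bounds. MWS ranges are disjoint
# and contiguous (the hard requirement); the absolute-age labels of the
# older classes overlap, as the published class definitions do.
# Editable: replace with any scheme whose MWS ranges tile the domain.
classes:
  - {label: "0-1 m",      lower_months: 0,   upper_months: 1,   mws_min: 1,  mws_max: 2}
  - {label: "1-8 m",      lower_months: 1,   upper_months: 8,   mws_min: 3,  mws_max: 13}
  - {label: "8-18 m",     lower_months: 8,   upper_months: 18,  mws_min: 14, mws_max: 26}
  - {label: "18-34 m",    lower_months: 18,  upper_months: 34,  mws_min: 27, mws_max: 35}
  - {label: "34-43 m",    lower_months: 34,  upper_months: 43,  mws_min: 36, mws_max: 43}
  - {label: "3.4-6.5 y",  lower_months: 41,  upper_months: 78,  mws_min: 44, mws_max: 48}
  - {label: "6-11 y",     lower_months: 72,  upper_months: 132, mws_min: 49, mws_max: 51}
  - {label: "7-20 y",     lower_months: 84,  upper_months: 240, mws_min: 52, mws_max: 54}
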