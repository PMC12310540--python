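# MIPSS-PV mutation-enhanced survival score — comparator configuration.
# Component weights originate in the published MIPSS-PV score, not in this
# package: VERIFY AGAINST THE CITED SOURCE before clinical interpretation.
# The has_SRSF2 field comes from pvhmr.riskclass.genomic_features.
name: mipss_pv
criteria:
  - {field: age_dx, op: ge, value: 67, points: 2}
  - {field: leukocytes, op: ge, value: 15, points: 1}
  - {field: prior_thrombosis_any, op: eq, value: 1, points: 1}
  - {field: has_SRSF2, op: eq, value: 1, points: 3}
cutpoints:
  - {min_points: 0, category: low}
  - {min_points: 1, category: intermediate}
  - {min_points: 3, category: high}
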