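# IWG-PV survival score — comparator configuration.
# Component weights originate in the published IWG score for PV, not in this
# package: VERIFY AGAINST THE CITED SOURCE before clinical interpretation.
name: iwg_pv
criteria:
  - {field: age_dx, op: in_range, value: [57, 67], points: 2}
  - {field: age_dx, op: ge, value: 67, points: 5}
  - {field: leukocytes, op: ge, value: 15, points: 1}
  - {field: prior_venous_thrombosis, op: eq, value: 1, points: 1}
cutpoints:
  - {min_points: 0, category: low}
  - {min_points: 1, category: intermediate}
  - {min_points: 3, category: high}
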