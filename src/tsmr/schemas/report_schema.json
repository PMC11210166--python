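{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tsmr analysis report",
  "type": "object",
  "required": [
    "schema_version",
    "package_version",
    "config",
    "provenance",
    "strength",
    "harmonization",
    "estimates",
    "heterogeneity",
    "egger_intercept",
    "leave_one_out",
    "plot_data",
    "runtime"
  ],
  "properties": {
    "schema_version": {"type": "string"},
    "package_version": {"type": "string"},
    "config": {"type": "object"},
    "provenance": {"type": "array"},
    "strength": {"type": "object"},
    "harmonization": {"type": "object"},
    "estimates": {"type": "array"},
    "heterogeneity": {"type": "object"},
    "egger_intercept": {"type": "object"},
    "presso": {"type": ["object", "null"]},
    "leave_one_out": {"type": "object"},
    "plot_data": {"type": "object"},
    "runtime": {"type": "object"}
  }
}
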