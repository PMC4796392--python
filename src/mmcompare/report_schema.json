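{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mmcompare comparison report",
  "type": "object",
  "required": ["tool", "version", "operation", "estimates", "intervals", "statistics", "verdicts", "warnings"],
  "properties": {
    "tool": {"type": "string"},
    "version": {"type": "string"},
    "operation": {"type": "string"},
    "inputs": {"type": "object"},
    "estimates": {"type": "object"},
    "intervals": {"type": "object"},
    "statistics": {"type": "object"},
    "verdicts": {"type": "object"},
    "warnings": {"type": "array"},
    "seed": {"type": ["integer", "null"]}
  }
}
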