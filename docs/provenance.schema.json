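{
 "description": "What produced an output directory: command, config, inputs, counts.",
 "properties": {
  "command": {
   "title": "Command",
   "type": "string"
  },
  "package_version": {
   "default": "0.1.0",
   "title": "Package Version",
   "type": "string"
  },
  "python_version": {
   "title": "Python Version",
   "type": "string"
  },
  "config": {
   "additionalProperties": true,
   "title": "Config",
   "type": "object"
  },
  "input_checksums": {
   "additionalProperties": {
    "type": "string"
   },
   "title": "Input Checksums",
   "type": "object"
  },
  "counts": {
   "additionalProperties": {
    "type": "integer"
   },
   "title": "Counts",
   "type": "object"
  }
 },
 "required": [
  "command"
 ],
 "title": "Provenance",
 "type": "object"
}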