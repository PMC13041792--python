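{
 "additionalProperties": false,
 "description": "Declarative instrument description (the config.json schema).",
 "properties": {
  "ccd_x": {
   "default": 1340,
   "minimum": 2,
   "title": "Ccd X",
   "type": "integer"
  },
  "ccd_y": {
   "default": 100,
   "minimum": 1,
   "title": "Ccd Y",
   "type": "integer"
  },
  "detector": {
   "default": "",
   "title": "Detector",
   "type": "string"
  },
  "excitation_wavelength_nm": {
   "exclusiveMinimum": 0.0,
   "title": "Excitation Wavelength Nm",
   "type": "number"
  },
  "probe": {
   "default": "",
   "title": "Probe",
   "type": "string"
  },
  "requires_calibration": {
   "anyOf": [
    {
     "type": "boolean"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Requires Calibration"
  },
  "requires_src": {
   "anyOf": [
    {
     "type": "boolean"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Requires Src"
  },
  "spectral_range": {
   "default": [
    100.0,
    3400.0
   ],
   "maxItems": 2,
   "minItems": 2,
   "prefixItems": [
    {
     "type": "number"
    },
    {
     "type": "number"
    }
   ],
   "title": "Spectral Range",
   "type": "array"
  },
  "system": {
   "enum": [
    "Cart",
    "Portable",
    "Renishaw",
    "MANTIS",
    "custom"
   ],
   "title": "System",
   "type": "string"
  }
 },
 "required": [
  "system",
  "excitation_wavelength_nm"
 ],
 "title": "SystemConfig",
 "type": "object"
}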