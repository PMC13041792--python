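{
 "$defs": {
  "FbsConfig": {
   "additionalProperties": false,
   "description": "Fluorescence background subtraction (P7) parameters.",
   "properties": {
    "max_iterations": {
     "default": 100,
     "minimum": 1,
     "title": "Max Iterations",
     "type": "integer"
    },
    "poly_order": {
     "default": 5,
     "minimum": 0,
     "title": "Poly Order",
     "type": "integer"
    },
    "tolerance": {
     "default": 0.0001,
     "minimum": 0.0,
     "title": "Tolerance",
     "type": "number"
    }
   },
   "title": "FbsConfig",
   "type": "object"
  },
  "SmoothingConfig": {
   "additionalProperties": false,
   "properties": {
    "method": {
     "default": "none",
     "enum": [
      "savgol",
      "moving_average",
      "median",
      "none"
     ],
     "title": "Method",
     "type": "string"
    },
    "polyorder": {
     "default": 2,
     "title": "Polyorder",
     "type": "integer"
    },
    "window": {
     "default": 5,
     "title": "Window",
     "type": "integer"
    }
   },
   "title": "SmoothingConfig",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "Full P1\u2013P8 parameterization; together with the system configuration\nthis determines execution completely.",
 "properties": {
  "apply_src": {
   "default": false,
   "title": "Apply Src",
   "type": "boolean"
  },
  "bin_width": {
   "default": 3.5,
   "exclusiveMinimum": 0.0,
   "title": "Bin Width",
   "type": "number"
  },
  "cosmic_ray": {
   "const": "none",
   "default": "none",
   "title": "Cosmic Ray",
   "type": "string"
  },
  "fbs": {
   "$ref": "#/$defs/FbsConfig"
  },
  "normalization": {
   "default": "mean",
   "enum": [
    "mean",
    "area",
    "max"
   ],
   "title": "Normalization",
   "type": "string"
  },
  "smoothing": {
   "$ref": "#/$defs/SmoothingConfig"
  },
  "truncate_start": {
   "default": 900.0,
   "title": "Truncate Start",
   "type": "number"
  },
  "truncate_stop": {
   "default": 1700.0,
   "title": "Truncate Stop",
   "type": "number"
  }
 },
 "title": "PipelineConfig",
 "type": "object"
}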