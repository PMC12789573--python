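{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "sitski run configuration",
  "type": "object",
  "properties": {
    "athlete": {
      "type": "object",
      "properties": {
        "mass_total": {"type": "number", "exclusiveMinimum": 0, "description": "athlete + sit-ski + skis mass, kg"},
        "drag_area": {"type": "number", "minimum": 0, "description": "C_d * s product, m^2"},
        "lean_max": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 90, "description": "maximum lean angle, deg"},
        "com_height": {"type": "number", "exclusiveMinimum": 0, "description": "ski edge to COM distance, m (reporting only)"}
      },
      "additionalProperties": false
    },
    "environment": {
      "type": "object",
      "properties": {
        "gravity": {"type": "number", "exclusiveMinimum": 0, "description": "m/s^2"},
        "air_density": {"type": "number", "exclusiveMinimum": 0, "description": "kg/m^3"},
        "friction_coeff": {"type": "number", "minimum": 0, "exclusiveMaximum": 1},
        "altitude": {"type": ["number", "null"], "minimum": 0, "maximum": 6000, "description": "m"},
        "temperature": {"type": ["number", "null"], "minimum": -90, "maximum": 60, "description": "degC"}
      },
      "additionalProperties": false
    },
    "slope": {
      "type": "object",
      "properties": {
        "slope_angle": {"type": "number", "minimum": 0, "exclusiveMaximum": 90, "description": "deg"}
      },
      "additionalProperties": false
    },
    "solver": {
      "type": "object",
      "properties": {
        "n_knots": {"type": "integer", "minimum": 4},
        "dt": {"type": "number", "exclusiveMinimum": 0, "maximum": 0.01},
        "seed": {"type": "integer"},
        "time_cap": {"type": "number", "exclusiveMinimum": 0}
      },
      "additionalProperties": false
    },
    "paths": {
      "type": "object",
      "description": "course_in, trajectory_in, output_dir ...; *_in paths must exist at load time",
      "additionalProperties": {"type": "string"}
    }
  },
  "additionalProperties": false
}
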