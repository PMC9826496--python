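{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "multistress factorial response database row",
  "description": "One fully factorial two-stressor response: control, temperature alone, second stressor alone, and combined treatment, each summarised by mean, standard deviation and replicate count. CSV is RFC-4180, UTF-8, '.' decimal separator, one row per response.",
  "type": "object",
  "properties": {
    "study_id": {"type": "string"},
    "response_id": {"type": "string", "description": "unique within study"},
    "stressor_b_type": {
      "enum": ["acidification", "contamination", "food_quantity", "habitat_alteration", "invasion", "light", "nutrients", "salinity", "oxygen"]
    },
    "organisation_level": {"enum": ["individual", "population", "community"]},
    "organism_group": {"type": "string"},
    "response_metric": {
      "enum": ["abundance", "biomass", "condition", "diversity", "growth_size", "survival", "decomposition"]
    },
    "ctrl_mean": {"type": "number"},
    "ctrl_sd": {"type": "number", "minimum": 0},
    "ctrl_n": {"type": "integer", "minimum": 1},
    "ta_mean": {"type": "number"},
    "ta_sd": {"type": "number", "minimum": 0},
    "ta_n": {"type": "integer", "minimum": 1},
    "tb_mean": {"type": "number"},
    "tb_sd": {"type": "number", "minimum": 0},
    "tb_n": {"type": "integer", "minimum": 1},
    "tab_mean": {"type": "number"},
    "tab_sd": {"type": "number", "minimum": 0},
    "tab_n": {"type": "integer", "minimum": 1}
  },
  "required": [
    "study_id", "response_id", "stressor_b_type", "organisation_level",
    "organism_group", "response_metric",
    "ctrl_mean", "ctrl_sd", "ctrl_n", "ta_mean", "ta_sd", "ta_n",
    "tb_mean", "tb_sd", "tb_n", "tab_mean", "tab_sd", "tab_n"
  ]
}
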