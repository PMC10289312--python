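{
  "type": "object",
  "required": [
    "schema_version",
    "seed",
    "config_hash",
    "n_performances",
    "n_used",
    "discarded",
    "event_recovery",
    "model",
    "baseline",
    "rules",
    "stats"
  ],
  "properties": {
    "schema_version": {"type": "integer"},
    "seed": {"type": "integer"},
    "config_hash": {"type": "string"},
    "n_performances": {"type": "integer"},
    "n_used": {"type": "integer"},
    "discarded": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["index", "day", "stage", "reason"],
        "properties": {
          "index": {"type": "integer"},
          "day": {"type": "integer"},
          "stage": {"type": "string"},
          "reason": {"type": "string"}
        }
      }
    },
    "event_recovery": {
      "type": "object",
      "required": ["n_evaluated", "within_one_frame_rate", "per_event"],
      "properties": {
        "n_evaluated": {"type": "integer"},
        "within_one_frame_rate": {"type": "number"},
        "per_event": {"type": "object"}
      }
    },
    "model": {
      "type": "object",
      "required": [
        "train_days",
        "test_days",
        "n_train",
        "n_test",
        "metrics",
        "importances",
        "selected_features",
        "importance_threshold"
      ],
      "properties": {
        "train_days": {"type": "array", "items": {"type": "integer"}},
        "test_days": {"type": "array", "items": {"type": "integer"}},
        "n_train": {"type": "integer"},
        "n_test": {"type": "integer"},
        "metrics": {"type": "object"},
        "importances": {"type": "object"},
        "selected_features": {"type": "array", "items": {"type": "string"}},
        "importance_threshold": {"type": "number"}
      }
    },
    "baseline": {
      "type": "object",
      "required": ["feature", "regressor", "metrics"],
      "properties": {
        "feature": {"type": "string"},
        "regressor": {"type": "string"},
        "metrics": {"type": "object"}
      }
    },
    "rules": {
      "type": "object",
      "required": ["n_paths_first_tree", "min_deduction_path", "max_deduction_path"],
      "properties": {
        "n_paths_first_tree": {"type": "integer"},
        "min_deduction_path": {"type": "object"},
        "max_deduction_path": {"type": "object"}
      }
    },
    "stats": {
      "type": "object",
      "required": ["cond_a", "cond_b", "group_sizes"],
      "properties": {
        "cond_a": {"type": "string"},
        "cond_b": {"type": "string"},
        "group_sizes": {"type": "object"}
      }
    }
  }
}
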