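{
  "$comment": "Descriptive schema for the mrdsim dataset JSON (version 1.0). This document describes the contract enforced by mrdsim.io; it is reference documentation, not an executable JSON Schema.",
  "schema_version": "1.0",
  "top_level_keys": ["metadata", "subjects", "observations", "covariates", "endpoints", "ground_truth"],
  "notes": [
    "Keys appear in the fixed order listed above.",
    "ground_truth is omitted from blinded exports.",
    "Unknown keys are ignored with a warning on read (forward compatibility).",
    "All floats are written with shortest round-trip decimal representation.",
    "A relapse time of +infinity (subject never relapses) is encoded as null.",
    "Colormap entries must be 6-digit hex codes of the form #RRGGBB."
  ],
  "metadata": {
    "schema_version": "string, e.g. '1.0'",
    "time_unit": "string; all times in the dataset share this unit",
    "seed": "integer master seed of the simulation",
    "n_subjects": "integer",
    "noise_mode": "additive | multiplicative",
    "lod": "number or null; assay limit of detection",
    "colormaps": "object: covariate name -> list of hex codes (or object level -> hex)",
    "config": "the fully-resolved simulation configuration; together with seed it reproduces the dataset byte for byte"
  },
  "subjects[]": {
    "id": "string, unique",
    "subgroup": "string label (e.g. CR/PR/SD/PD)",
    "covariates": "object: baseline covariate name -> value",
    "time_variant_covariates": "object: name -> [{start: number, value: any}] piecewise-constant track",
    "event_time": "number; follow-up end (event or censoring), <= hazard t_max",
    "status": "1 = event, 0 = censored",
    "censor_reason": "none | administrative | dropout"
  },
  "observations[]": {
    "subject_id": "string referencing subjects[].id",
    "time": "number >= 0, <= subject's event_time",
    "value": "number >= 0, or null for missing visits",
    "raw_value": "pre-floor measurement draw (may be negative under additive noise)",
    "below_lod": "boolean; value < lod (strict), i.e. the MRD-negativity call",
    "missing": "boolean; visit occurred in the schedule but no measurement"
  },
  "covariates[]": {
    "name": "string",
    "kind": "binary | categorical | continuous",
    "params": "distribution parameters (binary: p; categorical: levels+probs; continuous: mean+sd)",
    "change_times": "list of numbers; non-empty makes the covariate time-variant"
  },
  "endpoints": "object: endpoint name -> [{subject_id, time, status}] one record per subject",
  "ground_truth": {
    "trajectories": "object: subject id -> {beta0, beta1, beta2, te, tr (null = never), sigma}",
    "hazard": "the HazardSpec used (baseline family/params, gamma, alpha1-3, link_scale, t_max, dropout_rate)",
    "subgroups": "the SubgroupSpec list used"
  }
}
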