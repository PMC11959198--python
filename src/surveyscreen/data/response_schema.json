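{
  "format": "CSV, UTF-8, header row, one row per completed survey response",
  "missing_value": "empty string",
  "multi_select_separator": ";",
  "columns": {
    "response_id": {"type": "string", "required": true, "notes": "opaque unique id within a cohort"},
    "submitted_at": {"type": "iso8601 datetime", "required": true, "notes": "stored UTC; naive values read as UTC"},
    "ip_address": {"type": "string", "required": true, "notes": "IPv4 or IPv6 literal"},
    "geo_country": {"type": "string", "required": false, "notes": "ISO 3166-1 alpha-2 from IP geolocation; produced upstream, no lookup performed here"},
    "self_report_country": {"type": "enum", "values": ["US", "CA", "OTHER"], "required": false},
    "recaptcha_score": {"type": "float in [0,1]", "required": false, "notes": "lower = more bot-like"},
    "duration_seconds": {"type": "int >= 0", "required": true, "notes": "survey completion time"},
    "email": {"type": "string", "required": false},
    "consent_contact": {"type": "bool (true/false)", "required": true, "notes": "agreed to follow-up contact"},
    "language": {"type": "enum", "values": ["en", "fr", "es"], "required": true},
    "age_years": {"type": "int >= 0", "required": false},
    "sex_assigned_at_birth": {"type": "enum", "values": ["female", "male"], "required": false},
    "social_transition": {"type": "tristate", "values": ["yes", "no", "unsure"], "required": true},
    "medical_transition": {"type": "tristate", "values": ["yes", "no", "unsure"], "required": true},
    "hormones_initial_transition": {"type": "multi-select", "values": ["estrogen", "testosterone", "blockers", "none"], "required": false},
    "gender_terms_past": {"type": "multi-select of free terms", "required": false, "notes": "case-folded, whitespace-collapsed on read"},
    "gender_terms_current": {"type": "multi-select of free terms", "required": false},
    "social_transition_year": {"type": "int year", "required": false},
    "trap_chekalism": {"type": "tristate", "values": ["yes", "no", "unsure"], "required": true, "notes": "fictitious condition; 'yes' marks fraud/carelessness"},
    "trap_syndomitis": {"type": "tristate", "values": ["yes", "no", "unsure"], "required": true, "notes": "fictitious condition"},
    "geo_subdivision": {"type": "string", "required": false, "notes": "state/province"}
  }
}
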