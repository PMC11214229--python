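# Default ICD-10 diagnosis-code prefixes used to supplement N and M from
# coded hospital-admission records.  These are engineering defaults, not a
# jurisdictional code list: registries should review and override them for
# their own coding standard (e.g. ICD-10-AM) via --code-map.
#
# nodal:       secondary and unspecified malignant neoplasm of lymph nodes
# metastasis:  secondary malignant neoplasm of other organs/sites
# exclusions:  prefixes to ignore entirely (takes priority over both sets)
nodal:
  - C77
metastasis:
  - C78
  - C79
exclusions: []
# Optional per-site overrides; keys replace the corresponding default list.
site_overrides: {}
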