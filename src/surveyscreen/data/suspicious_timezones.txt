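# IANA timezones treated as a priori suspicious for a US/Canada survey,
# based on scheduling anomalies reported for click-farm sign-ups
# (West African time zone cluster). One zone per line; "#" starts a comment.
Africa/Lagos
Africa/Accra
Africa/Abidjan
Africa/Porto-Novo
Africa/Lome
Africa/Cotonou
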