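# Synthetic placeholder lexicon for the "hateful email" signal.
# These tokens stand in for abusive vocabulary; no real slurs are shipped.
# Deployments should replace this file with their own curated list.
# Plain lines match as substrings; "token:" lines match whole tokens only.
hatetoken
slurtoken
bigotoken
token:abuseword
token:trollword
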