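# RIETE prognostic model - stub.
# The item table and cut-offs are not reproduced here; complete this file from
# the original publication before enabling.  The pipeline skips disabled
# models with a named warning.
name: riete
enabled: false
items: []
classes: []
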