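# Spanish prognostic score - stub.
# Complete the items/classes from the original publication before enabling.
name: spanish
enabled: false
items: []
classes: []
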