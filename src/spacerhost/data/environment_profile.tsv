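# Accepted trait classes for a hypersaline, alkaline, oligotrophic pond.
# One trait per line; edit freely for other source environments.
halophilic
halotolerant
alkaliphilic
thermophilic
oligotrophic
sulfate-reducing
sulfur-oxidizing
marine
archaea
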