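OOOWWWWWWWWOOO
OOWWIIIIIIWWOO
OWWIIIIIIIIWWO
WWIIIIIIIIIIWO
WIIIIIIIIIIIWW
WIIIIIIIIIIIIW
WIIIIIIIIIIIIW
WIIIIIIIIIIIWW
WWIIIIIIIIIIWO
OWWWWWWWWWWWWO
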