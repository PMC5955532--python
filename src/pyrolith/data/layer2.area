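OOOOWWWWWWWWWWOOOO
OOWWWIIIIIIIIWWOOO
OWWIIIIIIIIIIIWWOO
OWIIIIIIIIIIIIIWWO
WWIIIIIIIIIIIIIIWO
WIIIIIIIIIIIIIIIWW
WIIIIIIIIIIIIIIIIW
WIIIIIIIIIIIIIIIIW
WIIIIIIIIIIIIIIIIW
WIIIIIIIIIIIIIIIWW
WWIIIIIIIIIIIIIIWO
OWWIIIIIIIIIIIIWWO
OOWWIIIIIIIIIIWWOO
OOOWWWWWWWWWWWWOOO
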