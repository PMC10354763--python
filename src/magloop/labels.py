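"""The two object classes recognized on the platform."""

CLASS_DROPLET = "droplet"
CLASS_PARTICLE = "particle"
CLASSES = (CLASS_DROPLET, CLASS_PARTICLE)
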