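"""Small shared helpers."""


def fmt_float(x) -> str:
    """Shortest round-trip decimal representation of a float, for TSV output."""
    return repr(float(x))
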