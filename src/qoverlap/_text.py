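"""Label normalization used everywhere free-text labels are compared."""


def normalize_label(label: str) -> str:
    """Trim, collapse internal whitespace, and case-fold a label.

    This is the single normalization rule of the package: two labels are
    "the same" iff their normalized forms are equal.
    """
    return " ".join(label.split()).casefold()
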