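"""Small shared helpers: chromosome-name normalization."""

from __future__ import annotations

#: Canonical human nuclear + mitochondrial chromosome names (no "chr").
AUTOSOMES = frozenset(str(i) for i in range(1, 23))
CANONICAL = AUTOSOMES | {"X", "Y", "MT"}


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the bare UCSC-less dialect.

    Strips a leading ``chr`` prefix and maps ``M`` to ``MT`` so that
    ``chrX``/``X`` and ``chrM``/``MT`` compare equal.  Unknown contigs
    (decoys, unplaced scaffolds) pass through stripped but otherwise
    unchanged.
    """
    s = str(name)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"M", "MT"}:
        return "MT"
    return s.upper() if s.upper() in {"X", "Y"} else s


def is_canonical_autosome(name: str) -> bool:
    """True if the name denotes one of the 22 human autosomes."""
    return normalize_chrom(name) in AUTOSOMES
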