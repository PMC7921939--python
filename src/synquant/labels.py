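"""Canonical vocabulary for interface accumulation patterns.

A GFP-tagged sensor in a T cell conjugated to an antigen presenting cell
(APC) either shows no interface enrichment ("none") or accumulates in one
of six mutually exclusive supramolecular patterns at the T cell:APC
interface.
"""

from __future__ import annotations

#: Canonical pattern labels, in fixed output order.  ``none`` is the
#: no-accumulation label (interface enrichment below the 35% rule).
PATTERNS: tuple[str, ...] = (
    "none",
    "central",
    "invagination",
    "diffuse",
    "lamellal",
    "peripheral",
    "asymmetric",
)

#: The six accumulation patterns (everything except ``none``).
ACCUMULATION_PATTERNS: tuple[str, ...] = PATTERNS[1:]

_ALIASES = {"no_accumulation": "none", "no-accumulation": "none"}


def canonical_label(label: str) -> str:
    """Map a pattern label (or alias) to the canonical vocabulary.

    Raises
    ------
    ValueError
        If *label* is not a known pattern.
    """
    label = _ALIASES.get(label, label)
    if label not in PATTERNS:
        raise ValueError(
            f"unknown pattern label {label!r}; expected one of {PATTERNS}"
        )
    return label
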