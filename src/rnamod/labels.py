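"""The twelve RNA modification types and their original (modifiable) bases.

Each widespread base-resolution-profilable RNA modification occurs on exactly
one nucleotide: m6A, m1A, m6Am, Am and inosine (I) on adenosine; m5C and Cm on
cytidine; Gm and m7G on guanosine; pseudouridine (Psi), Um and m5U on uridine.
The label order below is fixed and defines the slot order of every 12-long
label vector in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ModificationLabel",
    "LABELS",
    "LABEL_NAMES",
    "LABEL_INDEX",
    "ORIGINAL_BASE",
    "LABELS_FOR_BASE",
    "NEGATIVE",
    "label_for",
]


@dataclass(frozen=True)
class ModificationLabel:
    """One RNA modification type.

    Attributes
    ----------
    name : str
        Short name, e.g. ``"m6A"`` or ``"Psi"``.
    original_base : str
        The unmodified nucleotide the modification occurs on (A/C/G/U).
    index : int
        Fixed slot in the 12-long label vector.
    """

    name: str
    original_base: str
    index: int


_LABEL_SPEC = [
    ("m6A", "A"),
    ("m1A", "A"),
    ("m5C", "C"),
    ("m5U", "U"),
    ("m6Am", "A"),
    ("m7G", "G"),
    ("Psi", "U"),
    ("I", "A"),
    ("Am", "A"),
    ("Cm", "C"),
    ("Gm", "G"),
    ("Um", "U"),
]

LABELS: tuple[ModificationLabel, ...] = tuple(
    ModificationLabel(name, base, i) for i, (name, base) in enumerate(_LABEL_SPEC)
)
LABEL_NAMES: tuple[str, ...] = tuple(l.name for l in LABELS)
LABEL_INDEX: dict[str, int] = {l.name: l.index for l in LABELS}
ORIGINAL_BASE: dict[str, str] = {l.name: l.original_base for l in LABELS}

#: Labels compatible with each center base, in slot order.
LABELS_FOR_BASE: dict[str, tuple[str, ...]] = {
    b: tuple(l.name for l in LABELS if l.original_base == b) for b in "ACGU"
}

#: Sentinel label name for unmodified (negative) sites.
NEGATIVE = "NEG"

# accept a few common aliases on input
_ALIASES = {
    "psi": "Psi", "Ψ": "Psi", "pseudouridine": "Psi",
    "Tm": "Um",  # DNA-style name for 2'-O-methyluridine
    "inosine": "I",
}


def label_for(name: str) -> ModificationLabel:
    """Resolve a label name (or alias) to its :class:`ModificationLabel`.

    Raises ``KeyError`` for anything outside the closed 12-label set.
    """
    canonical = _ALIASES.get(name, name)
    if canonical not in LABEL_INDEX:
        raise KeyError(
            f"unknown modification label {name!r}; expected one of {LABEL_NAMES}"
        )
    return LABELS[LABEL_INDEX[canonical]]
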