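"""Tissue class taxonomy.

Four narrow-band-imaging tissue classes with a stable integer encoding:
hypertrophic blood vessels (Hbv), healthy tissue (He), abnormal
intrapapillary capillary loop-like vessels (IPCL) and leukoplakia (Le).
"""

from enum import IntEnum


class ClassLabel(IntEnum):
    """Tissue class with stable integer encoding 0-3."""

    Hbv = 0
    He = 1
    IPCL = 2
    Le = 3

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        """Case-insensitive lookup ('HBV' and 'Hbv' both resolve)."""
        for member in cls:
            if member.name.lower() == name.lower():
                return member
        accepted = ", ".join(m.name for m in cls)
        raise ValueError(f"unknown class name {name!r}; accepted names: {accepted}")


CLASS_NAMES: tuple[str, ...] = tuple(m.name for m in ClassLabel)
N_CLASSES: int = len(ClassLabel)
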