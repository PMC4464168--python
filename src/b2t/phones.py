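"""Grouped phone inventory and the fine-phone -> grouped-phone mapping.

With only minutes of training data per session, one Gaussian per fine
phone is not trainable, so phonetically similar phones share a class:
voicing distinctions collapse (t/d, s/z), near vowels merge, and
diphthongs are written as two grouped monophthongs.  The result is 20
grouped phone classes plus the silence unit ``sil``.

The mapping is expressed over ARPABET fine-phone tokens (the alphabet of
CMUdict-style lexica) and is user-extensible: pass an extended dict to
any consumer that accepts a ``grouping`` argument.
"""

from __future__ import annotations

SILENCE = "sil"

# fine ARPABET token -> grouped phone(s); diphthongs map to two phones
DEFAULT_GROUPING: dict[str, tuple[str, ...]] = {
    # vowels
    "aa": ("aa",), "ae": ("aa",), "ah": ("aa",),
    "eh": ("eh",), "er": ("eh",), "ey": ("eh",),
    "ih": ("ih",), "iy": ("ih",),
    "ow": ("ow",), "ao": ("ow",),
    "uw": ("uw",), "uh": ("uw",),
    # diphthongs -> two grouped phones
    "ay": ("aa", "ih"), "oy": ("ow", "ih"), "aw": ("aa", "ow"),
    # consonants
    "b": ("b",),
    "ch": ("ch",), "sh": ("ch",), "zh": ("ch",),
    "f": ("f",),
    "hh": ("hh",),
    "jh": ("jh",), "g": ("jh",), "y": ("jh",),
    "k": ("k",),
    "l": ("l",),
    "m": ("m",),
    "n": ("n",), "ng": ("n",),
    "p": ("p",),
    "r": ("r",),
    "s": ("s",), "z": ("s",), "dh": ("s",), "th": ("s",),
    "t": ("t",), "d": ("t",),
    "v": ("v",),
    "w": ("w",),
}


def group_phone(
    label: str, grouping: dict[str, tuple[str, ...]] | None = None
) -> tuple[str, ...]:
    """Map one fine phone to its grouped phone(s); diphthongs give two."""
    grouping = grouping if grouping is not None else DEFAULT_GROUPING
    key = label.lower()
    if key not in grouping:
        raise KeyError(f"unknown phone {label!r}: not in the grouping map")
    return grouping[key]


def grouped_inventory(
    grouping: dict[str, tuple[str, ...]] | None = None,
) -> list[str]:
    """Sorted distinct grouped phone classes (excludes silence)."""
    grouping = grouping if grouping is not None else DEFAULT_GROUPING
    return sorted({g for targets in grouping.values() for g in targets})
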