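"""Built-in CMUdict-style lexicon for synthetic sessions.

About ninety words of mid-19th-century political oratory with
stress-stripped ARPABET pronunciations — the register of the prompt
texts such sessions emulate.  Used as the default word pool of the
synthetic generator; any user lexicon file can replace it.
"""

from __future__ import annotations

from . import phones
from .io_session import PronunciationDict

# word -> fine ARPABET pronunciation (no stress digits)
FINE_LEXICON: dict[str, str] = {
    "add": "ae d",
    "ago": "ah g ow",
    "all": "ao l",
    "altogether": "ao l t ah g eh dh er",
    "and": "ae n d",
    "any": "eh n iy",
    "are": "aa r",
    "battlefield": "b ae t ah l f iy l d",
    "brave": "b r ey v",
    "brought": "b r ao t",
    "but": "b ah t",
    "can": "k ae n",
    "civil": "s ih v ah l",
    "come": "k ah m",
    "conceived": "k ah n s iy v d",
    "consecrate": "k aa n s ah k r ey t",
    "continent": "k aa n t ah n ah n t",
    "created": "k r iy ey t ah d",
    "dead": "d eh d",
    "dedicate": "d eh d ah k ey t",
    "dedicated": "d eh d ah k ey t ah d",
    "detract": "d ih t r ae k t",
    "did": "d ih d",
    "do": "d uw",
    "endure": "eh n d uh r",
    "engaged": "eh n g ey jh d",
    "equal": "iy k w ah l",
    "fathers": "f aa dh er z",
    "field": "f iy l d",
    "final": "f ay n ah l",
    "fitting": "f ih t ih ng",
    "for": "f ao r",
    "forget": "f er g eh t",
    "forth": "f ao r th",
    "four": "f ao r",
    "gave": "g ey v",
    "great": "g r ey t",
    "ground": "g r aw n d",
    "hallow": "hh ae l ow",
    "have": "hh ae v",
    "here": "hh ih r",
    "in": "ih n",
    "is": "ih z",
    "larger": "l aa r jh er",
    "liberty": "l ih b er t iy",
    "little": "l ih t ah l",
    "live": "l ih v",
    "lives": "l ay v z",
    "living": "l ih v ih ng",
    "long": "l ao ng",
    "men": "m eh n",
    "met": "m eh t",
    "might": "m ay t",
    "nation": "n ey sh ah n",
    "never": "n eh v er",
    "new": "n uw",
    "nor": "n ao r",
    "not": "n aa t",
    "note": "n ow t",
    "now": "n aw",
    "on": "aa n",
    "our": "aw er",
    "place": "p l ey s",
    "poor": "p uh r",
    "portion": "p ao r sh ah n",
    "power": "p aw er",
    "proper": "p r aa p er",
    "proposition": "p r aa p ah z ih sh ah n",
    "remember": "r ih m eh m b er",
    "resting": "r eh s t ih ng",
    "say": "s ey",
    "score": "s k ao r",
    "sense": "s eh n s",
    "seven": "s eh v ah n",
    "should": "sh uh d",
    "so": "s ow",
    "struggled": "s t r ah g ah l d",
    "testing": "t eh s t ih ng",
    "that": "dh ae t",
    "the": "dh ah",
    "their": "dh eh r",
    "they": "dh ey",
    "this": "dh ih s",
    "those": "dh ow z",
    "to": "t uw",
    "war": "w ao r",
    "we": "w iy",
    "what": "w ah t",
    "whether": "w eh dh er",
    "who": "hh uw",
    "world": "w er l d",
    "years": "y ih r z",
}


def builtin_lexicon(
    grouping: dict[str, tuple[str, ...]] | None = None,
) -> PronunciationDict:
    """The built-in lexicon with pronunciations mapped to the grouped inventory."""
    lex = PronunciationDict()
    for word, pron in FINE_LEXICON.items():
        grouped: list[str] = []
        for tok in pron.split():
            grouped.extend(phones.group_phone(tok, grouping))
        lex.add(word, grouped)
    return lex


def builtin_lexicon_text() -> str:
    """The lexicon as CMUdict-style text (fine phones)."""
    return "\n".join(f"{w.upper()}  {p}" for w, p in sorted(FINE_LEXICON.items())) + "\n"
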