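"""Snowball stemming algorithm for Italian.

A direct implementation of the published Snowball Italian stemmer:
attached-pronoun removal, standard-suffix removal, verb-suffix removal,
and residual vowel/ch-gh cleanup, operating on the usual R1/R2/RV
regions.  Accented vowels are normalised from acute to grave first;
``u`` after ``q`` and ``u``/``i`` between vowels are temporarily
upper-cased so they count as consonants when regions are computed.
"""

from __future__ import annotations

__all__ = ["ItalianStemmer", "stem_italian"]

_VOWELS = set("aeiouàèìòù")

_ACUTE_TO_GRAVE = str.maketrans("áéíóú", "àèìòù")

_PRONOUN_SUFFIXES = sorted(
    [
        "ci", "gli", "la", "le", "li", "lo", "mi", "ne", "si", "ti", "vi",
        "sene", "gliela", "gliele", "glieli", "glielo", "gliene",
        "mela", "mele", "meli", "melo", "mene",
        "tela", "tele", "teli", "telo", "tene",
        "cela", "cele", "celi", "celo", "cene",
        "vela", "vele", "veli", "velo", "vene",
    ],
    key=len,
    reverse=True,
)

# step-1 suffixes mapped to their rule; searched longest-first
_STEP1 = sorted(
    [
        ("anza", "del_r2"), ("anze", "del_r2"),
        ("ico", "del_r2"), ("ici", "del_r2"), ("ica", "del_r2"), ("ice", "del_r2"),
        ("iche", "del_r2"), ("ichi", "del_r2"),
        ("ismo", "del_r2"), ("ismi", "del_r2"),
        ("abile", "del_r2"), ("abili", "del_r2"), ("ibile", "del_r2"), ("ibili", "del_r2"),
        ("ista", "del_r2"), ("iste", "del_r2"), ("isti", "del_r2"),
        ("istà", "del_r2"), ("istè", "del_r2"), ("istì", "del_r2"),
        ("oso", "del_r2"), ("osi", "del_r2"), ("osa", "del_r2"), ("ose", "del_r2"),
        ("mente", "del_r2"),
        ("atrice", "del_r2"), ("atrici", "del_r2"),
        ("ante", "del_r2"), ("anti", "del_r2"),
        ("azione", "ion"), ("azioni", "ion"), ("atore", "ion"), ("atori", "ion"),
        ("logia", "log"), ("logie", "log"),
        ("uzione", "u"), ("uzioni", "u"), ("usione", "u"), ("usioni", "u"),
        ("enza", "ente"), ("enze", "ente"),
        ("amento", "del_rv"), ("amenti", "del_rv"),
        ("imento", "del_rv"), ("imenti", "del_rv"),
        ("amente", "amente"),
        ("ità", "ita"),
        ("ivo", "iv"), ("ivi", "iv"), ("iva", "iv"), ("ive", "iv"),
    ],
    key=lambda t: len(t[0]),
    reverse=True,
)

_STEP2 = sorted(
    [
        "ammo", "ando", "ano", "are", "arono", "asse", "assero", "assi",
        "assimo", "ata", "ate", "ati", "ato", "ava", "avamo", "avano",
        "avate", "avi", "avo", "emmo", "enda", "ende", "endi", "endo",
        "erà", "erai", "eranno", "ere", "erebbe", "erebbero", "erei",
        "eremmo", "eremo", "ereste", "eresti", "erete", "erò", "erono",
        "essero", "ete", "eva", "evamo", "evano", "evate", "evi", "evo",
        "iamo", "iate", "ii", "immo", "irà", "irai", "iranno", "ire",
        "irebbe", "irebbero", "irei", "iremmo", "iremo", "ireste",
        "iresti", "irete", "irò", "irono", "isca", "iscano", "isce",
        "isci", "isco", "iscono", "issero", "ita", "ite", "iti", "ito",
        "iva", "ivamo", "ivano", "ivate", "ivi", "ivo", "ono", "uta",
        "ute", "uti", "uto", "ar", "ir",
    ],
    key=len,
    reverse=True,
)


def _is_vowel(ch: str) -> bool:
    return ch in _VOWELS


def _mark(word: str) -> str:
    """Upper-case u after q and u/i between vowels (treated as consonants)."""
    chars = list(word)
    for i, ch in enumerate(chars):
        if ch == "u" and i > 0 and chars[i - 1] == "q":
            chars[i] = "U"
        elif ch in "ui" and 0 < i < len(chars) - 1:
            if _is_vowel(chars[i - 1].lower()) and _is_vowel(chars[i + 1].lower()) and chars[i - 1] != "q":
                chars[i] = ch.upper()
    return "".join(chars)


def _r_after_vowel_consonant(word: str, start: int) -> int:
    """Position after the first non-vowel that follows a vowel, from start."""
    n = len(word)
    i = start
    while i < n and not _is_vowel(word[i]):
        i += 1
    while i < n and _is_vowel(word[i]):
        i += 1
    return min(i + 1, n) if i < n else n


def _regions(word: str) -> tuple[int, int, int]:
    """(r1, r2, rv) start positions on the marked word."""
    n = len(word)
    r1 = _r_after_vowel_consonant(word, 0)
    r2 = _r_after_vowel_consonant(word, r1)
    if n < 3:
        return r1, r2, n
    if not _is_vowel(word[1]):
        # consonant in 2nd position: region after the next vowel
        i = 2
        while i < n and not _is_vowel(word[i]):
            i += 1
        rv = min(i + 1, n)
    elif _is_vowel(word[0]) and _is_vowel(word[1]):
        # two initial vowels: region after the next consonant
        i = 2
        while i < n and _is_vowel(word[i]):
            i += 1
        rv = min(i + 1, n)
    else:
        # consonant-vowel: region after the third letter
        rv = 3
    return r1, r2, rv


def _in_region(word: str, suffix: str, region_start: int) -> bool:
    return len(word) - len(suffix) >= region_start


class ItalianStemmer:
    """Callable Snowball Italian stemmer (``stem(word) -> str``)."""

    def stem(self, word: str) -> str:
        word = word.lower().translate(_ACUTE_TO_GRAVE)
        if len(word) < 2:
            return word
        word = _mark(word)
        r1, r2, rv = _regions(word)

        word = self._step0(word, rv)
        after1 = self._step1(word, r1, r2, rv)
        if after1 is not None:
            word = after1
        else:
            word = self._step2(word, rv)
        word = self._step3a(word, rv)
        word = self._step3b(word, rv)
        return word.lower()

    __call__ = stem

    # -- steps ---------------------------------------------------------

    @staticmethod
    def _step0(word: str, rv: int) -> str:
        for suf in _PRONOUN_SUFFIXES:
            for stem_end, action in (("ando", "del"), ("endo", "del"), ("ar", "e"), ("er", "e"), ("ir", "e")):
                full = stem_end + suf
                if word.endswith(full) and _in_region(word, full, rv):
                    if action == "del":
                        return word[: -len(suf)]
                    return word[: -len(suf)] + "e"
        return word

    @staticmethod
    def _step1(word: str, r1: int, r2: int, rv: int) -> str | None:
        """Return the changed word, or None if no ending was removed."""
        for suf, rule in _STEP1:
            if not word.endswith(suf):
                continue
            if rule == "del_r2":
                return word[: -len(suf)] if _in_region(word, suf, r2) else None
            if rule == "del_rv":
                return word[: -len(suf)] if _in_region(word, suf, rv) else None
            if rule == "log":
                return word[: -len(suf)] + "log" if _in_region(word, suf, r2) else None
            if rule == "u":
                return word[: -len(suf)] + "u" if _in_region(word, suf, r2) else None
            if rule == "ente":
                return word[: -len(suf)] + "ente" if _in_region(word, suf, r2) else None
            if rule == "ion":
                if not _in_region(word, suf, r2):
                    return None
                word = word[: -len(suf)]
                if word.endswith("ic") and _in_region(word, "ic", r2):
                    word = word[:-2]
                return word
            if rule == "amente":
                if not _in_region(word, suf, r1):
                    return None
                word = word[: -len(suf)]
                if word.endswith("iv") and _in_region(word, "iv", r2):
                    word = word[:-2]
                    if word.endswith("at") and _in_region(word, "at", r2):
                        word = word[:-2]
                else:
                    for extra in ("os", "ic", "abil"):
                        if word.endswith(extra) and _in_region(word, extra, r2):
                            word = word[: -len(extra)]
                            break
                return word
            if rule == "ita":
                if not _in_region(word, suf, r2):
                    return None
                word = word[: -len(suf)]
                for extra in ("abil", "ic", "iv"):
                    if word.endswith(extra) and _in_region(word, extra, r2):
                        word = word[: -len(extra)]
                        break
                return word
            if rule == "iv":
                if not _in_region(word, suf, r2):
                    return None
                word = word[: -len(suf)]
                if word.endswith("at") and _in_region(word, "at", r2):
                    word = word[:-2]
                    if word.endswith("ic") and _in_region(word, "ic", r2):
                        word = word[:-2]
                return word
        return None

    @staticmethod
    def _step2(word: str, rv: int) -> str:
        for suf in _STEP2:
            if word.endswith(suf) and _in_region(word, suf, rv):
                return word[: -len(suf)]
        return word

    @staticmethod
    def _step3a(word: str, rv: int) -> str:
        if word and word[-1] in "aeioàèìò" and _in_region(word, word[-1], rv):
            word = word[:-1]
            if word and word[-1] == "i" and _in_region(word, "i", rv):
                word = word[:-1]
        return word

    @staticmethod
    def _step3b(word: str, rv: int) -> str:
        if (word.endswith("ch") or word.endswith("gh")) and _in_region(word, "ch", rv):
            return word[:-1]
        return word


_DEFAULT = ItalianStemmer()


def stem_italian(word: str) -> str:
    """Stem one lower-case Italian word."""
    return _DEFAULT.stem(word)
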