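"""Heuristic plausibility scoring of contact email addresses.

Survey-fraud screening flags submissions whose contact address looks
machine-generated ("nonsense") or contains abusive vocabulary ("hateful").
No published rule exists for either signal, so the classifier is an explicit,
deterministic heuristic with config-exposed thresholds:

* ``hateful`` — the local part or domain contains a lexicon entry, either as
  a substring (default entry type) or as a delimiter-separated token
  (entries prefixed ``token:``). The packaged lexicon contains only
  placeholder tokens, never real slurs; deployments supply their own list.
* ``nonsense`` — the local part has a run of >= 6 consecutive consonants, or
  is >= 10 characters with character-bigram entropy above 3.8 bits
  (keyboard-mash strings have near-uniform bigrams; real names repeat
  vowel-consonant patterns). Addresses without "@" are nonsense.
* ``ok`` — everything else.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

_CONSONANTS = set("bcdfghjklmnpqrstvwxyz")
_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")

DEFAULT_ENTROPY_CUTOFF = 3.8   # bits
DEFAULT_ENTROPY_MIN_LEN = 10   # characters of local part
DEFAULT_CONSONANT_RUN = 6


class Lexicon:
    """Term list for the 'hateful' signal.

    File format: one entry per line; ``#`` starts a comment. A plain entry
    matches as a substring; an entry written ``token:word`` matches only as a
    whole delimiter-separated token.
    """

    def __init__(self, substrings: Iterable[str] = (), tokens: Iterable[str] = ()):
        self.substrings = tuple(sorted({s.lower() for s in substrings if s}))
        self.tokens = frozenset(t.lower() for t in tokens if t)

    def __len__(self) -> int:
        return len(self.substrings) + len(self.tokens)

    def matches(self, text: str) -> bool:
        text = text.lower()
        if any(s in text for s in self.substrings):
            return True
        if self.tokens:
            parts = set(_TOKEN_SPLIT.split(text))
            if parts & self.tokens:
                return True
        return False

    @classmethod
    def from_path(cls, path) -> "Lexicon":
        subs, toks = [], []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("token:"):
                toks.append(line[len("token:"):].strip())
            else:
                subs.append(line)
        return cls(subs, toks)

    @classmethod
    def packaged(cls) -> "Lexicon":
        """The shipped placeholder lexicon (synthetic tokens only)."""
        ref = resources.files("surveyscreen.data") / "placeholder_lexicon.txt"
        with resources.as_file(ref) as p:
            return cls.from_path(p)


def bigram_entropy(text: str) -> float:
    """Shannon entropy (bits) of the overlapping character-bigram distribution."""
    if len(text) < 2:
        return 0.0
    counts = Counter(text[i:i + 2] for i in range(len(text) - 1))
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def max_consonant_run(text: str) -> int:
    run = best = 0
    for ch in text.lower():
        if ch in _CONSONANTS:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def score_email_plausibility(
    email: str,
    lexicon: Optional[Lexicon] = None,
    *,
    entropy_cutoff: float = DEFAULT_ENTROPY_CUTOFF,
    entropy_min_len: int = DEFAULT_ENTROPY_MIN_LEN,
    consonant_run: int = DEFAULT_CONSONANT_RUN,
) -> str:
    """Classify an address as ``"ok"``, ``"nonsense"``, or ``"hateful"``."""
    lexicon = lexicon if lexicon is not None else Lexicon()
    if "@" not in email:
        return "nonsense"
    local, _, domain = email.partition("@")
    if lexicon.matches(local) or lexicon.matches(domain):
        return "hateful"
    if max_consonant_run(local) >= consonant_run:
        return "nonsense"
    if len(local) >= entropy_min_len and bigram_entropy(local) > entropy_cutoff:
        return "nonsense"
    return "ok"
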