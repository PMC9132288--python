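"""Reading and writing CHAT (.cha) transcripts.

The CHILDES CHAT format stores one recording session per file: ``@``-prefixed
header lines (including an ``@ID`` line per participant carrying the age),
``*COD:``-prefixed main tiers holding the utterances of speaker ``COD``, and
``%``-prefixed dependent tiers (morphology, phonology, comments).  This module
implements a deliberately minimal dialect of that format: enough to extract,
for a target speaker (the child, ``CHI`` by convention), the session age and
the set of word *types* the child produced.  Dependent tiers, non-target
speakers and the full CLAN annotation system are ignored.

Token normalization is centralized in :class:`TokenizerConfig` /
:func:`normalize_token` so that every rule (fillers, unintelligible tokens,
special-form markers, compounds) is explicit and configurable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AgeSpec",
    "ChatSession",
    "TokenizerConfig",
    "ChatParseError",
    "parse_age",
    "normalize_token",
    "tokenize_tier",
    "parse_chat",
    "read_chat_file",
    "read_chat_dir",
    "write_chat",
    "sessions_to_listing",
]

logger = logging.getLogger(__name__)

#: Average Gregorian month length in days, used to convert Y;M.D ages to months.
DAYS_PER_MONTH = 30.44


class ChatParseError(ValueError):
    """Raised when a CHAT document or header field cannot be parsed."""


@dataclass(frozen=True)
class AgeSpec:
    """A CHAT ``@ID`` age field decomposed into years;months.days."""

    years: int
    months: int
    days: int = 0

    def __post_init__(self) -> None:
        if self.years < 0:
            raise ChatParseError(f"age years must be non-negative, got {self.years}")
        if not 0 <= self.months < 12:
            raise ChatParseError(f"age months must be in [0, 11], got {self.months}")
        if not 0 <= self.days < 31:
            raise ChatParseError(f"age days must be in [0, 30], got {self.days}")

    def to_months(self) -> float:
        """Age in months, with days converted via a 30.44-day month."""
        return round(self.years * 12 + self.months + self.days / DAYS_PER_MONTH, 2)


@dataclass(frozen=True)
class ChatSession:
    """One recording session: the target child's age and produced word types."""

    child_id: str
    session_index: int
    child_age_months: float
    child_word_types: frozenset[str]

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ValueError("session_index must be a positive integer")
        if not (self.child_age_months > 0 and self.child_age_months < float("inf")):
            raise ValueError("child_age_months must be finite and > 0")
        for w in self.child_word_types:
            if not w:
                raise ValueError("child_word_types must not contain empty strings")


_AGE_RE = re.compile(r"^(\d+);(\d+)(?:\.(\d+))?$")


def parse_age(text: str) -> float:
    """Parse a CHAT age string ``Y;M`` or ``Y;M.D`` into months.

    Months are ``years*12 + months + days/30.44``, rounded to two decimals.

    >>> parse_age("1;0")
    12.0
    >>> parse_age("2;0.15")
    24.49
    """
    m = _AGE_RE.match(text.strip())
    if m is None:
        raise ChatParseError(f"malformed CHAT age string: {text!r}")
    spec = AgeSpec(int(m.group(1)), int(m.group(2)), int(m.group(3) or 0))
    return spec.to_months()


@dataclass(frozen=True)
class TokenizerConfig:
    """Rules for mapping raw main-tier tokens to word types.

    All rules bias conservatively toward real lexical types: unintelligible
    material, fillers/fragments and annotation codes are dropped; child forms
    keep their stem; compounds stay single types.
    """

    lowercase: bool = True
    #: tokens that stand for unintelligible / untranscribed / phonological material
    drop_tokens: frozenset[str] = frozenset({"xxx", "yyy", "www"})
    #: prefixes marking fillers, fragments and non-word vocalizations (&-um, &=laughs)
    drop_prefixes: tuple[str, ...] = ("&", "[", "(", "+", "-", "0")
    #: trailing special-form markers (word@c, word@o ...) are stripped to the stem
    strip_form_markers: bool = True
    #: characters that may join a compound into one type
    compound_joiners: frozenset[str] = frozenset({"+", "_"})


DEFAULT_TOKENIZER = TokenizerConfig()

_WORD_CHAR_RE = re.compile(r"[a-z0-9]", re.IGNORECASE)
# bracketed CLAN codes ([!], [//], [: text], [* err] ...) and <...> retrace scopes
_BRACKET_RE = re.compile(r"\[[^\]]*\]")
_ANGLE_RE = re.compile(r"[<>]")


def normalize_token(raw: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> str | None:
    """Normalize one whitespace-delimited main-tier token.

    Returns the normalized word type, or ``None`` (DROP) for excluded tokens.
    Total function: never raises on any string.
    """
    tok = raw.strip()
    if not tok:
        return None
    if config.lowercase:
        tok = tok.lower()
    if tok in config.drop_tokens:
        return None
    # leading prefix rules, except a leading compound joiner that is part of a word
    for pfx in config.drop_prefixes:
        if tok.startswith(pfx):
            if pfx in config.compound_joiners and _WORD_CHAR_RE.search(tok):
                continue
            return None
    if config.strip_form_markers and "@" in tok:
        tok = tok.split("@", 1)[0]
    # strip non-word leading/trailing punctuation while keeping compound joiners
    keep = "".join(config.compound_joiners) + "'"
    tok = tok.strip("".join(c for c in set(tok) if not (_WORD_CHAR_RE.match(c) or c in keep)))
    if not tok or not _WORD_CHAR_RE.search(tok):
        return None
    return tok


def tokenize_tier(tier_text: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> list[str]:
    """Split one main-tier utterance into normalized word types (with repeats)."""
    cleaned = _BRACKET_RE.sub(" ", tier_text)
    cleaned = _ANGLE_RE.sub(" ", cleaned)
    out = []
    for raw in cleaned.split():
        word = normalize_token(raw, config)
        if word is not None:
            out.append(word)
    return out


def _strip_bom(text: str) -> str:
    return text.lstrip("\ufeff")


def parse_chat(
    document: str,
    target_speaker: str = "CHI",
    child_id: str | None = None,
    session_index: int = 1,
    config: TokenizerConfig = DEFAULT_TOKENIZER,
) -> ChatSession:
    """Parse a CHAT document into a :class:`ChatSession` for one speaker.

    Only main tiers whose speaker code equals ``target_speaker`` contribute
    word types; all other speakers' tiers and all ``%`` dependent tiers are
    ignored.  The session age comes from the target speaker's ``@ID`` header.
    """
    age_months: float | None = None
    id_child: str | None = None
    words: set[str] = set()
    saw_target_tier = False
    current_is_target = False

    for line in _strip_bom(document).splitlines():
        if line.startswith("\t") and current_is_target:
            words.update(tokenize_tier(line, config))
            continue
        current_is_target = False
        if line.startswith("@ID:"):
            fields = [f.strip() for f in line[len("@ID:"):].strip().split("|")]
            # @ID: language|corpus|code|age|sex|group|SES|role|...
            if len(fields) >= 4 and fields[2] == target_speaker:
                if not fields[3]:
                    raise ChatParseError(
                        f"@ID for speaker {target_speaker!r} has an empty age field"
                    )
                age_months = parse_age(fields[3])
                id_child = fields[1] or None
        elif line.startswith("*"):
            code, sep, rest = line[1:].partition(":")
            if sep and code.strip() == target_speaker:
                current_is_target = True
                saw_target_tier = True
                words.update(tokenize_tier(rest, config))

    if age_months is None:
        raise ChatParseError(
            f"document has no @ID header with an age for speaker {target_speaker!r}"
        )
    if not saw_target_tier:
        logger.warning(
            "no main tier for speaker %r; returning an empty word set", target_speaker
        )
    return ChatSession(
        child_id=child_id or id_child or target_speaker,
        session_index=session_index,
        child_age_months=age_months,
        child_word_types=frozenset(words),
    )


def read_chat_file(
    path: str | Path,
    target_speaker: str = "CHI",
    child_id: str | None = None,
    session_index: int = 1,
    config: TokenizerConfig = DEFAULT_TOKENIZER,
) -> ChatSession:
    """Read one ``.cha`` file (UTF-8, BOM tolerated) as a session."""
    text = Path(path).read_text(encoding="utf-8-sig")
    return parse_chat(text, target_speaker, child_id, session_index, config)


def read_chat_dir(
    root: str | Path,
    target_speaker: str = "CHI",
    config: TokenizerConfig = DEFAULT_TOKENIZER,
) -> dict[str, list[ChatSession]]:
    """Read a directory tree of ``.cha`` files grouped by child.

    Layout convention: ``root/<child_id>/*.cha`` — one subdirectory per child,
    one file per session, session order given by sorted file names.  A flat
    directory of ``.cha`` files is treated as a single child named after the
    directory.
    """
    root = Path(root)
    groups: dict[str, list[Path]] = {}
    subdirs = sorted(p for p in root.iterdir() if p.is_dir())
    if subdirs:
        for d in subdirs:
            files = sorted(d.glob("*.cha"))
            if files:
                groups[d.name] = files
    flat = sorted(root.glob("*.cha"))
    if flat:
        groups[root.name] = flat
    if not groups:
        raise ChatParseError(f"no .cha files found under {root}")
    out: dict[str, list[ChatSession]] = {}
    for child, files in groups.items():
        out[child] = [
            read_chat_file(f, target_speaker, child_id=child, session_index=i + 1,
                           config=config)
            for i, f in enumerate(files)
        ]
    return out


def _months_to_age_string(age_months: float) -> str:
    years, rem = divmod(age_months, 12.0)
    months = int(rem)
    days = int(round((rem - months) * DAYS_PER_MONTH))
    if days >= 31:  # rounding spill-over
        months, days = months + 1, 0
        if months == 12:
            years, months = years + 1, 0
    return f"{int(years)};{months:02d}.{days:02d}"


def write_chat(session: ChatSession, target_speaker: str = "CHI") -> str:
    """Serialize a session to the minimal CHAT dialect read by :func:`parse_chat`.

    Word types are emitted one utterance per type, sorted, so that
    ``parse_chat(write_chat(s)) == s`` (round trip).
    """
    age = _months_to_age_string(session.child_age_months)
    lines = [
        "@UTF8",
        "@Begin",
        f"@ID:\teng|{session.child_id}|{target_speaker}|{age}|||||Target_Child|||",
        f"@ID:\teng|{session.child_id}|MOT||||||Mother|||",
    ]
    for word in sorted(session.child_word_types):
        lines.append(f"*{target_speaker}:\t{word} .")
    lines.append("@End")
    return "\n".join(lines) + "\n"


def sessions_to_listing(sessions: Iterable[ChatSession]) -> pd.DataFrame:
    """Long-format per-session word-type listing.

    One row per (child, session, word type); columns ``child_id``,
    ``session_index``, ``age_months``, ``word``.
    """
    rows = [
        (s.child_id, s.session_index, s.child_age_months, w)
        for s in sessions
        for w in sorted(s.child_word_types)
    ]
    return pd.DataFrame(rows, columns=["child_id", "session_index", "age_months", "word"])
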