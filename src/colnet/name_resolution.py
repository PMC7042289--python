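"""Collector-name cleaning: atomization, normalization and resolution.

Raw ``recordedBy`` strings hold one or more collector names joined by
inconsistent delimiters ("Irwin, H.S.; Ratter, J.A.", "Silva, M. et al.",
"A. Lima | B. Costa" ...).  The pipeline here is

1. **atomize** — split the string into individual raw names, flagging and
   discarding "et al." markers (which denote unnamed secondary collectors
   and therefore carry no usable tie);
2. **normalize** — map each raw name deterministically onto a canonical
   collector identifier of the form ``surname,initials`` — lowercase,
   diacritics stripped, internal whitespace and punctuation removed
   (e.g. "Proença, C.E.B." -> ``proenca,ceb``);
3. **resolve** — apply an optional variant→canonical name map, deduplicate
   within each record, and fill the record's ``collector_ids``.

Two people can normalize to the same token; disambiguating them needs
external knowledge supplied through the name map, not heuristics here.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from colnet.errors import ConfigurationError, NameRejectedError
from colnet.occurrence_io import OccurrenceRecord

#: Default separators between collector names.  A bare comma is *not* a
#: between-name separator because the dominant "Surname, Initials" layout
#: uses it within one name.
DEFAULT_DELIMITERS: tuple[str, ...] = (";", "|", "&", " e ", " and ")

#: Tokens that are placeholders, not names (collector unknown / sine nomine).
DEFAULT_STOP_LIST: frozenset[str] = frozenset({"sn", "s.n.", "s.n", "?", "-", "al", "ilegivel"})

_ET_AL_RE = re.compile(r"\bet\.?\s*al[li]*\.?\s*$", re.IGNORECASE)
_NON_ALPHA_RE = re.compile(r"[^a-z]+")


@dataclass
class AtomizationReport:
    """Counters and rejections accumulated while resolving a dataset."""

    records_processed: int = 0
    names_extracted: int = 0
    et_al_flags: int = 0
    rejected_tokens: list[tuple[str, str, str]] = field(default_factory=list)  # (record_id, token, reason)
    empty_records: list[str] = field(default_factory=list)  # record ids whose id list came out empty

    def write(self, path, delimiter: str = "\t") -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter=delimiter)
            w.writerow(["records_processed", self.records_processed])
            w.writerow(["names_extracted", self.names_extracted])
            w.writerow(["et_al_flags", self.et_al_flags])
            w.writerow(["empty_records", len(self.empty_records)])
            for rid, tok, reason in self.rejected_tokens:
                w.writerow(["rejected", rid, tok, reason])


def atomize(
    recorded_by_raw: str, delimiters: Sequence[str] = DEFAULT_DELIMITERS
) -> tuple[list[str], bool]:
    """Split a raw ``recordedBy`` string into individual name strings.

    Returns ``(names, et_al_seen)``: names in original order, trimmed, empty
    fragments dropped; "et al."-type markers removed from the list and
    reported through the flag.
    """
    if not delimiters:
        raise ConfigurationError("delimiters must be nonempty")
    if not recorded_by_raw or not recorded_by_raw.strip():
        return [], False
    pattern = "|".join(re.escape(d) for d in delimiters)
    fragments = re.split(pattern, recorded_by_raw)
    names: list[str] = []
    et_al = False
    for frag in fragments:
        frag = frag.strip()
        if not frag:
            continue
        if _ET_AL_RE.search(frag):
            et_al = True
            frag = _ET_AL_RE.sub("", frag).strip().rstrip(",").strip()
            if not frag:
                continue
        names.append(frag)
    return names, et_al


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def _initials_from(chunks: Iterable[str]) -> str:
    """First letter of each given-name chunk; an unpunctuated all-caps run of
    ≤4 letters is treated as packed initials ("HS" -> "hs")."""
    out = []
    for chunk in chunks:
        letters = re.sub(r"[^A-Za-zÀ-ÿ]", "", chunk)
        if not letters:
            continue
        if letters.isupper() and len(letters) <= 4:
            out.append(letters.lower())
        else:
            out.append(letters[0].lower())
    return "".join(out)


def normalize(raw_name: str) -> str:
    """Normalize one collector name to its canonical ``surname,initials`` id.

    Accepts the two layouts seen in collection data: "Surname, Given/Initials"
    (comma present) and "Given/Initials Surname" (no comma, last word is the
    surname).  Deterministic, case-insensitive, diacritic-free; multi-part
    surnames are concatenated ("Carvalho Silva, M." -> ``carvalhosilva,m``).

    Raises
    ------
    NameRejectedError
        If the token has no alphabetic content, or either the surname or the
        initials part comes out empty.
    """
    if raw_name is None or not raw_name.strip():
        raise NameRejectedError(raw_name or "", "blank")
    text = _strip_diacritics(raw_name).strip()
    if not re.search(r"[A-Za-z]", text):
        raise NameRejectedError(raw_name, "no alphabetic content")
    if re.fullmatch(r"[a-z]+,[a-z]+", text):
        return text  # already a canonical token; normalize is idempotent

    if "," in text:
        surname_part, _, given_part = text.partition(",")
    else:
        words = text.split()
        if len(words) < 2:
            raise NameRejectedError(raw_name, "missing initials")
        surname_part = words[-1]
        given_part = " ".join(words[:-1])

    surname = _NON_ALPHA_RE.sub("", surname_part.lower())
    given_chunks = re.split(r"[\s.\-]+", given_part.strip())
    initials = _initials_from(given_chunks)
    if not surname:
        raise NameRejectedError(raw_name, "missing surname")
    if not initials:
        raise NameRejectedError(raw_name, "missing initials")
    return f"{surname},{initials}"


def load_name_map(path, delimiter: Optional[str] = None) -> dict[str, str]:
    """Load a two-column (variant, canonical) delimited file into a name map."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        sample = fh.read()
    delim = delimiter or ("\t" if "\t" in sample.splitlines()[0] else ",")
    mapping: dict[str, str] = {}
    for row in csv.reader(sample.splitlines(), delimiter=delim):
        if not row or not row[0].strip():
            continue
        if len(row) < 2:
            raise ConfigurationError(f"name map row needs two columns: {row!r}")
        variant, canonical = row[0].strip(), row[1].strip()
        if variant in mapping and mapping[variant] != canonical:
            raise ConfigurationError(f"variant {variant!r} maps to multiple canonicals")
        mapping[variant] = canonical
    _check_functional(mapping)
    return mapping


def _check_functional(name_map: Mapping[str, str]) -> None:
    for variant, canonical in name_map.items():
        if canonical in name_map and name_map[canonical] != canonical:
            raise ConfigurationError(
                f"name map is not functional: {variant!r} -> {canonical!r} -> {name_map[canonical]!r}"
            )


@dataclass
class RejectionRules:
    """When to discard a normalized token instead of keeping it as a node."""

    min_alpha_chars: int = 2
    stop_list: frozenset[str] = DEFAULT_STOP_LIST

    def check(self, raw: str) -> Optional[str]:
        """Return a rejection reason, or None if the token is acceptable."""
        stripped = _strip_diacritics(raw).strip().lower()
        if stripped in self.stop_list:
            return "stop-list"
        alpha = re.sub(r"[^a-z]", "", stripped)
        if not alpha:
            return "no alphabetic content"
        if len(alpha) < self.min_alpha_chars:
            return "too short"
        return None


def resolve(
    records: Sequence[OccurrenceRecord],
    name_map: Optional[Mapping[str, str]] = None,
    delimiters: Sequence[str] = DEFAULT_DELIMITERS,
    rejection_rules: Optional[RejectionRules] = None,
) -> tuple[list[OccurrenceRecord], AtomizationReport]:
    """Fill ``collector_ids`` on every record.

    Each record's ids are the mapped, deduplicated normalized tokens in
    first-appearance order.  Records whose id list comes out empty (only
    "et al.", only rejected tokens, blank field) are flagged in the report
    but kept in the output — dropping them is a filtering decision that
    belongs to the caller.
    """
    name_map = dict(name_map) if name_map else {}
    _check_functional(name_map)
    rules = rejection_rules or RejectionRules()
    report = AtomizationReport()
    out: list[OccurrenceRecord] = []
    for rec in records:
        report.records_processed += 1
        names, et_al = atomize(rec.recorded_by_raw, delimiters)
        if et_al:
            report.et_al_flags += 1
        ids: list[str] = []
        for raw in names:
            reason = rules.check(raw)
            if reason is not None:
                report.rejected_tokens.append((rec.record_id, raw, reason))
                continue
            try:
                token = normalize(raw)
            except NameRejectedError as exc:
                report.rejected_tokens.append((rec.record_id, raw, exc.reason))
                continue
            token = name_map.get(token, token)
            if token not in ids:
                ids.append(token)
        report.names_extracted += len(ids)
        if not ids:
            report.empty_records.append(rec.record_id)
        out.append(rec.with_collectors(ids))
    return out, report
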