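"""Corpus, record-table and lexicon input/output.

A corpus is an ordered collection of records, each carrying a record
identifier (a PMID for PubMed-derived data, any local id otherwise) and the
set of controlled-vocabulary descriptor terms indexed on that record.  Two
on-disk representations are supported: the MEDLINE/PubMed citation XML
dialect, and a plain two-column record table (``record_id<TAB>descriptor``)
of the kind produced by bibliographic database exports.  Term lexicons used
as filters (e.g. a table of Chinese herb names) are one term per line.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

__all__ = [
    "DescriptorRecord",
    "Corpus",
    "HerbLexicon",
    "CorpusParseError",
    "normalize_term",
    "read_medline_xml",
    "write_medline_xml",
    "read_record_table",
    "write_record_table",
    "read_lexicon",
    "write_lexicon",
]

_WS_RUN = re.compile(r"\s+")


class CorpusParseError(ValueError):
    """Raised when a corpus or lexicon file cannot be parsed."""


def normalize_term(term: str) -> str:
    """Trim and collapse internal whitespace runs; case is preserved.

    Controlled-vocabulary descriptors are case-meaningful enough that
    lowercasing could merge distinct terms, so case-insensitive behaviour is
    confined to lexicon matching.
    """
    return _WS_RUN.sub(" ", term.strip())


@dataclass(frozen=True)
class DescriptorRecord:
    """One citation: a record id plus its set of descriptor terms."""

    record_id: str
    descriptors: frozenset[str]

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        normalized = frozenset(
            t for t in (normalize_term(d) for d in self.descriptors) if t
        )
        object.__setattr__(self, "descriptors", normalized)


@dataclass
class Corpus:
    """Ordered collection of records with pairwise-distinct record ids."""

    records: list[DescriptorRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id: {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DescriptorRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        # order-insensitive record comparison; labels compared as-is
        return (
            sorted(self.records, key=lambda r: r.record_id)
            == sorted(other.records, key=lambda r: r.record_id)
            and self.source_label == other.source_label
        )


@dataclass(frozen=True)
class HerbLexicon:
    """Ordered set of filter terms with case-insensitive lookup."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        cleaned: list[str] = []
        seen: set[str] = set()
        for raw in self.terms:
            t = normalize_term(raw)
            if not t:
                raise ValueError("lexicon terms must be non-empty")
            key = t.casefold()
            if key not in seen:
                seen.add(key)
                cleaned.append(t)
        object.__setattr__(self, "terms", tuple(cleaned))
        object.__setattr__(self, "_lookup", frozenset(seen))

    @property
    def size(self) -> int:
        return len(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term).casefold() in self._lookup  # type: ignore[attr-defined]

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)


# ---------------------------------------------------------------------------
# MEDLINE citation XML


def read_medline_xml(
    path: str | Path,
    major_topic_only: bool = False,
    include_qualifiers: bool = False,
    source_label: str = "",
) -> Corpus:
    """Read a MEDLINE/PubMed citation XML export into a :class:`Corpus`.

    Parameters
    ----------
    path:
        XML file containing ``PubmedArticle`` (or bare ``MedlineCitation``)
        elements with a ``PMID`` and an optional ``MeshHeadingList``.
    major_topic_only:
        Keep only headings flagged ``MajorTopicYN="Y"`` (on the descriptor
        or, when qualifiers are harvested, on the qualifier itself).
    include_qualifiers:
        Also harvest ``QualifierName`` text as standalone terms.  MEDLINE
        attaches subheading qualifiers (e.g. "physiopathology") to
        descriptors; some exports list them alongside descriptors, so this
        flag reproduces that mixed view.

    Records whose heading list is empty after filtering are retained; they
    simply contribute no co-occurrence pairs.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(
            f"{path}: malformed XML at line {exc.lineno}, column {exc.position[1]}: "
            f"{exc.msg}"
        ) from exc

    records: list[DescriptorRecord] = []
    seen_ids: set[str] = set()
    for citation in tree.iter("MedlineCitation"):
        pmid_el = citation.find("PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            raise CorpusParseError(f"{path}: citation without a PMID")
        pmid = pmid_el.text.strip()
        if pmid in seen_ids:
            raise CorpusParseError(f"{path}: duplicate PMID {pmid!r}")
        seen_ids.add(pmid)

        terms: set[str] = set()
        for heading in citation.iter("MeshHeading"):
            desc = heading.find("DescriptorName")
            if desc is not None and (desc.text or "").strip():
                if not major_topic_only or desc.get("MajorTopicYN") == "Y":
                    terms.add(desc.text)
            if include_qualifiers:
                for qual in heading.findall("QualifierName"):
                    if (qual.text or "").strip():
                        if not major_topic_only or qual.get("MajorTopicYN") == "Y":
                            terms.add(qual.text)
        records.append(DescriptorRecord(pmid, frozenset(terms)))

    return Corpus(records, source_label or path.stem)


def write_medline_xml(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as minimal MEDLINE-dialect citation XML (round-trippable)."""
    root = etree.Element("PubmedArticleSet")
    for rec in corpus:
        article = etree.SubElement(root, "PubmedArticle")
        citation = etree.SubElement(article, "MedlineCitation")
        etree.SubElement(citation, "PMID").text = rec.record_id
        heading_list = etree.SubElement(citation, "MeshHeadingList")
        for term in sorted(rec.descriptors):
            heading = etree.SubElement(heading_list, "MeshHeading")
            etree.SubElement(heading, "DescriptorName").text = term
    etree.ElementTree(root).write(
        str(path), encoding="UTF-8", xml_declaration=True, pretty_print=True
    )


# ---------------------------------------------------------------------------
# Plain record tables


def read_record_table(
    path: str | Path,
    delimiter: str = "\t",
    header: bool = False,
    source_label: str = "",
) -> Corpus:
    """Read a two-column ``record_id<delim>descriptor`` table into a corpus.

    Lines are grouped by record id (first-seen order preserved); duplicate
    ``(record_id, descriptor)`` lines collapse to one descriptor.
    """
    path = Path(path)
    grouped: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise CorpusParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            rid, term = parts[0].strip(), normalize_term(parts[1])
            if not rid or not term:
                raise CorpusParseError(
                    f"{path}: line {lineno}: empty record id or descriptor"
                )
            grouped.setdefault(rid, set()).add(term)
    records = [DescriptorRecord(rid, frozenset(terms)) for rid, terms in grouped.items()]
    return Corpus(records, source_label or path.stem)


def write_record_table(
    corpus: Corpus, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a corpus as a two-column record table (deterministic row order)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in corpus:
            for term in sorted(rec.descriptors):
                fh.write(f"{rec.record_id}{delimiter}{term}\n")


# ---------------------------------------------------------------------------
# Lexicons


def read_lexicon(path: str | Path) -> HerbLexicon:
    """Read a one-term-per-line lexicon; blank lines and ``#`` comments ignored."""
    path = Path(path)
    terms: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            terms.append(line)
    if not terms:
        warnings.warn(f"{path}: lexicon is empty", stacklevel=2)
    return HerbLexicon(tuple(terms))


def write_lexicon(lexicon: HerbLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for term in lexicon:
            fh.write(term + "\n")


def corpus_from_pairs(
    pairs: Iterable[tuple[str, str]], source_label: str = ""
) -> Corpus:
    """Build a corpus from an iterable of ``(record_id, descriptor)`` pairs."""
    grouped: dict[str, set[str]] = {}
    for rid, term in pairs:
        grouped.setdefault(rid, set()).add(term)
    return Corpus(
        [DescriptorRecord(rid, frozenset(ts)) for rid, ts in grouped.items()],
        source_label,
    )
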