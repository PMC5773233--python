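"""Mining refractive-error phenotypes from OMIM-style flat-text records.

The workflow mirrors how syndromic candidate genes are assembled from a
Mendelian-phenotype catalog: parse record-delimited flat text, scan each
entry's clinical synopsis for refractive-error vocabulary (myopia,
hyperopia, astigmatism, other ametropia), link the flagged phenotypes to
their causal genes through morbidmap/mim2gene-style mapping tables, and
collapse the per-phenotype links into deduplicated per-class gene sets.

The record dialect is the classic ``*RECORD*`` / ``*FIELD*`` flat file:
records separated by a line ``*RECORD*``, the identifier under
``*FIELD* NO``, the title under ``*FIELD* TI`` and the clinical synopsis
under ``*FIELD* CS``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "CLASS_LABELS",
    "MalformedRecordError",
    "PhenotypeRecord",
    "TermLexicon",
    "RefractiveClassification",
    "GenePhenotypeLink",
    "GeneSet",
    "LinkResult",
    "parse_omim_records",
    "classify_refractive",
    "link_genes",
    "build_gene_sets",
    "mining_report",
    "write_gene_sets",
]

#: Refractive-error classes recognized by the default lexicon.
CLASS_LABELS = ("myopia", "hyperopia", "astigmatism", "ametropia_other")

_RECORD_DELIM = "*RECORD*"
_FIELD_PREFIX = "*FIELD*"


class MalformedRecordError(ValueError):
    """A record block lacks its identifier field."""


@dataclass(frozen=True)
class PhenotypeRecord:
    """One catalog entry: identifier, title, clinical synopsis, raw text."""

    mim_id: str
    title: str
    clinical_text: str
    raw_block: str


@dataclass(frozen=True)
class RefractiveClassification:
    """Refractive classes detected in one record's clinical text.

    ``matches`` lists every hit as ``(class, term, character_offset)``;
    ``classes_found`` is exactly the set of classes appearing in it.
    """

    mim_id: str
    classes_found: frozenset[str]
    matches: tuple[tuple[str, str, int], ...]


@dataclass(frozen=True)
class GenePhenotypeLink:
    """A phenotype-to-gene assignment (one row per phenotype/gene pair)."""

    mim_id: str
    gene_symbol: str
    gene_id: str = ""
    chromosome: str = ""


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene symbols with phenotype provenance.

    ``provenance`` keeps one entry per contributing phenotype link, so a
    gene carried by several phenotypes appears once in ``gene_symbols``
    but contributes several provenance entries; ``n_duplicates`` is the
    number of links collapsed away (total links minus unique genes).
    """

    name: str
    gene_symbols: tuple[str, ...]
    provenance: tuple[str, ...]
    n_duplicates: int
    by_gene: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __len__(self) -> int:
        return len(self.gene_symbols)

    def provenance_of(self, symbol: str) -> tuple[str, ...]:
        return dict(self.by_gene).get(symbol, ())


def _word_pattern(term: str) -> re.Pattern[str]:
    # Letters and "-" are word-joining: "amyopiaX" and "pre-myopia" do not
    # contain the word "myopia", while punctuation/whitespace delimit it.
    body = re.escape(term)
    return re.compile(rf"(?<![A-Za-z-]){body}(?![A-Za-z-])", re.IGNORECASE)


@dataclass
class TermLexicon:
    """Search vocabulary: refractive class label -> whole-word terms."""

    classes: dict[str, list[str]]
    _patterns: dict[str, list[tuple[str, re.Pattern[str]]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, terms in self.classes.items():
            if not terms:
                raise ValueError(f"lexicon class {label!r} has no terms")
            for term in terms:
                key = term.casefold()
                if key in seen and seen[key] != label:
                    raise ValueError(
                        f"term {term!r} appears under both {seen[key]!r} and {label!r}"
                    )
                seen[key] = label
        self._patterns = {
            label: [(term, _word_pattern(term)) for term in terms]
            for label, terms in self.classes.items()
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TermLexicon":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle)
        return cls({str(k): [str(t) for t in v] for k, v in data.items()})

    @classmethod
    def default(cls) -> "TermLexicon":
        text = resources.files("omimgwas").joinpath("data/lexicon.yaml").read_text()
        data = yaml.safe_load(text)
        return cls({str(k): [str(t) for t in v] for k, v in data.items()})


def _read_text(stream) -> str:
    if isinstance(stream, Path):
        return stream.read_text(encoding="utf-8")
    if isinstance(stream, str):
        if "\n" not in stream and len(stream) < 4096:
            try:
                if Path(stream).is_file():
                    return Path(stream).read_text(encoding="utf-8")
            except OSError:
                pass
        return stream
    return stream.read()


_FIELD_RE = re.compile(r"^\*FIELD\* +(\S+) *$", re.MULTILINE)
_DELIM_RE = re.compile(r"^\*RECORD\* *$", re.MULTILINE)


def _field_spans(block: str) -> dict[str, str]:
    """First occurrence of each ``*FIELD* XX`` section -> its verbatim body."""
    fields: dict[str, str] = {}
    matches = list(_FIELD_RE.finditer(block))
    for i, m in enumerate(matches):
        name = m.group(1)
        start = m.end()
        end = matches[i + 1].start() if i + 1 < len(matches) else len(block)
        if name not in fields:
            fields[name] = block[start:end]
    return fields


def parse_omim_records(stream) -> list[PhenotypeRecord]:
    """Parse ``*RECORD*``-delimited flat text into :class:`PhenotypeRecord`.

    Accepts a path, a string of text, or a file-like object.  Text before
    the first delimiter is ignored.  A record without a ``*FIELD* NO``
    identifier raises :class:`MalformedRecordError` naming the byte offset
    of the offending record.
    """
    text = _read_text(stream)
    records: list[PhenotypeRecord] = []
    starts = [m.start() for m in _DELIM_RE.finditer(text)]
    if not starts:
        return records
    bounds = starts + [len(text)]
    for i in range(len(starts)):
        block = text[bounds[i] : bounds[i + 1]]
        body = _DELIM_RE.sub("", block, count=1)
        if not body.strip():
            continue  # trailing bare delimiter, not a record
        fields = _field_spans(block)
        if "NO" not in fields or not fields["NO"].strip():
            offset = len(text[: bounds[i]].encode("utf-8"))
            raise MalformedRecordError(
                f"record at byte offset {offset} is missing its *FIELD* NO identifier"
            )
        mim_id = fields["NO"].strip().split()[0]
        title = fields.get("TI", "").strip().splitlines()
        records.append(
            PhenotypeRecord(
                mim_id=mim_id,
                title=title[0].strip() if title else "",
                clinical_text=fields.get("CS", "").strip(),
                raw_block=block,
            )
        )
    return records


def classify_refractive(
    record: PhenotypeRecord, lexicon: TermLexicon | None = None
) -> RefractiveClassification:
    """Scan a record's clinical synopsis for refractive-error terms.

    Matching is case-insensitive and whole-word (letters and ``-`` join
    words); every hit is reported with its character offset.
    """
    lexicon = lexicon or TermLexicon.default()
    matches: list[tuple[str, str, int]] = []
    for label, patterns in lexicon._patterns.items():
        for term, pattern in patterns:
            for m in pattern.finditer(record.clinical_text):
                matches.append((label, term, m.start()))
    matches.sort(key=lambda t: (t[2], t[0], t[1]))
    return RefractiveClassification(
        mim_id=record.mim_id,
        classes_found=frozenset(m[0] for m in matches),
        matches=tuple(matches),
    )


def _as_morbidmap(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.read_csv(
        table,
        sep="\t",
        header=None,
        names=["phenotype", "gene_symbols", "mim_id"],
        dtype=str,
        comment="#",
    )


def _as_gene_ids(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.read_csv(
        table,
        sep="\t",
        header=None,
        names=["mim_id", "type", "entrez", "symbol", "ensembl"],
        dtype=str,
        comment="#",
    )


@dataclass
class LinkResult:
    """Outcome of phenotype-to-gene linkage."""

    links: list[GenePhenotypeLink]
    skipped_mim_ids: list[str]
    unmapped_symbols: list[str]


def link_genes(classified: Sequence[RefractiveClassification], morbidmap, gene_id_table) -> LinkResult:
    """Link refractive phenotypes to causal genes via mapping tables.

    Only classifications with at least one refractive class are linked.
    Phenotypes with no gene row in the morbidmap go to
    ``skipped_mim_ids`` (the catalog's entities-without-genes side
    channel).  A symbol present in the morbidmap but absent from the
    gene-id table keeps its link with an empty ``gene_id`` and is
    reported in ``unmapped_symbols``.
    """
    mm = _as_morbidmap(morbidmap)
    ids = _as_gene_ids(gene_id_table)
    id_by_symbol = {
        str(row.symbol): ("" if pd.isna(row.entrez) else str(row.entrez))
        for row in ids.itertuples()
    }
    by_mim: dict[str, list[str]] = {}
    for row in mm.itertuples():
        symbols = [s.strip() for s in str(row.gene_symbols).split(",") if s.strip()]
        by_mim.setdefault(str(row.mim_id), []).extend(symbols)

    links: list[GenePhenotypeLink] = []
    skipped: list[str] = []
    unmapped: list[str] = []
    seen_pairs: set[tuple[str, str]] = set()
    for cls in classified:
        if not cls.classes_found:
            continue
        symbols = by_mim.get(cls.mim_id, [])
        if not symbols:
            skipped.append(cls.mim_id)
            continue
        for symbol in symbols:
            if (cls.mim_id, symbol) in seen_pairs:
                continue
            seen_pairs.add((cls.mim_id, symbol))
            gene_id = id_by_symbol.get(symbol)
            if gene_id is None:
                unmapped.append(symbol)
                gene_id = ""
            links.append(GenePhenotypeLink(cls.mim_id, symbol, gene_id))
    return LinkResult(links=links, skipped_mim_ids=skipped, unmapped_symbols=unmapped)


def _make_set(name: str, links: Iterable[GenePhenotypeLink]) -> GeneSet:
    ordered: list[str] = []
    provenance: list[str] = []
    by_gene: dict[str, list[str]] = {}
    n_links = 0
    for link in links:
        n_links += 1
        provenance.append(link.mim_id)
        if link.gene_symbol not in by_gene:
            ordered.append(link.gene_symbol)
            by_gene[link.gene_symbol] = []
        by_gene[link.gene_symbol].append(link.mim_id)
    return GeneSet(
        name=name,
        gene_symbols=tuple(ordered),
        provenance=tuple(provenance),
        n_duplicates=n_links - len(ordered),
        by_gene=tuple((g, tuple(m)) for g, m in by_gene.items()),
    )


def build_gene_sets(
    links: Sequence[GenePhenotypeLink],
    classifications: Sequence[RefractiveClassification],
) -> dict[str, GeneSet]:
    """Collapse phenotype-gene links into per-class gene sets.

    Emits ``any-<class>`` sets (phenotype lists the class, possibly among
    others) for myopia/hyperopia/astigmatism, the global ``all-ametropia``
    union, and exclusive ``<class>-only`` sets (the class is the sole
    refractive feature).  Gene identity is the approved symbol; duplicate
    links are collapsed and counted.
    """
    classes_by_mim = {c.mim_id: c.classes_found for c in classifications}
    sets: dict[str, GeneSet] = {}
    for label in ("myopia", "hyperopia", "astigmatism"):
        sets[f"any-{label}"] = _make_set(
            f"any-{label}",
            (l for l in links if label in classes_by_mim.get(l.mim_id, frozenset())),
        )
    sets["all-ametropia"] = _make_set(
        "all-ametropia", (l for l in links if classes_by_mim.get(l.mim_id))
    )
    for label in CLASS_LABELS:
        sets[f"{label}-only"] = _make_set(
            f"{label}-only",
            (l for l in links if classes_by_mim.get(l.mim_id) == frozenset({label})),
        )
    return sets


def mining_report(
    records: Sequence[PhenotypeRecord],
    classifications: Sequence[RefractiveClassification],
    link_result: LinkResult,
    gene_sets: Mapping[str, GeneSet],
) -> dict:
    """Assemble the JSON-serializable mining summary."""
    classified = [c for c in classifications if c.classes_found]
    return {
        "n_records": len(records),
        "n_refractive_entities": len(classified),
        "n_linked_phenotypes": len({l.mim_id for l in link_result.links}),
        "n_links": len(link_result.links),
        "n_skipped_without_gene": len(link_result.skipped_mim_ids),
        "skipped_mim_ids": sorted(link_result.skipped_mim_ids),
        "n_unmapped_symbols": len(link_result.unmapped_symbols),
        "gene_sets": {
            name: {
                "n_genes": len(gs),
                "n_duplicates": gs.n_duplicates,
            }
            for name, gs in gene_sets.items()
        },
    }


def write_gene_sets(gene_sets: Mapping[str, GeneSet], path: str | Path) -> None:
    """Write per-class gene sets as a tidy TSV (set, symbol, provenance)."""
    rows = []
    for name, gs in gene_sets.items():
        for symbol in gs.gene_symbols:
            rows.append(
                {
                    "gene_set": name,
                    "gene_symbol": symbol,
                    "provenance": ",".join(gs.provenance_of(symbol)),
                }
            )
    pd.DataFrame(rows, columns=["gene_set", "gene_symbol", "provenance"]).to_csv(
        path, sep="\t", index=False
    )
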