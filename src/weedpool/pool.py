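"""Species-pool assembly from heterogeneous source lists.

A *species pool* is the union of taxa recorded by several sources — expert
floras, specialist lists and plot-based surveys — each taxon carrying
membership flags for the sources that record it, plus biological attributes
(Raunkiaer life form, biogeographic origin, red-list status). The pool is
the unit the downstream comparisons operate on: Venn partitions of source
memberships, attribute tabulations, and observed-vs-expected contrasts.

Name matching is exact on normalized strings; no fuzzy matching and no
synonymy resolution against a taxonomic backbone. This keeps the assembly
fully reproducible from the input lists alone. Infra-specific taxa
(subspecies, varieties) are kept as distinct records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from ._util import logger, percent

LIFE_FORMS = frozenset(
    {"therophyte", "hemicryptophyte", "geophyte", "chamaephyte",
     "phanerophyte", "other", "unknown"}
)
ORIGINS = frozenset(
    {"mediterranean", "european", "eurasian", "cosmopolitan", "introduced",
     "other", "unknown"}
)
RED_LIST = frozenset({"listed", "not_listed", "DD_LC_excluded", "unknown"})

_ATTR_DOMAINS = {"family": None, "life_form": LIFE_FORMS, "origin": ORIGINS,
                 "red_list": RED_LIST}

# Infra-specific rank markers stay lower-case but are not epithets.
_RANK_MARKERS = {"subsp.", "var.", "f.", "x", "×", "ssp.", "subvar."}


@dataclass
class TaxonRecord:
    """One taxon with its attributes and per-source membership flags."""

    taxon_id: str
    name: str
    family: str = "unknown"
    life_form: str = "unknown"
    origin: str = "unknown"
    red_list: str = "unknown"
    memberships: set[str] = field(default_factory=set)


@dataclass
class SpeciesPool:
    """A compiled pool: taxa plus the registry of contributing sources."""

    taxa: list[TaxonRecord]
    sources: list[str]

    def __len__(self) -> int:
        return len(self.taxa)

    def members_of(self, source: str) -> set[str]:
        """Taxon ids flagged as present in ``source``."""
        if source not in self.sources:
            raise KeyError(f"unregistered source: {source!r}")
        return {t.taxon_id for t in self.taxa if source in t.memberships}

    def subset(self, sources_any: Sequence[str] | None = None) -> list[TaxonRecord]:
        """Taxa belonging to at least one of the given sources (all if None)."""
        if sources_any is None:
            return list(self.taxa)
        for s in sources_any:
            if s not in self.sources:
                raise KeyError(f"unregistered source: {s!r}")
        want = set(sources_any)
        return [t for t in self.taxa if t.memberships & want]


def normalize_name(raw: str) -> str:
    """Canonicalize a taxon name at string level.

    Trims and collapses whitespace, capitalizes the genus and lower-cases
    epithets; rank markers (subsp., var., ...) are preserved as written in
    lower case. Idempotent by construction. Raises ``ValueError`` on
    empty/blank input.
    """
    s = re.sub(r"\s+", " ", raw.strip())
    if not s:
        raise ValueError("taxon name is empty or blank")
    parts = s.split(" ")
    out = [parts[0].capitalize()]
    for p in parts[1:]:
        low = p.lower()
        out.append(low)
    return " ".join(out)


def _clean_attr(attr: str, value: str | None) -> str:
    """Map a raw attribute value into its declared domain (or 'unknown')."""
    if value is None:
        return "unknown"
    v = str(value).strip()
    if not v:
        return "unknown"
    domain = _ATTR_DOMAINS[attr]
    if domain is None:  # free-text attribute (family)
        return v
    if v in domain:
        return v
    lv = v.lower()
    if lv in domain:
        return lv
    logger.warning("unknown %s value %r mapped to 'unknown'", attr, value)
    return "unknown"


def merge_sources(
    source_lists: Mapping[str, Iterable[Mapping[str, str]]],
) -> SpeciesPool:
    """Compile a pool from per-source taxon rows.

    ``source_lists`` maps source name -> iterable of row mappings, each with
    at least a ``name`` key and optionally ``family``, ``life_form``,
    ``origin``, ``red_list``. Names are normalized and matched exactly;
    membership flags record every source containing the name. When two
    sources disagree on an attribute, the first-listed source wins and the
    conflict is logged. Duplicates within one source are collapsed with a
    warning.
    """
    if not source_lists:
        raise ValueError("at least one source list is required")
    sources = list(source_lists)
    records: dict[str, TaxonRecord] = {}
    for source in sources:
        seen_here: set[str] = set()
        for row in source_lists[source]:
            if "name" not in row:
                raise ValueError(f"source {source!r}: row without a 'name' field")
            name = normalize_name(row["name"])
            if name in seen_here:
                logger.warning("source %r: duplicate taxon %r collapsed", source, name)
                continue
            seen_here.add(name)
            attrs = {a: _clean_attr(a, row.get(a)) for a in _ATTR_DOMAINS}
            if name not in records:
                records[name] = TaxonRecord(
                    taxon_id=name, name=name, memberships={source}, **attrs
                )
            else:
                rec = records[name]
                rec.memberships.add(source)
                for a, v in attrs.items():
                    cur = getattr(rec, a)
                    if cur == "unknown" and v != "unknown":
                        setattr(rec, a, v)
                    elif v not in ("unknown", cur):
                        logger.info(
                            "attribute conflict for %r.%s: keeping %r "
                            "(precedence), ignoring %r from %r",
                            name, a, cur, v, source,
                        )
    taxa = sorted(records.values(), key=lambda t: t.name)
    logger.info("merged %d sources into a pool of %d taxa", len(sources), len(taxa))
    return SpeciesPool(taxa=taxa, sources=sources)


def venn_partition(pool: SpeciesPool, set_names: Sequence[str]) -> dict[tuple[str, ...], int]:
    """Counts over all non-empty membership regions of 2–3 sources.

    Keys are sorted tuples of the sources defining the (exclusive) region;
    e.g. with sources A, B the key ``("A",)`` counts taxa in A but not B.
    Region counts sum to the size of the union.
    """
    if not 2 <= len(set_names) <= 3:
        raise ValueError("venn_partition takes 2 or 3 source names")
    for s in set_names:
        if s not in pool.sources:
            raise KeyError(f"unregistered source: {s!r}")
    names = list(set_names)
    counts: dict[tuple[str, ...], int] = {}
    for pattern in product([False, True], repeat=len(names)):
        if not any(pattern):
            continue
        key = tuple(sorted(n for n, inc in zip(names, pattern) if inc))
        counts[key] = 0
    for t in pool.taxa:
        inside = tuple(sorted(n for n in names if n in t.memberships))
        if inside:
            counts[inside] += 1
    return counts


def tabulate(
    pool: SpeciesPool,
    attribute: str,
    subset: Sequence[str] | None = None,
) -> list[tuple[str, int, float]]:
    """Tabulate (category, count, percent) for one attribute.

    ``subset`` optionally restricts to taxa belonging to at least one of the
    named sources. Percentages are of the subset size, reported to one
    decimal with round-half-up, and ordered by descending count.
    """
    if attribute not in _ATTR_DOMAINS:
        raise ValueError(f"unknown attribute {attribute!r}")
    taxa = pool.subset(subset)
    if not taxa:
        raise ValueError("empty subset: nothing to tabulate")
    counts: dict[str, int] = {}
    for t in taxa:
        v = getattr(t, attribute)
        counts[v] = counts.get(v, 0) + 1
    total = len(taxa)
    rows = [(cat, n, percent(n, total)) for cat, n in counts.items()]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows
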