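"""Disease Ontology loading and dictionary-based disease tagging.

Series metadata is annotated with Disease Ontology (DO) terms by scanning
each text field against an index of DO names and exact/related synonyms —
a greedy longest-match dictionary tagger with plural normalisation.  Each
tag carries three hierarchy fields (is_leaf, distance_from_root,
is_obsolete) so that a search for a non-leaf disease can also return every
series tagged with one of its descendants.

OBO parsing is delegated to :mod:`obonet`; the hierarchy lives in a
networkx graph whose ``is_a`` edges point child → parent, rooted at
"disease" (DOID:4).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional

import networkx as nx
import obonet

from .geo_io import SeriesMetadata

__all__ = [
    "OntologyIndex",
    "DiseaseTag",
    "load_ontology",
    "load_bundled_ontology",
    "hierarchy_metrics",
    "tag_text",
    "tag_series",
    "descendants",
    "STOP_WORDS",
]

logger = logging.getLogger(__name__)

#: Small fixed stop-word list; these surface forms never match on their own.
STOP_WORDS = frozenset(
    "a an and by disease for in of or syndrome the to with".split()
)

_MIN_SURFACE_LEN = 3
_SYNONYM_RE = re.compile(r'"(?P<text>[^"]*)"\s*(?P<scope>[A-Z_]+)?')


def _normalize_surface(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


def _singularize(word: str) -> str:
    if word.endswith("ses") or word.endswith("xes") or word.endswith("ches"):
        return word[:-2]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        return word[:-1]
    return word


@dataclass
class OntologyIndex:
    """A loaded disease ontology with a surface-string lookup index.

    ``terms`` maps a numeric DOID (e.g. ``"8469"``) to its name, synonyms,
    obsolete flag and ``is_a`` parents; ``name_index`` maps a normalized
    surface form to the DOIDs it denotes; ``children`` is the inverse of
    the parent map.
    """

    terms: dict[str, dict] = field(default_factory=dict)
    name_index: dict[str, set[str]] = field(default_factory=dict)
    children: dict[str, set[str]] = field(default_factory=dict)
    root: str = "4"

    @property
    def max_phrase_tokens(self) -> int:
        return max((s.count(" ") + 1 for s in self.name_index), default=1)

    def __contains__(self, doid: str) -> bool:
        return doid in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def _doid_number(identifier: str) -> str:
    return identifier.split(":", 1)[-1].lstrip("0") or "0"


def load_ontology(obo: str | Path | IO[str]) -> OntologyIndex:
    """Build an :class:`OntologyIndex` from an OBO 1.2 stream or path.

    Names and EXACT/RELATED synonyms enter the surface index; strings
    shorter than 3 characters after normalisation (short abbreviations)
    and bare stop words are excluded.  Terms with an id but no name are
    skipped with a warning; a cyclic ``is_a`` hierarchy is a hard error.
    """
    graph = obonet.read_obo(obo, ignore_obsolete=False)

    index = OntologyIndex()
    for node, data in graph.nodes(data=True):
        if not str(node).upper().startswith("DOID"):
            continue
        name = data.get("name")
        if not name:
            warnings.warn(f"OBO term {node} has no name; skipped", stacklevel=2)
            continue
        doid = _doid_number(str(node))
        synonyms: list[str] = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if not m:
                continue
            scope = (m.group("scope") or "RELATED").upper()
            if scope in ("EXACT", "RELATED"):
                synonyms.append(m.group("text"))
        parents = sorted(
            {_doid_number(str(p)) for p in data.get("is_a", [])}
            | {
                _doid_number(str(v))
                for _, v, key in graph.out_edges(node, keys=True)
                if key == "is_a"
            }
        )
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        index.terms[doid] = {
            "name": name,
            "synonyms": synonyms,
            "obsolete": obsolete,
            "parents": parents,
        }
        if name.lower() == "disease":
            index.root = doid

    for doid, term in index.terms.items():
        for parent in term["parents"]:
            index.children.setdefault(parent, set()).add(doid)
        if term["obsolete"]:
            continue
        for surface in [term["name"], *term["synonyms"]]:
            norm = _normalize_surface(surface)
            if len(norm) < _MIN_SURFACE_LEN or norm in STOP_WORDS:
                continue
            index.name_index.setdefault(norm, set()).add(doid)

    _check_acyclic(index)
    if not index.terms:
        warnings.warn("OBO stream contained no DOID terms", stacklevel=2)
    return index


def _check_acyclic(index: OntologyIndex) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(index.terms)
    for doid, term in index.terms.items():
        for parent in term["parents"]:
            if parent in index.terms:
                g.add_edge(doid, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"cyclic is_a hierarchy in ontology: {cycle}")


def load_bundled_ontology() -> OntologyIndex:
    """Load the miniature DO snapshot shipped with the package.

    ~30 human-disease terms (root DOID:4, influenza DOID:8469 with synonym
    "flu", prostate cancer DOID:10283, ...) sufficient for tests and small
    demonstrations; real analyses should supply a full doid.obo.
    """
    ref = resources.files("timecourse_miner.data").joinpath("mini_do.obo")
    with resources.as_file(ref) as path:
        return load_ontology(path)


def hierarchy_metrics(index: OntologyIndex, doid: str) -> tuple[bool, int, bool]:
    """Return ``(is_leaf, distance_from_root, is_obsolete)`` for a term.

    Distance is the shortest ``is_a`` path to the root (root itself is 0),
    found by breadth-first search; obsolete terms detached from the
    hierarchy report -1.
    """
    if doid not in index.terms:
        raise KeyError(f"unknown DOID: {doid}")
    term = index.terms[doid]
    is_leaf = not index.children.get(doid)
    if doid == index.root:
        return is_leaf, 0, term["obsolete"]

    dist = -1
    frontier = [doid]
    seen = {doid}
    depth = 0
    while frontier:
        depth += 1
        nxt: list[str] = []
        for node in frontier:
            for parent in index.terms.get(node, {}).get("parents", []):
                if parent == index.root:
                    return is_leaf, depth, term["obsolete"]
                if parent in index.terms and parent not in seen:
                    seen.add(parent)
                    nxt.append(parent)
        frontier = nxt
    return is_leaf, dist, term["obsolete"]


def descendants(index: OntologyIndex, doid: str) -> set[str]:
    """All DOIDs below ``doid`` in the is_a hierarchy (excluding itself)."""
    out: set[str] = set()
    frontier = [doid]
    while frontier:
        node = frontier.pop()
        for child in index.children.get(node, ()):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


@dataclass(frozen=True)
class DiseaseTag:
    """One DO annotation on a series, with hierarchy metrics."""

    doid: str
    term_name: str
    is_leaf: bool
    distance_from_root: int
    is_obsolete: bool
    matched_text: str
    field_source: str


_WORD_RE = re.compile(r"[A-Za-z][A-Za-z'\-]*")


def tag_text(index: OntologyIndex, text: str, field_source: str = "summary") -> list[DiseaseTag]:
    """Scan one text field for disease mentions.

    Greedy longest-match over word boundaries, case-insensitive, with
    plural→singular fallback on the last word of a phrase; shorter matches
    nested inside an accepted longer match are suppressed, and each DOID is
    reported once per field with its first matched span.
    """
    words = [(m.group(0), m.start(), m.end()) for m in _WORD_RE.finditer(text)]
    max_tokens = index.max_phrase_tokens
    tags: list[DiseaseTag] = []
    seen_doids: set[str] = set()
    i = 0
    while i < len(words):
        matched = None
        for n in range(min(max_tokens, len(words) - i), 0, -1):
            span_words = words[i:i + n]
            phrase = text[span_words[0][1]:span_words[-1][2]]
            norm = _normalize_surface(phrase)
            if n == 1 and norm in STOP_WORDS:
                continue
            doids = index.name_index.get(norm)
            if doids is None:
                tokens = norm.split(" ")
                tokens[-1] = _singularize(tokens[-1])
                doids = index.name_index.get(" ".join(tokens))
            if doids:
                matched = (n, phrase, doids)
                break
        if matched is None:
            i += 1
            continue
        n, phrase, doids = matched
        for doid in sorted(doids):
            if doid in seen_doids:
                continue
            seen_doids.add(doid)
            is_leaf, dist, obsolete = hierarchy_metrics(index, doid)
            tags.append(
                DiseaseTag(doid, index.terms[doid]["name"], is_leaf, dist,
                           obsolete, phrase, field_source)
            )
        i += n
    return tags


_FIELD_PRECEDENCE = ("title", "summary", "overall_design", "abstract", "organism")


def tag_series(index: OntologyIndex, meta: SeriesMetadata) -> list[DiseaseTag]:
    """Tag one series across its five annotated metadata fields.

    Fields are scanned in precedence order title > summary > overall
    design > citation abstract > organism; a DOID found in several fields
    is reported once, from the highest-precedence field.
    """
    field_text = {
        "title": meta.title,
        "summary": meta.summary,
        "overall_design": meta.overall_design,
        "abstract": meta.abstract,
        "organism": meta.organism,
    }
    out: list[DiseaseTag] = []
    seen: set[str] = set()
    for source in _FIELD_PRECEDENCE:
        for tag in tag_text(index, field_text[source], source):
            if tag.doid not in seen:
                seen.add(tag.doid)
                out.append(tag)
    return out
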