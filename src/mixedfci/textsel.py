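"""Embedding-based variable pre-selection.

Variable labels from a data dictionary and a list of target risk-factor
phrases are embedded; each variable is scored by its maximum cosine
similarity to any phrase, per backend.  A configurable rule (threshold per
backend combined by any/all/mean, or top-k per phrase) picks the candidate
set, and selection accuracy is the fraction of evaluable gold categories
covered by at least one selected variable.

Backends are pluggable.  The shipped :class:`HashEmbeddingBackend` is a
deterministic hash-seeded table over a controlled vocabulary in which tokens
of the same lexicon category cluster around a category anchor, so the
selection stage is testable without any pre-trained model.  Real word2vec
vectors in the standard *text* format can be loaded with
:func:`load_word2vec_text`.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np

from .data import VariableMeta

#: Shipped stopword list (versioned with the package): articles, auxiliaries,
#: pronouns and similar function words.  Deliberately small and curated —
#: content-bearing adverbs such as "ever" are kept.
STOPWORDS = frozenset(
    """a an the and or but if then than that this these those of in on at by for
    with to from into as is are was were be been being am do does did done has
    have had having will would shall should can could may might must not no nor
    it its he she his her they them their we us our you your i me my type other
    per""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def preprocess_text(raw: str) -> list[str]:
    """Lowercase, strip punctuation, drop stopwords; keeps original order."""
    return [t for t in _TOKEN_RE.findall(raw.lower()) if t not in STOPWORDS]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share a dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(np.dot(u, v) / (nu * nv))


class EmbeddingBackend:
    """Interface: word-level backends implement ``lookup``; document-level
    backends implement ``infer``.  Unknown tokens return None from lookup."""

    name: str = "backend"
    dimension: int = 0
    is_document_level: bool = False

    def lookup(self, token: str) -> np.ndarray | None:  # pragma: no cover - interface
        raise NotImplementedError

    def infer(self, tokens: list[str]) -> np.ndarray | None:  # pragma: no cover - interface
        raise NotImplementedError


def _hash_rng(*parts: str) -> np.random.Generator:
    digest = hashlib.sha256("\x1f".join(parts).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


class HashEmbeddingBackend(EmbeddingBackend):
    """Deterministic fixture backend.

    Every token in the controlled vocabulary gets a fixed unit vector: tokens
    belonging to a lexicon category sit near that category's anchor
    (anchor + ``spread`` · token noise, renormalised), so same-category tokens
    have high mutual cosine similarity; out-of-lexicon vocabulary tokens are
    pure hash noise.  Tokens outside the vocabulary are out-of-vocabulary.
    """

    def __init__(
        self,
        lexicon: dict[str, list[str]],
        extra_vocabulary: list[str] = (),
        dimension: int = 32,
        spread: float = 0.35,
        name: str = "hash-w2v",
    ):
        self.name = name
        self.dimension = dimension
        self._vectors: dict[str, np.ndarray] = {}
        for cat, words in lexicon.items():
            anchor = _hash_rng("anchor", name, cat).normal(size=dimension)
            anchor /= np.linalg.norm(anchor)
            for w in words:
                noise = _hash_rng("token", name, w).normal(size=dimension)
                vec = anchor + spread * noise / np.linalg.norm(noise)
                self._vectors[w] = vec / np.linalg.norm(vec)
            # the category name itself embeds at the anchor (multi-word names
            # contribute per word)
            for w in cat.split():
                self._vectors.setdefault(w, anchor)
        for w in extra_vocabulary:
            if w not in self._vectors:
                noise = _hash_rng("token", name, w).normal(size=dimension)
                self._vectors[w] = noise / np.linalg.norm(noise)

    def lookup(self, token: str) -> np.ndarray | None:
        return self._vectors.get(token)


class DocHashEmbeddingBackend(HashEmbeddingBackend):
    """Document-level twin of the fixture backend: infers a phrase vector as a
    length-weighted token average with a small deterministic phrase offset,
    standing in for a doc2vec-style model."""

    is_document_level = True

    def __init__(self, lexicon, extra_vocabulary=(), dimension=32, spread=0.35, name="hash-d2v"):
        super().__init__(lexicon, extra_vocabulary, dimension, spread, name)

    def infer(self, tokens: list[str]) -> np.ndarray | None:
        vecs = [self._vectors[t] for t in tokens if t in self._vectors]
        if not vecs:
            return None
        mean = np.mean(vecs, axis=0)
        offset = _hash_rng("doc", self.name, " ".join(tokens)).normal(size=self.dimension)
        vec = mean + 0.05 * offset / np.linalg.norm(offset)
        return vec / np.linalg.norm(vec)


class KeyedVectorsBackend(EmbeddingBackend):
    """Word-level backend over an in-memory token → vector table."""

    def __init__(self, table: dict[str, np.ndarray], name: str = "word2vec"):
        if not table:
            raise ValueError("empty vector table")
        self.name = name
        self._table = table
        self.dimension = len(next(iter(table.values())))

    def lookup(self, token: str) -> np.ndarray | None:
        return self._table.get(token)


def load_word2vec_text(path, name: str = "word2vec") -> KeyedVectorsBackend:
    """Load vectors from the standard word2vec text format
    (header ``n_words dim``, then ``token v1 ... vdim`` per line)."""
    table: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("expected 'n_words dim' header")
        dim = int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"malformed vector line for {parts[0]!r}")
            table[parts[0]] = np.array(parts[1:], dtype=float)
    return KeyedVectorsBackend(table, name=name)


def embed_phrase(tokens: list[str], backend: EmbeddingBackend) -> np.ndarray | None:
    """Mean of in-vocabulary token vectors (word-level) or ``infer`` output
    (document-level); None when nothing is scorable."""
    if not tokens:
        return None
    if backend.is_document_level:
        return backend.infer(tokens)
    vecs = [v for v in (backend.lookup(t) for t in tokens) if v is not None]
    if not vecs:
        return None
    return np.mean(vecs, axis=0)


@dataclass
class SelectionResult:
    variable: str
    best_phrase: str | None
    scores: dict[str, float]  # backend name -> best similarity over phrases
    phrase_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    selected: bool = False
    assigned_category: str | None = None
    scorable: bool = True


@dataclass
class SelectionReport:
    n_selected: int
    covered_categories: set[str]
    evaluable_categories: set[str]

    @property
    def accuracy(self) -> float:
        return len(self.covered_categories & self.evaluable_categories) / len(self.evaluable_categories)


@dataclass
class SelectionRule:
    """Threshold-or-top-k selection.

    Exactly one of ``threshold`` / ``top_k`` must be set.  ``threshold`` may be
    a single float (applied to every backend) or a per-backend map; ``combine``
    says how backends vote: "any" (default), "all", or "mean" (mean across
    backends exceeds the scalar threshold).
    """

    threshold: float | dict[str, float] | None = None
    top_k: int | None = None
    combine: str = "any"

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.top_k is None):
            raise ValueError("specify exactly one of threshold / top_k")
        if self.combine not in ("any", "all", "mean"):
            raise ValueError(f"unknown combine rule {self.combine!r}")
        if self.combine == "mean" and isinstance(self.threshold, dict):
            raise ValueError("mean-combination takes a scalar threshold")


def score_variables(
    dictionary: list[VariableMeta],
    phrases: list[str],
    backends: list[EmbeddingBackend],
) -> list[SelectionResult]:
    """Similarity of every variable label to every target phrase, per backend.

    The per-variable score under a backend is the maximum over phrases;
    ``best_phrase`` maximizes the mean score across backends (ties broken by
    phrase order).  Variables whose label has no in-vocabulary token under any
    backend are flagged unscorable, never dropped.
    """
    if not backends:
        raise ValueError("need at least one backend")
    if not phrases:
        raise ValueError("need at least one target phrase")
    phrase_vecs = {
        be.name: {ph: embed_phrase(preprocess_text(ph), be) for ph in phrases} for be in backends
    }
    results = []
    for var in dictionary:
        tokens = preprocess_text(var.label)
        per_backend: dict[str, dict[str, float]] = {}
        for be in backends:
            vvec = embed_phrase(tokens, be)
            if vvec is None or not np.linalg.norm(vvec):
                continue
            row = {}
            for ph in phrases:
                pvec = phrase_vecs[be.name][ph]
                if pvec is None or not np.linalg.norm(pvec):
                    continue
                row[ph] = cosine_similarity(vvec, pvec)
            if row:
                per_backend[be.name] = row
        if not per_backend:
            results.append(
                SelectionResult(var.name, None, {}, {}, selected=False, assigned_category=None, scorable=False)
            )
            continue
        mean_by_phrase = {
            ph: float(np.mean([row[ph] for row in per_backend.values() if ph in row]))
            for ph in phrases
            if any(ph in row for row in per_backend.values())
        }
        best_phrase = max(mean_by_phrase, key=lambda ph: (mean_by_phrase[ph], -phrases.index(ph)))
        results.append(
            SelectionResult(
                variable=var.name,
                best_phrase=best_phrase,
                scores={name: max(row.values()) for name, row in per_backend.items()},
                phrase_scores=per_backend,
                assigned_category=best_phrase,
            )
        )
    return results


def select_variables(results: list[SelectionResult], rule: SelectionRule) -> list[SelectionResult]:
    """Apply the selection rule; returns the same results with ``selected`` set."""
    if rule.top_k is not None:
        chosen: set[str] = set()
        phrases = sorted({ph for r in results for row in r.phrase_scores.values() for ph in row})
        for ph in phrases:
            scored = []
            for r in results:
                vals = [row[ph] for row in r.phrase_scores.values() if ph in row]
                if vals:
                    scored.append((float(np.mean(vals)), r.variable))
            scored.sort(key=lambda t: (-t[0], t[1]))
            chosen.update(v for _, v in scored[: rule.top_k])
        for r in results:
            r.selected = r.scorable and r.variable in chosen
        return results

    thr = rule.threshold
    for r in results:
        if not r.scorable:
            r.selected = False
            continue
        if rule.combine == "mean":
            r.selected = bool(np.mean(list(r.scores.values())) >= thr)
            continue
        votes = []
        for name, s in r.scores.items():
            t = thr[name] if isinstance(thr, dict) else thr
            votes.append(s >= t)
        r.selected = any(votes) if rule.combine == "any" else all(votes)
    return results


def evaluate_selection(
    selected: list[SelectionResult],
    gold: dict[str, set[str]],
    excluded_categories: set[str] = frozenset(),
) -> SelectionReport:
    """Coverage accuracy: a gold category is covered iff at least one selected
    variable belongs to it; accuracy = covered / evaluable."""
    if not gold:
        raise ValueError("gold standard must be non-empty")
    evaluable = set(gold) - set(excluded_categories)
    if not evaluable:
        raise ValueError("all categories excluded — accuracy undefined")
    chosen = {r.variable for r in selected if r.selected}
    covered = {c for c in evaluable if gold[c] & chosen}
    return SelectionReport(
        n_selected=len(chosen),
        covered_categories=covered,
        evaluable_categories=evaluable,
    )


def write_scores_tsv(results: list[SelectionResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("variable\tphrase\tbackend\tscore\tselected\n")
        for r in results:
            if not r.scorable:
                fh.write(f"{r.variable}\tNA\tNA\tNA\t{r.selected}\n")
                continue
            for backend, row in sorted(r.phrase_scores.items()):
                for ph, s in sorted(row.items()):
                    fh.write(f"{r.variable}\t{ph}\t{backend}\t{s:.6f}\t{r.selected}\n")
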