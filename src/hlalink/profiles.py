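"""Literature concept profiles and cohesion scoring.

A concept profile is a weight vector over a gene vocabulary that
quantifies how strongly each gene's literature co-occurs with a concept
(a disease, a gene, ...).  Weights are the symmetric uncertainty
coefficient U(C,G) = 2*I(C;G) / (H(C)+H(G)) computed over per-document
binary occurrence indicators, with U := 0 when the concept and gene
never co-occur or when both indicators are constant.  The similarity of
two profiles is their inner product (cohesion score), which decomposes
additively into per-gene contributions; significance is assessed by a
permutation null over random profile groups drawn from a caller-supplied
pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Corpus",
    "ConceptProfile",
    "CohesionResult",
    "symmetric_uncertainty",
    "build_profile",
    "cohesion_score",
    "contributions",
    "permutation_p",
    "read_corpus",
    "write_corpus",
    "read_profile",
    "write_profile",
]


@dataclass(frozen=True)
class Corpus:
    """Documents as (doc_id, set-of-concept-ids) records.

    Genes and query concepts live in one identifier space; a document's
    concept set is the pre-disambiguated result of upstream indexing.
    """

    documents: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        ids = [d for d, _ in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_ids in corpus")
        if any(not c for _, c in self.documents):
            raise ValueError("empty concept set in corpus")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, Iterable[str]]]) -> "Corpus":
        return cls(tuple((d, frozenset(c)) for d, c in records))

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    def concepts(self) -> frozenset[str]:
        out: set[str] = set()
        for _, c in self.documents:
            out |= c
        return frozenset(out)

    def occurrence_vector(self, concept_id: str) -> np.ndarray:
        return np.array([concept_id in c for _, c in self.documents], dtype=bool)


@dataclass(frozen=True)
class ConceptProfile:
    """Gene -> weight mapping for one concept; zero weights are not stored."""

    concept_id: str
    weights: Mapping[str, float]
    vocabulary_size: int

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("profile weights must be >= 0")
        if self.vocabulary_size < len(self.weights):
            raise ValueError("vocabulary_size smaller than number of stored weights")


@dataclass(frozen=True)
class CohesionResult:
    cs: float
    p_value: float
    iterations: int
    contributions: tuple[tuple[str, float], ...] = field(default_factory=tuple)


def _entropy(counts: Sequence[int]) -> float:
    """Shannon entropy (nats) of a discrete distribution given by counts."""
    n = sum(counts)
    return -sum((c / n) * math.log(c / n) for c in counts if c > 0)


def symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """U(X,Y) = 2*I(X;Y)/(H(X)+H(Y)) for two binary indicator vectors.

    Defined as 0 when H(X)+H(Y) = 0 or when x and y are never jointly
    true (no observed co-occurrence).
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("indicator vectors must have equal length")
    n = x.size
    n11 = int(np.count_nonzero(x & y))
    if n11 == 0:
        return 0.0
    n10 = int(np.count_nonzero(x & ~y))
    n01 = int(np.count_nonzero(~x & y))
    n00 = n - n11 - n10 - n01
    hx = _entropy([n11 + n10, n01 + n00])
    hy = _entropy([n11 + n01, n10 + n00])
    if hx + hy == 0:
        return 0.0
    hxy = _entropy([n11, n10, n01, n00])
    mi = hx + hy - hxy
    # clamp tiny negative round-off
    return max(0.0, 2.0 * mi / (hx + hy))


def build_profile(corpus: Corpus, concept_id: str, gene_vocabulary: Iterable[str]) -> ConceptProfile:
    """Build a concept profile over ``gene_vocabulary``.

    The concept itself may be part of the vocabulary (a gene is maximally
    associated with its own literature).  Genes with weight 0 are not
    stored but still count toward ``vocabulary_size``.
    """
    vocabulary = sorted(set(gene_vocabulary))
    if not vocabulary:
        raise ValueError("gene vocabulary is empty")
    cvec = corpus.occurrence_vector(concept_id)
    if not cvec.any():
        raise ValueError(f"concept {concept_id!r} does not occur in the corpus")
    weights: dict[str, float] = {}
    for gene in vocabulary:
        u = symmetric_uncertainty(cvec, corpus.occurrence_vector(gene))
        if u > 0:
            weights[gene] = u
    return ConceptProfile(concept_id=concept_id, weights=weights, vocabulary_size=len(vocabulary))


def cohesion_score(profile_a: ConceptProfile, profile_b: ConceptProfile) -> float:
    """Inner product of two profiles over their shared vocabulary."""
    if profile_a.vocabulary_size != profile_b.vocabulary_size:
        raise ValueError(
            "profiles are defined over different vocabularies "
            f"({profile_a.vocabulary_size} vs {profile_b.vocabulary_size} genes)"
        )
    small, large = profile_a.weights, profile_b.weights
    if len(small) > len(large):
        small, large = large, small
    return sum(w * large[g] for g, w in small.items() if g in large)


def contributions(
    profile_a: ConceptProfile,
    profile_b: ConceptProfile,
    threshold_percent: float = 0.0,
) -> list[tuple[str, float]]:
    """Per-gene share (percent) of the cohesion score.

    Only genes contributing strictly more than ``threshold_percent`` are
    returned, sorted by decreasing percentage with ties broken by gene id.
    """
    cs = cohesion_score(profile_a, profile_b)
    if cs <= 0:
        raise ValueError("cohesion score is zero: no similarity to decompose")
    rows = []
    for gene, wa in profile_a.weights.items():
        wb = profile_b.weights.get(gene)
        if wb is None:
            continue
        percent = 100.0 * wa * wb / cs
        if percent > threshold_percent:
            rows.append((gene, percent))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def _group_score(profiles: Sequence[ConceptProfile]) -> float:
    """Cohesion of a profile group: mean pairwise score (= the pair score for size 2)."""
    pairs = list(combinations(profiles, 2))
    return sum(cohesion_score(a, b) for a, b in pairs) / len(pairs)


def permutation_p(
    cs_observed: float,
    profile_pool: Sequence[ConceptProfile],
    group_size: int = 2,
    iterations: int = 200,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation P-value for an observed cohesion score.

    Draws ``iterations`` random groups of ``group_size`` distinct
    profiles from the pool and returns (r+1)/(iterations+1) where r is
    the number of null group scores >= ``cs_observed``.  The +1
    correction keeps the estimate away from an unattainable exact zero.
    """
    pool = list(profile_pool)
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    if len(pool) < group_size:
        raise ValueError(f"profile pool (size {len(pool)}) smaller than group_size {group_size}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = 0
    for _ in range(iterations):
        idx = rng.choice(len(pool), size=group_size, replace=False)
        if _group_score([pool[i] for i in idx]) >= cs_observed:
            r += 1
    return (r + 1) / (iterations + 1)


# ---------------------------------------------------------------------------
# I/O: one document per line "doc_id<TAB>concept;concept;...", '#' comments

def read_corpus(path: str | Path) -> Corpus:
    records = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: expected 'doc_id<TAB>concept;concept;...'")
            doc_id, concepts = parts
            records.append((doc_id, [c.strip() for c in concepts.split(";") if c.strip()]))
    return Corpus.from_records(records)


def write_corpus(corpus: Corpus, path: str | Path, header_comment: str = "") -> None:
    with Path(path).open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for doc_id, concepts in corpus.documents:
            fh.write(f"{doc_id}\t{';'.join(sorted(concepts))}\n")


def read_profile(path: str | Path) -> ConceptProfile:
    """Read a profile TSV: '# concept_id=...', '# vocabulary_size=...' then gene/weight rows."""
    concept_id = None
    vocabulary_size = None
    weights: dict[str, float] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("concept_id="):
                    concept_id = body.split("=", 1)[1]
                elif body.startswith("vocabulary_size="):
                    vocabulary_size = int(body.split("=", 1)[1])
                continue
            if line.startswith("gene\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>weight'")
            weights[parts[0]] = float(parts[1])
    if concept_id is None:
        raise ValueError(f"{path}: missing '# concept_id=' header")
    if vocabulary_size is None:
        vocabulary_size = len(weights)
    return ConceptProfile(concept_id=concept_id, weights=weights, vocabulary_size=vocabulary_size)


def write_profile(profile: ConceptProfile, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# concept_id={profile.concept_id}\n")
        fh.write(f"# vocabulary_size={profile.vocabulary_size}\n")
        fh.write("gene\tweight\n")
        for gene in sorted(profile.weights):
            fh.write(f"{gene}\t{profile.weights[gene]:.12g}\n")
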