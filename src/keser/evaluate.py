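"""Scoring embeddings against curated similar/related code pairs.

Known relationship pairs (disease-disease, disease-drug, drug-drug,
lab-lab) are scored by the cosine similarity of their embedding vectors
against a reference distribution of randomly sampled pairs of the same
relation type.  Accuracy is summarized by the AUC (rank probability that a
known pair outscores a random pair) and by sensitivity at fixed false
positive rates, with the classification threshold set at an empirical
quantile of the null-score distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .embed import EmbeddingSet
from .io import Vocabulary, code_type

__all__ = [
    "RelationPair",
    "RelationPairSet",
    "DetectionReport",
    "make_pair_type",
    "cosine",
    "pair_scores",
    "sample_null_pairs",
    "auc",
    "sensitivity_at_fpr",
    "evaluate",
]


def make_pair_type(code_a: str, code_b: str) -> str:
    """Canonical relation-type label, e.g. 'PheCode-RXNORM' (sorted)."""
    return "-".join(sorted((code_type(code_a), code_type(code_b))))


@dataclass(frozen=True)
class RelationPair:
    a: str
    b: str
    relation_class: str = "related"  # similar | related
    pair_type: str = ""
    source: str = ""

    def __post_init__(self):
        if not self.pair_type:
            object.__setattr__(self, "pair_type", make_pair_type(self.a, self.b))

    @property
    def key(self) -> tuple:
        return (frozenset((self.a, self.b)), self.relation_class)


class RelationPairSet:
    """Deduplicated unordered code pairs with relation class and type."""

    def __init__(self, pairs: Iterable[RelationPair]):
        seen: dict[tuple, RelationPair] = {}
        for p in pairs:
            seen.setdefault(p.key, p)
        self.pairs: list[RelationPair] = list(seen.values())

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, other: RelationPair) -> bool:
        return other.key in {p.key for p in self.pairs}

    def union(self, *others: "RelationPairSet") -> "RelationPairSet":
        out = list(self.pairs)
        for o in others:
            out.extend(o.pairs)
        return RelationPairSet(out)

    def of_type(self, pair_type: str, relation_class: str | None = None) -> "RelationPairSet":
        return RelationPairSet(
            p
            for p in self.pairs
            if p.pair_type == pair_type
            and (relation_class is None or p.relation_class == relation_class)
        )

    def code_keys(self) -> set[frozenset]:
        return {frozenset((p.a, p.b)) for p in self.pairs}

    def resolve(self, vocab: Vocabulary) -> tuple["RelationPairSet", list[RelationPair]]:
        """Split into pairs resolvable against *vocab* and those dropped.

        Unresolvable curated pairs are a real phenomenon (knowledge-source
        concepts that do not map onto a site's codes), so they are counted
        and returned rather than silently discarded.
        """
        ok, dropped = [], []
        for p in self.pairs:
            (ok if p.a in vocab and p.b in vocab else dropped).append(p)
        if dropped:
            warnings.warn(f"{len(dropped)} curated pair(s) not resolvable against vocabulary")
        return RelationPairSet(ok), dropped

    # -- persistence -------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            [(p.a, p.b, p.relation_class, p.pair_type, p.source) for p in self.pairs],
            columns=["code_a", "code_b", "relation_class", "pair_type", "source"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RelationPairSet":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(
            RelationPair(r.code_a, r.code_b, r.relation_class or "related", r.pair_type, r.source)
            for r in df.itertuples()
        )


def cosine(emb: EmbeddingSet, a: str, b: str) -> float:
    """Cosine similarity between the embedding vectors of two codes."""
    va, vb = emb.vector(a), emb.vector(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        bad = a if na == 0 else b
        raise ValueError(f"cosine undefined: code {bad!r} has a zero-norm vector")
    return float(va @ vb / (na * nb))


def pair_scores(emb: EmbeddingSet, pairs: RelationPairSet) -> np.ndarray:
    """Vectorized cosine similarities for every pair in the set."""
    if len(pairs) == 0:
        return np.empty(0)
    U = emb.rows_normalized()
    ia = np.array([emb.vocab.index(p.a) for p in pairs])
    ib = np.array([emb.vocab.index(p.b) for p in pairs])
    return np.einsum("ij,ij->i", U[ia], U[ib])


def _type_members(vocab: Vocabulary, pair_type: str) -> tuple[list[str], list[str]]:
    ta, tb = pair_type.split("-", 1)
    return list(vocab.of_type(ta)), list(vocab.of_type(tb))


def n_available_pairs(vocab: Vocabulary, pair_type: str, exclude: RelationPairSet | None = None) -> int:
    """Distinct unordered non-self pairs of the type, minus excluded ones."""
    A, B = _type_members(vocab, pair_type)
    if pair_type.split("-", 1)[0] == pair_type.split("-", 1)[1]:
        total = len(A) * (len(A) - 1) // 2
    else:
        total = len(A) * len(B)
    if exclude is not None:
        sa, sb = set(A), set(B)
        total -= sum(
            1
            for k in exclude.code_keys()
            if (lambda pair: any(x in sa for x in pair) and any(x in sb for x in pair) and len(pair) == 2)(k)
        )
    return max(total, 0)


def sample_null_pairs(
    vocab: Vocabulary,
    pair_type: str,
    n: int,
    seed: int = 0,
    exclude: RelationPairSet | None = None,
) -> RelationPairSet:
    """Sample n distinct random unordered code pairs of the given type.

    Self-pairs and pairs in *exclude* are never drawn; the sample is a
    deterministic function of the seed.
    """
    A, B = _type_members(vocab, pair_type)
    same = pair_type.split("-", 1)[0] == pair_type.split("-", 1)[1]
    avail = n_available_pairs(vocab, pair_type, exclude)
    if n > avail:
        raise ValueError(f"requested {n} null pairs but only {avail} distinct pairs available")
    banned = exclude.code_keys() if exclude is not None else set()
    rng = np.random.default_rng(seed)
    out: dict[frozenset, RelationPair] = {}
    while len(out) < n:
        batch = max(4 * (n - len(out)), 16)
        ia = rng.integers(0, len(A), size=batch)
        ib = rng.integers(0, len(B), size=batch)
        for x, y in zip(ia, ib):
            a, b = A[x], B[y]
            if a == b:
                continue
            key = frozenset((a, b))
            if key in banned or key in out:
                continue
            out[key] = RelationPair(a, b, "null", pair_type, "random")
            if len(out) == n:
                break
    return RelationPairSet(out.values())


def auc(known_scores, null_scores) -> float:
    """Mann-Whitney probability that a known score exceeds a null score.

    Ties count one half.  Equivalent to the area under the ROC curve of the
    score as a classifier of known vs. null pairs.
    """
    known = np.asarray(known_scores, dtype=float)
    null = np.asarray(null_scores, dtype=float)
    if known.size == 0 or null.size == 0:
        raise ValueError("score lists must be non-empty")
    ranks = rankdata(np.concatenate([known, null]))
    rk = ranks[: known.size].sum()
    return float((rk - known.size * (known.size + 1) / 2) / (known.size * null.size))


def sensitivity_at_fpr(known_scores, null_scores, fpr: float) -> float:
    """Fraction of known scores above the (1 - fpr) null quantile.

    The threshold uses the "higher" interpolation of the empirical null
    distribution and exceedance is strict, so the realized FPR on the null
    sample never exceeds the nominal one.
    """
    known = np.asarray(known_scores, dtype=float)
    null = np.asarray(null_scores, dtype=float)
    if known.size == 0 or null.size == 0:
        raise ValueError("score lists must be non-empty")
    if not 0.0 < fpr < 1.0:
        raise ValueError("fpr must be in (0, 1)")
    threshold = np.quantile(null, 1.0 - fpr, method="higher")
    return float(np.mean(known > threshold))


@dataclass
class DetectionReport:
    """Per relation-type accuracy of cosine similarity as a pair detector."""

    pair_type: str
    relation_class: str
    n_known: int
    n_null: int
    auc: float
    sensitivity_at: dict[float, float]
    thresholds: dict[float, float]
    seed: int
    n_unresolved: int = 0

    def to_dict(self) -> dict:
        return {
            "pair_type": self.pair_type,
            "relation_class": self.relation_class,
            "n_known": self.n_known,
            "n_null": self.n_null,
            "auc": self.auc,
            "sensitivity_at": {str(k): v for k, v in self.sensitivity_at.items()},
            "thresholds": {str(k): v for k, v in self.thresholds.items()},
            "seed": self.seed,
            "n_unresolved": self.n_unresolved,
        }


def evaluate(
    emb: EmbeddingSet,
    pairs: RelationPairSet,
    n_null: int | None = None,
    seed: int = 0,
    fprs: tuple[float, ...] = (0.01, 0.05, 0.10),
) -> list[DetectionReport]:
    """Score known pairs against sampled nulls, per relation type and class.

    ``n_null`` defaults to 10x the known-pair count of each stratum,
    capped at the number of distinct pairs available.
    """
    resolved, dropped = pairs.resolve(emb.vocab)
    reports = []
    strata = sorted({(p.pair_type, p.relation_class) for p in resolved})
    for ptype, rclass in strata:
        known = resolved.of_type(ptype, rclass)
        if len(known) == 0:
            continue
        want = n_null if n_null is not None else 10 * len(known)
        avail = n_available_pairs(emb.vocab, ptype, exclude=resolved)
        if avail == 0:
            warnings.warn(f"no null pairs available for type {ptype}; stratum skipped")
            continue
        nulls = sample_null_pairs(emb.vocab, ptype, min(want, avail), seed=seed, exclude=resolved)
        ks = pair_scores(emb, known)
        ns = pair_scores(emb, nulls)
        sens = {f: sensitivity_at_fpr(ks, ns, f) for f in fprs}
        thr = {f: float(np.quantile(ns, 1.0 - f, method="higher")) for f in fprs}
        reports.append(
            DetectionReport(
                ptype, rclass, len(known), len(nulls), auc(ks, ns), sens, thr, seed,
                n_unresolved=sum(1 for p in dropped if p.pair_type == ptype and p.relation_class == rclass),
            )
        )
    return reports


def save_reports(reports: list[DetectionReport], path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=1))
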