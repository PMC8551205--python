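"""Cross-site code translation via orthogonal embedding alignment.

Two healthcare systems' embeddings live in different bases even when the
underlying clinical structure is shared.  Over codes common to both sites,
an orthogonal matrix Q minimizing ||V_tgt - V_src Q||_F (the orthogonal
Procrustes problem, solved in closed form from the SVD of V_src^T V_tgt)
aligns the source space to the target.  A source-only code is then
translated by mapping its vector through Q and ranking target codes by
cosine similarity, reported as top-1/5/10 accuracy on held-out pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .embed import EmbeddingSet
from .io import code_type

__all__ = ["OrthogonalMap", "fit_orthogonal_map", "topk_accuracy"]


@dataclass
class OrthogonalMap:
    """A d x d orthogonal alignment matrix with its training provenance."""

    Q: np.ndarray
    train_codes: tuple[str, ...]
    d: int
    normalized: bool = True

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        err = np.linalg.norm(self.Q.T @ self.Q - np.eye(self.d))
        if err > 1e-8:
            raise ValueError(f"map is not orthogonal (||Q^T Q - I||_F = {err:.2e})")

    def save(self, prefix) -> None:
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".tsv"), self.Q, delimiter="\t", fmt="%.17g")
        meta = {"d": self.d, "normalized": self.normalized, "train_codes": list(self.train_codes)}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "OrthogonalMap":
        prefix = Path(prefix)
        Q = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(Q, tuple(meta["train_codes"]), meta["d"], meta["normalized"])


def _rows(emb: EmbeddingSet, codes, normalize: bool) -> np.ndarray:
    M = np.stack([emb.vector(c) for c in codes])
    if normalize:
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        M = M / norms
    return M


def fit_orthogonal_map(
    src: EmbeddingSet, tgt: EmbeddingSet, shared: list[str], normalize: bool = True
) -> OrthogonalMap:
    """Closed-form Procrustes fit of Q = argmin ||V_tgt - V_src Q||_F.

    Rows are unit-normalized before fitting (``normalize=True``), matching
    cosine-based ranking downstream.  With fewer shared codes than the
    embedding dimension the problem is underdetermined; a warning is
    raised but the minimizer is still returned.
    """
    if src.d != tgt.d:
        raise ValueError(f"dimension mismatch: src d={src.d}, tgt d={tgt.d}")
    shared = [c for c in shared]
    if not shared:
        raise ValueError("shared code list is empty")
    missing = [c for c in shared if c not in src.vocab or c not in tgt.vocab]
    if missing:
        raise ValueError(f"shared codes absent from an embedding set: {missing[:5]}")
    if len(shared) < src.d:
        warnings.warn(
            f"only {len(shared)} shared codes for a {src.d}-dimensional map; fit is underdetermined"
        )
    A = _rows(src, shared, normalize)
    B = _rows(tgt, shared, normalize)
    Q, _ = orthogonal_procrustes(A, B)
    return OrthogonalMap(Q, tuple(shared), src.d, normalized=normalize)


def topk_accuracy(
    src: EmbeddingSet,
    mapping: OrthogonalMap,
    tgt: EmbeddingSet,
    test_pairs: list[tuple[str, str]],
    k: int,
    within_type: bool = True,
) -> float:
    """Fraction of test codes whose true translation ranks in the top k.

    Each source vector is mapped through Q and scored by cosine against the
    target vocabulary — restricted to the query's code-type namespace by
    default (a medication query ranks against medications).  Ties are
    broken by lexicographic code order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    overlap = [s for s, _ in test_pairs if s in mapping.train_codes]
    if overlap:
        warnings.warn(f"{len(overlap)} test source code(s) were used to train the map")
    for s, t in test_pairs:
        if s not in src.vocab or t not in tgt.vocab:
            raise ValueError(f"test pair ({s!r}, {t!r}) not resolvable")

    tgt_codes_all = list(tgt.vocab.codes)
    hits = 0
    for s, true_t in test_pairs:
        if within_type:
            qtype = code_type(s)
            cand = [c for c in tgt_codes_all if code_type(c) == qtype]
        else:
            cand = tgt_codes_all
        M = _rows(tgt, cand, mapping.normalized)
        v = src.vector(s) @ mapping.Q
        if mapping.normalized:
            nv = np.linalg.norm(v)
            v = v / nv if nv > 0 else v
        scores = M @ v
        ranked = sorted(zip(cand, scores), key=lambda t_: (-t_[1], t_[0]))
        if true_t in [c for c, _ in ranked[:k]]:
            hits += 1
    return hits / len(test_pairs)
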