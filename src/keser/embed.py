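"""Shifted-positive-PMI matrices and their spectral embeddings.

The SPPMI entry for a code pair (w, c) is

    SPPMI(w, c) = max{ log[ C(w,c) |D| / (C(w,.) C(c,.)) ] - log k, 0 }

where C is the symmetric co-occurrence matrix, C(w,.) its row sums, |D| its
grand total and k the negative-sampling shift (k = 1 means no shift).  The
embedding of code w is the w-th row of V_d = U_d diag(sqrt(l_1..l_d)), where
U_d holds the top-d singular vectors of the SPPMI matrix.  Because the
matrix is symmetric, singular triplets are obtained from a full symmetric
eigendecomposition ordered by |eigenvalue|; this makes the factorization
deterministic and makes truncation to a smaller dimension an exact column
slice of the larger factorization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .cooccur import CooccurrenceMatrix
from .io import Vocabulary

__all__ = [
    "SPPMIMatrix",
    "EmbeddingSet",
    "compute_sppmi",
    "factorize",
    "select_dim_variance",
    "select_dim_metric",
]


@dataclass
class SPPMIMatrix:
    """Sparse symmetric matrix of non-negative SPPMI values."""

    vocab: Vocabulary
    S: sp.csr_matrix
    shift_k: float = 1.0

    def __post_init__(self):
        self.S = sp.csr_matrix(self.S)

    def save(self, path) -> None:
        path = Path(path)
        scipy.io.mmwrite(str(path), sp.coo_matrix(self.S))
        self.vocab.save(path.with_suffix(path.suffix + ".vocab"))

    @classmethod
    def load(cls, path, shift_k: float = 1.0) -> "SPPMIMatrix":
        path = Path(path)
        S = sp.csr_matrix(scipy.io.mmread(str(path)))
        vocab = Vocabulary.load(path.with_suffix(path.suffix + ".vocab"))
        return cls(vocab, S, shift_k)


def compute_sppmi(C: CooccurrenceMatrix, k: float = 1.0, include_diagonal: bool = True) -> SPPMIMatrix:
    """Shifted positive PMI of a co-occurrence matrix.

    ``k`` is the negative-sample shift (default 1, i.e. no shifting; 5 and
    10 are the usual sensitivity settings).  Cells with zero counts map to
    0, never -inf, and explicit zeros are dropped from the result.  With
    ``include_diagonal=False`` the marginals C(w,.) exclude same-code
    (diagonal) co-occurrences.
    """
    if k <= 0:
        raise ValueError("shift k must be positive")
    M = sp.coo_matrix(C.C)
    if include_diagonal:
        row_sums = C.row_sums.astype(float)
    else:
        row_sums = C.row_sums.astype(float) - C.C.diagonal()
    total = float(row_sums.sum()) if not include_diagonal else float(C.total)
    zero_rows = row_sums == 0
    if zero_rows.any() and M.nnz:
        touched = zero_rows[M.row] | zero_rows[M.col]
        if touched.any():
            warnings.warn("codes with zero marginal count produce all-zero SPPMI rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = row_sums[M.row] * row_sums[M.col]
        val = np.log(M.data * total / denom) - np.log(k)
    val = np.where(np.isfinite(val), val, 0.0)
    keep = val > 0
    S = sp.coo_matrix((val[keep], (M.row[keep], M.col[keep])), shape=M.shape).tocsr()
    return SPPMIMatrix(C.vocab, S, shift_k=float(k))


@dataclass
class EmbeddingSet:
    """Code vocabulary plus d-dimensional embedding vectors.

    ``V`` has one row per code; when produced by :func:`factorize`,
    V = U_d diag(sqrt(l_1..l_d)) and ``singular_values`` holds l_1 >= ... >=
    l_d >= 0.  ``spectrum_signs`` records the sign of the corresponding
    eigenvalue of the (possibly indefinite) symmetric source matrix, which
    is what the full-rank reconstruction U S W^T needs.
    """

    vocab: Vocabulary
    V: np.ndarray
    singular_values: np.ndarray | None = None
    spectrum_signs: np.ndarray | None = None
    shift_k: float | None = None

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        if self.V.shape[0] != len(self.vocab):
            raise ValueError("embedding rows must match vocabulary size")
        if self.singular_values is not None:
            self.singular_values = np.asarray(self.singular_values, dtype=float)

    @property
    def d(self) -> int:
        return self.V.shape[1]

    def vector(self, code: str) -> np.ndarray:
        return self.V[self.vocab.index(code)]

    def truncate(self, d: int) -> "EmbeddingSet":
        """First d columns — identical to refactorizing the source at d."""
        if not 1 <= d <= self.d:
            raise ValueError(f"d must be in [1, {self.d}]")
        return EmbeddingSet(
            self.vocab,
            self.V[:, :d],
            None if self.singular_values is None else self.singular_values[:d],
            None if self.spectrum_signs is None else self.spectrum_signs[:d],
            self.shift_k,
        )

    def rows_normalized(self) -> np.ndarray:
        norms = np.linalg.norm(self.V, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.V / norms
        return np.where(np.isfinite(out), out, 0.0)

    def reconstruct(self) -> np.ndarray:
        """U S W^T for the retained triplets; equals V diag(signs) V^T."""
        if self.spectrum_signs is None:
            raise ValueError("no spectrum signs recorded; not a factorization product")
        return (self.V * self.spectrum_signs) @ self.V.T

    # -- persistence -------------------------------------------------------

    def save(self, prefix) -> None:
        """TSV of (code, v1..vd) plus a JSON sidecar with the spectrum."""
        prefix = Path(prefix)
        df = pd.DataFrame(self.V, columns=[f"v{i+1}" for i in range(self.d)])
        df.insert(0, "code", list(self.vocab.codes))
        df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False, float_format="%.17g")
        meta = {
            "d": self.d,
            "vocab_hash": self.vocab.content_hash(),
            "shift_k": self.shift_k,
            "singular_values": None if self.singular_values is None else self.singular_values.tolist(),
            "spectrum_signs": None if self.spectrum_signs is None else self.spectrum_signs.tolist(),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "EmbeddingSet":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", dtype={"code": str})
        vocab = Vocabulary(tuple(df["code"]))
        V = df.drop(columns="code").to_numpy(dtype=float)
        meta = {}
        sidecar = prefix.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        sv = meta.get("singular_values")
        sg = meta.get("spectrum_signs")
        return cls(
            vocab,
            V,
            None if sv is None else np.asarray(sv, float),
            None if sg is None else np.asarray(sg, float),
            meta.get("shift_k"),
        )


def factorize(S: SPPMIMatrix, d: int) -> EmbeddingSet:
    """Top-d spectral embedding V_d = U_d diag(sqrt(l)) of a symmetric SPPMI.

    Singular triplets come from the dense symmetric eigendecomposition
    ordered by decreasing |eigenvalue| (stable sort, so ties resolve
    deterministically); each singular vector's sign is fixed by making its
    largest-magnitude entry positive.  The output is therefore bit-for-bit
    reproducible, and truncating the result to d' < d columns equals
    factorizing directly at d'.
    """
    n = len(S.vocab)
    if not 1 <= d <= n:
        raise ValueError(f"d must be in [1, {n}]")
    A = np.asarray(S.S.todense(), dtype=float)
    A = (A + A.T) / 2.0
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(-np.abs(vals), kind="stable")
    vals = vals[order][:d]
    vecs = vecs[:, order][:, :d]
    # sign convention: largest-|entry| of each eigenvector made positive
    anchor = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[anchor, np.arange(d)])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    sigma = np.abs(vals)
    V = vecs * np.sqrt(sigma)
    return EmbeddingSet(
        S.vocab,
        V,
        singular_values=sigma,
        spectrum_signs=np.sign(vals) + (vals == 0),
        shift_k=S.shift_k,
    )


def select_dim_variance(singular_values, fraction: float = 0.95, squared: bool = True) -> int:
    """Smallest d retaining the requested fraction of spectral variation.

    With ``squared=True`` (default) the retained share is cumulative squared
    singular values over their total — variance explained; ``squared=False``
    uses unsquared singular values.
    """
    sv = np.asarray(singular_values, dtype=float)
    if sv.size == 0:
        raise ValueError("empty spectrum")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    mass = sv**2 if squared else sv
    total = mass.sum()
    if total == 0:
        return 1
    cum = np.cumsum(mass) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def select_dim_metric(
    emb: EmbeddingSet,
    pairs,
    metric: str = "auc",
    grid=None,
    n_null: int | None = None,
    seed: int = 0,
) -> int:
    """Pick the embedding dimension on a grid by SNR or AUC against known pairs.

    For each candidate d the embeddings are truncated to d and cosine
    similarities of the known pairs are scored against random same-type
    pairs.  SNR(d) = W_d / S_d is the ratio of the mean known-pair cosine to
    the mean random-pair cosine; AUC(d) is the rank probability that a known
    pair outscores a random one.  Returns the grid value maximizing the
    metric, smallest d on ties.
    """
    from .evaluate import auc as _auc
    from .evaluate import pair_scores, sample_null_pairs

    if metric not in ("snr", "auc"):
        raise ValueError(f"unknown metric {metric!r}")
    if grid is None:
        grid = [emb.d]
    grid = sorted(int(g) for g in grid)
    if grid[-1] > emb.d:
        raise ValueError("grid dimension exceeds embedding dimension")
    resolved = pairs.resolve(emb.vocab)[0]
    if len(resolved) == 0:
        raise ValueError("no resolvable known pairs")
    if n_null is None:
        n_null = 10 * len(resolved)
    nulls = []
    for ptype in sorted({p.pair_type for p in resolved}):
        n_type = sum(p.pair_type == ptype for p in resolved)
        nulls.append(
            sample_null_pairs(
                emb.vocab, ptype, max(1, n_null * n_type // len(resolved)), seed=seed, exclude=resolved
            )
        )
    null_pairs = nulls[0] if len(nulls) == 1 else nulls[0].union(*nulls[1:])

    best_d, best_score = None, -np.inf
    for g in grid:
        sub = emb.truncate(g)
        known_scores = pair_scores(sub, resolved)
        null_scores = pair_scores(sub, null_pairs)
        if metric == "snr":
            denom = np.mean(null_scores)
            score = np.mean(known_scores) / denom if denom != 0 else np.inf
        else:
            score = _auc(known_scores, null_scores)
        if score > best_score + 1e-12:
            best_d, best_score = g, score
    return int(best_d)
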