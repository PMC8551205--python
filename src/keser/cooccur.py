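"""Within-window co-occurrence counting over patient event streams.

For each patient, every occurrence of a target code on day t is paired with
every occurrence of a context code on day t' with 0 <= t' - t <= window.
Only forward pairs are tallied; the returned matrix is the symmetrized
aggregate (directed tally plus its transpose), which is identical to counting
co-occurrences within +/- window days of the target.  Same-day unordered
pairs are counted once before symmetrization so that each contributes a
single unit to C(w, c) and C(c, w).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .io import EventTable, Vocabulary

__all__ = ["CooccurrenceMatrix", "count_cooccurrence"]


@dataclass
class CooccurrenceMatrix:
    """Symmetric sparse counts C(w, c) with marginals and grand total.

    ``row_sums`` is C(w, .), the row sum of C, and ``total`` is |D|, the
    grand sum — the symbols entering the shifted-PMI computation.
    """

    vocab: Vocabulary
    C: sp.csr_matrix

    def __post_init__(self):
        self.C = sp.csr_matrix(self.C)
        if self.C.shape != (len(self.vocab), len(self.vocab)):
            raise ValueError("matrix shape does not match vocabulary size")

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.C.sum(axis=1)).ravel()

    @property
    def total(self) -> int:
        return int(self.C.sum())

    def is_symmetric(self) -> bool:
        return (self.C != self.C.T).nnz == 0

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Write MatrixMarket coordinate format with a vocabulary sidecar."""
        path = Path(path)
        scipy.io.mmwrite(str(path), sp.coo_matrix(self.C), field="integer")
        self.vocab.save(path.with_suffix(path.suffix + ".vocab"))

    @classmethod
    def load(cls, path) -> "CooccurrenceMatrix":
        path = Path(path)
        C = sp.csr_matrix(scipy.io.mmread(str(path)))
        vocab = Vocabulary.load(path.with_suffix(path.suffix + ".vocab"))
        return cls(vocab, C)

    def save_tsv(self, path) -> None:
        """Three-column dialect: code_w, code_c, count (upper triangle incl. diagonal)."""
        coo = sp.coo_matrix(sp.triu(self.C))
        codes = self.vocab.codes
        df = pd.DataFrame(
            {
                "code_w": [codes[i] for i in coo.row],
                "code_c": [codes[j] for j in coo.col],
                "count": coo.data.astype(np.int64),
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path, vocab: Vocabulary) -> "CooccurrenceMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"code_w": str, "code_c": str, "count": np.int64})
        i = np.array([vocab.index(c) for c in df["code_w"]], dtype=np.int64)
        j = np.array([vocab.index(c) for c in df["code_c"]], dtype=np.int64)
        v = df["count"].to_numpy()
        n = len(vocab)
        upper = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsr()
        off = upper - sp.diags(upper.diagonal(), dtype=np.int64)
        return cls(vocab, upper + off.T)


def count_cooccurrence(
    events: EventTable, window_days: int = 30, vocab: Vocabulary | None = None
) -> CooccurrenceMatrix:
    """Count within-window code co-occurrences, streamed per patient.

    Parameters
    ----------
    events
        Deduplicated patient-day records.
    window_days
        Forward window in days (default 30; 7 and 60 are the usual
        sensitivity-analysis settings).  0 counts same-day pairs only.
    vocab
        Codes to count; events with other codes are ignored.  Defaults to
        the vocabulary of the events themselves.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    if vocab is None:
        vocab = events.vocabulary()
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")

    n = len(vocab)
    df = events.df
    idx = df["code"].map(vocab._index)
    keep = idx.notna()
    if not keep.any():
        return CooccurrenceMatrix(vocab, sp.csr_matrix((n, n), dtype=np.int64))
    work = pd.DataFrame(
        {"patient": df.loc[keep, "patient"], "day": df.loc[keep, "day"], "idx": idx[keep].astype(np.int64)}
    ).sort_values(["patient", "day", "idx"], kind="mergesort")

    rows_acc: list[np.ndarray] = []
    cols_acc: list[np.ndarray] = []
    for _, grp in work.groupby("patient", sort=False):
        days = grp["day"].to_numpy()
        codes = grp["idx"].to_numpy()
        m = len(days)
        if m < 2:
            continue
        # index of first event strictly beyond the forward window of each event
        ends = np.searchsorted(days, days + window_days, side="right")
        counts = ends - np.arange(1, m + 1)
        if counts.sum() <= 0:
            continue
        starts = np.arange(m) + 1
        cols = np.concatenate([codes[s:e] for s, e in zip(starts, ends) if e > s])
        rows = np.repeat(codes, np.maximum(counts, 0))
        rows_acc.append(rows)
        cols_acc.append(cols)

    if not rows_acc:
        return CooccurrenceMatrix(vocab, sp.csr_matrix((n, n), dtype=np.int64))
    r = np.concatenate(rows_acc)
    c = np.concatenate(cols_acc)
    directed = sp.coo_matrix((np.ones(len(r), dtype=np.int64), (r, c)), shape=(n, n)).tocsr()
    return CooccurrenceMatrix(vocab, directed + directed.T)
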