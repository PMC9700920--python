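"""Continuous Bag-of-Words embeddings of medical codes, and patient vectors.

The trainer implements the classic CBOW objective with negative sampling:
for each corpus position the mean of the surrounding context vectors predicts
the center token against ``negative`` noise tokens drawn from the unigram
distribution raised to 3/4.  Training is mini-batched numpy with a linearly
decaying learning rate; the shuffle order, noise draws, and initialization all
come from one seeded generator, so a fixed config yields identical vectors.

A patient's feature vector is the sum of the embedding vectors of their last
``K`` in-vocabulary codes (all of them when the sentence is shorter); two
patients with the same last-K code sequence therefore get the same vector,
and earlier history cannot change it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = ["CBOWConfig", "CodeEmbedding", "train_embeddings", "patient_vector",
           "save_embedding", "load_embedding"]


@dataclasses.dataclass(frozen=True)
class CBOWConfig:
    dimension: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 10
    negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    #: frequent-token subsampling threshold (0 disables); occurrences of a
    #: token with corpus frequency f are kept with prob sqrt(t/f) + t/f
    subsample: float = 1e-3
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.window < 1 or self.min_count < 1 or self.epochs < 1:
            raise ValueError("window, min_count and epochs must be >= 1")


@dataclasses.dataclass
class CodeEmbedding:
    """Trained token vectors: one ``dimension``-vector per vocabulary token."""

    tokens: list[str]
    vectors: np.ndarray  # (V, dimension)
    config: CBOWConfig

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray | None:
        i = self.index.get(token)
        return None if i is None else self.vectors[i]

    def similarity(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))


def _build_vocab(corpus, min_count):
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    kept = [(t, c) for t, c in counts.items() if c >= min_count]
    # deterministic order: frequency desc, then token
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    tokens = [t for t, _ in kept]
    freqs = np.array([c for _, c in kept], dtype=float)
    return tokens, freqs


def _encode_corpus(corpus, index):
    """Flat token-index array plus sentence-boundary ids (OOV tokens dropped)."""
    flat, sent_id = [], []
    for s, sent in enumerate(corpus):
        for tok in sent:
            i = index.get(tok)
            if i is not None:
                flat.append(i)
                sent_id.append(s)
    return np.array(flat, dtype=np.int64), np.array(sent_id, dtype=np.int64)


def _context_matrix(flat, sent_id, window, pad):
    """(N, 2*window) context indices per corpus position; ``pad`` marks absent."""
    n = len(flat)
    ctx = np.full((n, 2 * window), pad, dtype=np.int64)
    col = 0
    for off in range(-window, window + 1):
        if off == 0:
            continue
        if off < 0:
            src = flat[: n + off]
            same = sent_id[-off:] == sent_id[: n + off]
            ctx[-off:, col][same] = src[same]
        else:
            src = flat[off:]
            same = sent_id[: n - off] == sent_id[off:]
            ctx[: n - off, col][same] = src[same]
        col += 1
    return ctx


def _scatter_add(mat: np.ndarray, idx: np.ndarray, grad: np.ndarray) -> None:
    """``mat[idx] += grad`` with repeated indices (sort + reduceat; much
    faster than ``np.add.at`` for small vector dimensions)."""
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    starts = np.flatnonzero(np.diff(idx_s)) + 1
    starts = np.concatenate([[0], starts])
    sums = np.add.reduceat(grad[order], starts, axis=0)
    mat[idx_s[starts]] += sums


def train_embeddings(corpus, config: CBOWConfig = CBOWConfig()) -> CodeEmbedding:
    """Train CBOW vectors on an iterable of token lists.

    Deterministic under a fixed config; raises on an empty corpus or a corpus
    with no token reaching ``min_count``.
    """
    corpus = [list(s) for s in corpus]
    if not any(corpus):
        raise ValueError("empty corpus: no sentences with tokens")
    tokens, freqs = _build_vocab(corpus, config.min_count)
    if not tokens:
        raise ValueError(f"no token reaches min_count={config.min_count}")
    index = {t: i for i, t in enumerate(tokens)}
    v, d = len(tokens), config.dimension
    rng = np.random.default_rng(config.seed)
    w_in = (rng.random((v + 1, d)) - 0.5) / d  # last row = context padding (zero)
    w_in[v] = 0.0
    w_out = np.zeros((v, d))

    flat, sent_id = _encode_corpus(corpus, index)
    if config.subsample > 0 and len(flat):
        rel = freqs / freqs.sum()
        keep_p = np.minimum(
            1.0, np.sqrt(config.subsample / rel) + config.subsample / rel
        )
        keep = rng.random(len(flat)) < keep_p[flat]
        flat, sent_id = flat[keep], sent_id[keep]
    if len(flat) < 2:
        return CodeEmbedding(tokens=tokens, vectors=w_in[:v].copy(), config=config)
    ctx = _context_matrix(flat, sent_id, config.window, pad=v)
    has_ctx = (ctx != v).any(axis=1)
    flat, ctx = flat[has_ctx], ctx[has_ctx]
    n = len(flat)
    noise = freqs**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    n_batches_total = config.epochs * int(np.ceil(n / config.batch_size))
    lr0, lr1 = config.learning_rate, config.min_learning_rate
    batch_no = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            b = len(sel)
            lr = max(lr1, lr0 * (1 - batch_no / max(1, n_batches_total)))
            batch_no += 1
            c = ctx[sel]  # (b, 2w)
            mask = c != v
            n_ctx = mask.sum(axis=1, keepdims=True)  # >=1 by filtering
            h = w_in[c].sum(axis=1) / n_ctx  # (b, d) mean of context vectors
            neg = np.searchsorted(
                noise_cdf, rng.random((b, config.negative))
            ).astype(np.int64)
            out_idx = np.concatenate([flat[sel][:, None], neg], axis=1)  # (b, 1+k)
            labels = np.zeros((b, 1 + config.negative))
            labels[:, 0] = 1.0
            u = w_out[out_idx]  # (b, 1+k, d)
            scores = np.einsum("bkd,bd->bk", u, h)
            g = (expit(scores) - labels) * lr  # (b, 1+k)
            grad_h = np.einsum("bk,bkd->bd", g, u)  # (b, d)
            _scatter_add(
                w_out, out_idx.ravel(), -(g[:, :, None] * h[:, None, :]).reshape(-1, d)
            )
            grad_ctx = np.where(
                mask[:, :, None], (grad_h / n_ctx)[:, None, :], 0.0
            ).reshape(-1, d)
            _scatter_add(w_in, c.ravel(), -grad_ctx)
            w_in[v] = 0.0  # padding row stays zero
    return CodeEmbedding(tokens=tokens, vectors=w_in[:v].copy(), config=config)


def patient_vector(tokens, embedding: CodeEmbedding, k_last: int = 25) -> np.ndarray:
    """Sum of the embedding vectors of the last ``k_last`` in-vocabulary tokens.

    Out-of-vocabulary tokens are skipped and do not consume a slot, so the
    vector is a function of the last-K *in-vocabulary* code sequence alone.
    Shorter (or fully out-of-vocabulary) sentences sum what is available; an
    empty selection yields the zero vector.
    """
    if k_last < 1:
        raise ValueError("k_last must be >= 1")
    idx = [embedding.index[t] for t in tokens if t in embedding.index]
    sel = idx[-k_last:]
    if not sel:
        return np.zeros(embedding.dimension)
    return embedding.vectors[sel].sum(axis=0)


def patient_matrix(sentences, patient_ids, embedding, k_last=25) -> np.ndarray:
    """Stack patient vectors in the given patient order: (n, dimension)."""
    return np.vstack(
        [patient_vector(sentences[p].tokens, embedding, k_last) for p in patient_ids]
    )


def save_embedding(embedding: CodeEmbedding, path: str | Path) -> None:
    """Tabular token -> vector file (TSV, one token per line)."""
    with open(path, "w") as f:
        f.write(f"{len(embedding)}\t{embedding.dimension}\n")
        for t, vec in zip(embedding.tokens, embedding.vectors):
            f.write(t + "\t" + "\t".join(f"{x:.8g}" for x in vec) + "\n")


def load_embedding(path: str | Path, config: CBOWConfig | None = None) -> CodeEmbedding:
    with open(path) as f:
        header = f.readline().split("\t")
        v, d = int(header[0]), int(header[1])
        tokens, rows = [], []
        for line in f:
            parts = line.rstrip("\n").split("\t")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    vectors = np.array(rows, dtype=float).reshape(v, d)
    return CodeEmbedding(tokens=tokens, vectors=vectors,
                         config=config or CBOWConfig(dimension=d))
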