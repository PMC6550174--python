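"""Hashed sparse text features for the query classifier.

Each query yields namespaced string tokens — unigrams and bigrams from the
query text (``q:``), result titles (``t:``) and snippets (``s:``), URL path
tokens (``u:``), and concept-tag indicators (``c:``) — which are mapped into
a fixed ``D``-dimensional space by signed feature hashing.

The hash is BLAKE2b with an 8-byte digest of the UTF-8 token, interpreted
as a big-endian unsigned integer ``h``: the index is ``h mod D`` and the
sign is ``+1`` when the top bit of ``h`` is 0, else ``-1``. BLAKE2b is
fully specified and unkeyed here, so hashed indices are stable across
processes, platforms, and library versions; colliding features sum.
"""

from __future__ import annotations

import re
from functools import lru_cache
from hashlib import blake2b

import numpy as np
from scipy import sparse

from foodwatch.exceptions import ParameterError
from foodwatch.types import QueryEvent

_TOKEN_RE = re.compile(r"[^0-9a-z]+")
_URL_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters; no stemming."""
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


def ngram_tokens(tokens: list[str]) -> list[str]:
    """Unigrams plus adjacent bigrams (joined with ``_``)."""
    out = list(tokens)
    out.extend(f"{a}_{b}" for a, b in zip(tokens, tokens[1:]))
    return out


def url_tokens(url: str) -> list[str]:
    """Path-style tokens of a URL, scheme stripped."""
    u = url.lower()
    u = re.sub(r"^[a-z]+://", "", u)
    return [t for t in _URL_RE.split(u) if t and t not in ("www", "com", "org",
                                                           "gov", "html", "htm")]


@lru_cache(maxsize=1 << 20)
def _hash64(token: str) -> int:
    return int.from_bytes(blake2b(token.encode("utf-8"), digest_size=8).digest(),
                          "big")


def hash_token(token: str, dim: int) -> tuple[int, int]:
    """(index, sign) of a namespaced token under signed hashing."""
    h = _hash64(token)
    return h % dim, (1 if (h >> 63) & 1 == 0 else -1)


def feature_tokens(query: QueryEvent) -> list[str]:
    """All namespaced string features of a query, before hashing."""
    toks = [f"q:{t}" for t in ngram_tokens(tokenize(query.query_text))]
    for title in query.result_titles:
        toks.extend(f"t:{t}" for t in ngram_tokens(tokenize(title)))
    for snippet in query.result_snippets:
        toks.extend(f"s:{t}" for t in ngram_tokens(tokenize(snippet)))
    for url in query.result_urls:
        toks.extend(f"u:{t}" for t in url_tokens(url))
    toks.extend(f"c:{tag}" for tag in query.concept_tags)
    return toks


def extract_features(query: QueryEvent, dim: int) -> dict[int, float]:
    """Sparse feature vector of one query as an index -> value map."""
    if dim < 1:
        raise ParameterError("feature dimension must be >= 1")
    vec: dict[int, float] = {}
    for tok in feature_tokens(query):
        idx, sign = hash_token(tok, dim)
        vec[idx] = vec.get(idx, 0.0) + sign
    return {i: v for i, v in vec.items() if v != 0.0}


def design_matrix(queries: list[QueryEvent], dim: int) -> sparse.csr_matrix:
    """CSR matrix of hashed features, one row per query."""
    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for q in queries:
        vec = extract_features(q, dim)
        for i in sorted(vec):
            indices.append(i)
            data.append(vec[i])
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int64),
         np.asarray(indptr, dtype=np.int64)),
        shape=(len(queries), dim),
    )
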