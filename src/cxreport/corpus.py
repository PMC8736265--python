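"""Report preprocessing, vocabulary construction, encoding and corpus splits.

Radiology findings are free text of arbitrary length; the sequence model
works on short, cleaned word sequences bracketed by ``startseq``/``endseq``
sentinels and right-padded to a fixed length.  This module owns that whole
pipeline: text -> chunked lowercase alphabetic reports -> integer id
sequences -> reproducible train/test splits.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

START_TOKEN = "startseq"
END_TOKEN = "endseq"
PAD_ID = 0
START_ID = 1
END_ID = 2

#: default cap on report words; sentinels are counted on top of this
DEFAULT_MAX_WORDS = 22

_SENTENCE_SPLIT = re.compile(r"[.?!]+")
_WORD = re.compile(r"[a-z]+")


class EmptyReportError(ValueError):
    """No tokens survive the lowercase/alphabetic filter."""


class OutOfVocabularyError(KeyError):
    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"token not in vocabulary: {self.token!r}"


def _filter_tokens(text: str) -> list[str]:
    """Lowercase and keep only ASCII-alphabetic word runs."""
    return _WORD.findall(text.lower())


def preprocess_report(raw_text: str, max_words: int = DEFAULT_MAX_WORDS) -> list[str]:
    """Turn a free-text findings paragraph into one or more short reports.

    Text is split into sentences at ``.?!``, lowercased, and non-alphabetic
    tokens are dropped.  Sentences are packed greedily left-to-right into
    chunks of at most ``max_words`` tokens; a single sentence longer than
    ``max_words`` is cut into ``max_words``-sized pieces (each piece becomes
    its own chunk).  The concatenation of all chunk tokens equals the
    filtered token stream of the input.

    Parameters
    ----------
    raw_text : str
        The findings text.
    max_words : int
        Maximum number of words per chunk, excluding the start/end sentinels
        that are added at encoding time.

    Returns
    -------
    list of str
        Non-empty space-joined chunks.

    Raises
    ------
    EmptyReportError
        If no token survives filtering.
    """
    if max_words < 1:
        raise ValueError("max_words must be >= 1")
    sentences = [_filter_tokens(s) for s in _SENTENCE_SPLIT.split(raw_text)]
    sentences = [s for s in sentences if s]
    if not sentences:
        raise EmptyReportError("no tokens survive filtering")

    chunks: list[list[str]] = []
    cur: list[str] = []
    for sent in sentences:
        if len(cur) + len(sent) <= max_words:
            cur.extend(sent)
            continue
        if cur:
            chunks.append(cur)
            cur = []
        if len(sent) <= max_words:
            cur = list(sent)
        else:
            # oversized sentence: hard cuts at max_words, all pieces closed
            for i in range(0, len(sent), max_words):
                chunks.append(sent[i : i + max_words])
    if cur:
        chunks.append(cur)
    return [" ".join(c) for c in chunks]


@dataclass
class Vocabulary:
    """Bidirectional token <-> id map with reserved sentinel ids.

    Ids are 1-based; 0 is the padding id and never denotes a word.
    ``startseq`` and ``endseq`` hold the fixed ids 1 and 2; real words get
    ids from 3 upward in descending corpus frequency (ties lexicographic),
    which makes the assignment deterministic across runs.
    """

    index_of: dict[str, int]

    start_token: str = START_TOKEN
    end_token: str = END_TOKEN
    pad_id: int = PAD_ID

    def __post_init__(self) -> None:
        self._token_of = {i: t for t, i in self.index_of.items()}
        ids = sorted(self.index_of.values())
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("vocabulary ids must be a bijection onto 1..V")
        if self.index_of.get(self.start_token) != START_ID:
            raise ValueError("start token must have id 1")
        if self.index_of.get(self.end_token) != END_ID:
            raise ValueError("end token must have id 2")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_reports(cls, reports: Sequence[str]) -> "Vocabulary":
        """Build the vocabulary over preprocessed report strings."""
        if not reports:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        counts: dict[str, int] = {}
        for rep in reports:
            for tok in rep.split():
                if not tok.isalpha() or tok != tok.lower():
                    raise ValueError(f"report not preprocessed: bad token {tok!r}")
                counts[tok] = counts.get(tok, 0) + 1
        counts.pop(START_TOKEN, None)
        counts.pop(END_TOKEN, None)
        ordered = sorted(counts, key=lambda t: (-counts[t], t))
        index = {START_TOKEN: START_ID, END_TOKEN: END_ID}
        for i, tok in enumerate(ordered, start=3):
            index[tok] = i
        return cls(index_of=index)

    # -- mapping -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.index_of)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    @property
    def tokens(self) -> list[str]:
        """Tokens in id order (ids 1..V)."""
        return [self._token_of[i] for i in range(1, len(self) + 1)]

    def id(self, token: str) -> int:
        try:
            return self.index_of[token]
        except KeyError:
            raise OutOfVocabularyError(token) from None

    def token(self, idx: int) -> str:
        return self._token_of[idx]

    # -- serialisation -----------------------------------------------------

    def to_json(self, path: str | Path, l_max: int | None = None) -> None:
        payload = {
            "tokens": self.index_of,
            "meta": {
                "pad_id": self.pad_id,
                "start_token": self.start_token,
                "end_token": self.end_token,
                "l_max": l_max,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(index_of=payload["tokens"])


def build_vocabulary(reports: Sequence[str]) -> Vocabulary:
    """Functional alias for :meth:`Vocabulary.from_reports`."""
    return Vocabulary.from_reports(reports)


def encode_report(report: str, vocab: Vocabulary, l_max: int) -> np.ndarray:
    """Encode a preprocessed report as ``[start, ids..., end, pad...]``.

    The result has length exactly ``l_max``; raises on unknown tokens and on
    reports that do not fit (word count + 2 > l_max).
    """
    words = report.split()
    if len(words) + 2 > l_max:
        raise ValueError(
            f"report of {len(words)} words does not fit in l_max={l_max} "
            "(two sentinel positions are required)"
        )
    ids = [START_ID] + [vocab.id(w) for w in words] + [END_ID]
    out = np.full(l_max, PAD_ID, dtype=np.int64)
    out[: len(ids)] = ids
    return out


def decode_ids(token_ids: Iterable[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`encode_report`: strip sentinels/padding, join words."""
    words = []
    for i in token_ids:
        i = int(i)
        if i == PAD_ID or i == START_ID:
            continue
        if i == END_ID:
            break
        words.append(vocab.token(i))
    return " ".join(words)


@dataclass
class ReportRecord:
    """One image reference paired with one encoded short report."""

    image_ref: str
    raw_text: str
    token_ids: np.ndarray


@dataclass
class SplitPlan:
    """A reproducible train/test partition of record indices."""

    train_refs: list[int]
    test_refs: list[int]
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        if set(self.train_refs) & set(self.test_refs):
            raise ValueError("train and test overlap")


def split_corpus(
    records: Sequence, fraction: float, seed: int, repeats: int = 1
) -> list[SplitPlan]:
    """Draw ``repeats`` independent random train/test partitions.

    ``|train| = round(fraction * N)``.  The same seed reproduces the same
    list of plans; successive repeats consume the same generator stream, so
    they are distinct draws.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n = len(records)
    n_train = round(fraction * n)
    rng = np.random.default_rng(seed)
    plans = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        plans.append(
            SplitPlan(
                train_refs=[int(i) for i in perm[:n_train]],
                test_refs=[int(i) for i in perm[n_train:]],
                seed=seed,
                fraction=fraction,
            )
        )
    return plans


# -- manifest i/o ----------------------------------------------------------


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read an image/findings manifest.

    JSON-lines (one ``{"image": ..., "findings": ...}`` object per line) or
    a two-column CSV with an ``image,findings`` header.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
    else:
        df = pd.read_json(path, lines=True)
    missing = {"image", "findings"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df[["image", "findings"]]


def build_records(
    manifest: pd.DataFrame,
    vocab: Vocabulary,
    l_max: int,
    max_words: int = DEFAULT_MAX_WORDS,
) -> list[ReportRecord]:
    """Chunk, encode and wrap every manifest row; one record per chunk."""
    records = []
    for row in manifest.itertuples(index=False):
        for chunk in preprocess_report(row.findings, max_words=max_words):
            records.append(
                ReportRecord(
                    image_ref=str(row.image),
                    raw_text=chunk,
                    token_ids=encode_report(chunk, vocab, l_max),
                )
            )
    return records
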