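"""Overlapping k-mer tokenization and vocabulary handling.

Sequences are decomposed into overlapping (stride-1) k-mers, e.g.
``ACTAGGA`` at k=3 → ``ACT, CTA, TAG, AGG, GGA``, which serve as the
tokens of the language model.  The vocabulary is corpus-derived (its
size is the number of distinct observed k-mers plus specials) unless the
full 4^k enumeration is requested.  A non-overlapping mode exists but is
off by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import DnaSequence

PAD, UNK, BOS = "<pad>", "<unk>", "<bos>"
SPECIALS = (PAD, UNK, BOS)


@dataclass(frozen=True)
class KmerVocabulary:
    """Dense mapping from k-mer strings (plus specials) to integer ids."""

    k: int
    token_to_id: dict[str, int]
    id_to_token: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 6):
            raise ValueError("k must be in 1..6")
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("token ids must be dense in [0, size)")
        if not self.id_to_token:
            inv = sorted(self.token_to_id, key=self.token_to_id.get)
            object.__setattr__(self, "id_to_token", tuple(inv))

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    def lookup(self, kmer: str) -> int:
        return self.token_to_id.get(kmer, self.token_to_id[UNK])


@dataclass(frozen=True)
class TokenStream:
    """Integer token ids of one sequence, in sequence order."""

    ids: np.ndarray
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.ids)


def kmerize(sequence: DnaSequence | str, k: int, stride: int = 1) -> list[str]:
    """Overlapping k-mer windows of a sequence, left to right.

    With the default stride 1 the number of windows is ``L - k + 1``.
    """
    residues = sequence.residues if isinstance(sequence, DnaSequence) else sequence
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(residues):
        raise ValueError(f"k={k} exceeds sequence length {len(residues)}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return [residues[i : i + k] for i in range(0, len(residues) - k + 1, stride)]


def build_vocabulary(
    corpus: list[DnaSequence], k: int, full_enumeration: bool = False
) -> KmerVocabulary:
    """Build the k-mer vocabulary over a corpus.

    Non-special tokens are the distinct observed k-mers in sorted order
    (deterministic ids), or all 4^k ACGT k-mers when
    ``full_enumeration`` is set.  An empty corpus yields a
    specials-only vocabulary with a warning.
    """
    if full_enumeration:
        kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    else:
        observed: set[str] = set()
        for seq in corpus:
            observed.update(kmerize(seq, k))
        kmers = sorted(observed)
    if not kmers:
        import warnings

        warnings.warn("empty corpus: vocabulary contains only special tokens")
    tokens = list(SPECIALS) + kmers
    return KmerVocabulary(k=k, token_to_id={t: i for i, t in enumerate(tokens)})


def numericalize(
    sequence: DnaSequence | str,
    vocab: KmerVocabulary,
    add_bos: bool = False,
    stride: int = 1,
) -> TokenStream:
    """Map a sequence's k-mers to vocabulary ids; unknowns (e.g. k-mers
    containing N) map to the unk token."""
    kmers = kmerize(sequence, vocab.k, stride=stride)
    ids = [vocab.lookup(km) for km in kmers]
    if add_bos:
        ids = [vocab.bos_id] + ids
    source_id = sequence.id if isinstance(sequence, DnaSequence) else ""
    return TokenStream(ids=np.asarray(ids, dtype=np.int64), source_id=source_id)


def denumericalize(stream: TokenStream, vocab: KmerVocabulary) -> list[str]:
    """Inverse of :func:`numericalize` for in-vocabulary sequences."""
    return [vocab.id_to_token[i] for i in stream.ids]


def save_vocabulary(vocab: KmerVocabulary, path: str | Path) -> Path:
    """Serialize as a plain-text two-column (token, id) file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# k={vocab.k}\n")
        for token, idx in sorted(vocab.token_to_id.items(), key=lambda kv: kv[1]):
            fh.write(f"{token}\t{idx}\n")
    return path


def load_vocabulary(path: str | Path) -> KmerVocabulary:
    path = Path(path)
    token_to_id: dict[str, int] = {}
    k = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            k = int(line.split("=", 1)[1])
            continue
        if not line.strip():
            continue
        token, idx = line.rsplit("\t", 1)
        token_to_id[token] = int(idx)
    if k is None:
        raise ValueError(f"{path}: missing '# k=' header")
    return KmerVocabulary(k=k, token_to_id=token_to_id)
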