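"""FASTA input/output and the two-layer enhancer benchmark loader.

The benchmark (Liu et al. 2016 style) consists of fixed-length 200 bp
sequences organised in two prediction layers: enhancer vs. non-enhancer
(identification) and, among enhancers, strong vs. weak (strength).  The
data are distributed as one FASTA file per class per split; a manifest
file maps each FASTA file to its (task, split, label) triple so any
redistribution layout can be adapted without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

Layer1 = Literal["enhancer", "non_enhancer"]
Layer2 = Literal["strong", "weak", "not_applicable"]
Task = Literal["identification", "strength"]
Split = Literal["core", "independent_test"]

#: Expected class counts of the canonical benchmark, keyed by
#: (task, split, layer-label).  Mismatches warn but do not fail, so that
#: subsets or re-releases of the data remain loadable.
EXPECTED_COUNTS = {
    ("identification", "core", "enhancer"): 1484,
    ("identification", "core", "non_enhancer"): 1484,
    ("strength", "core", "strong"): 742,
    ("strength", "core", "weak"): 742,
    ("strength", "independent_test", "strong"): 100,
    ("strength", "independent_test", "weak"): 100,
}

#: Default file layout written by the synthetic generator and expected for
#: a locally installed benchmark.  The independent identification
#: non-enhancer file is optional (its existence differs between
#: redistributions); the loader reports what it finds.
DEFAULT_MANIFEST = {
    "identification": {
        "core": {"enhancer": "core_enhancers.fa", "non_enhancer": "core_non_enhancers.fa"},
        "independent_test": {
            "enhancer": "independent_enhancers.fa",
            "non_enhancer": "independent_non_enhancers.fa",
        },
    },
    "strength": {
        "core": {"strong": "core_strong.fa", "weak": "core_weak.fa"},
        "independent_test": {"strong": "independent_strong.fa", "weak": "independent_weak.fa"},
    },
}

MANIFEST_NAME = "manifest.yaml"


class FastaFormatError(ValueError):
    """Raised for files that are not parseable FASTA."""


class AlphabetError(ValueError):
    """Raised when a record contains residues outside {A,C,G,T,N}."""


class BenchmarkNotInstalledError(FileNotFoundError):
    """Raised when an expected benchmark FASTA file is absent."""


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence over the {A,C,G,T,N} alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains residues outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledExample:
    """A sequence with its two-layer label.

    ``layer2`` is only meaningful for enhancers; non-enhancers carry
    ``not_applicable``.
    """

    sequence: DnaSequence
    layer1: Layer1
    layer2: Layer2 = "not_applicable"

    def __post_init__(self) -> None:
        if self.layer1 == "non_enhancer" and self.layer2 != "not_applicable":
            raise ValueError("non-enhancers cannot carry a strength label")
        if self.layer1 == "enhancer" and self.layer2 not in ("strong", "weak", "not_applicable"):
            raise ValueError(f"invalid layer2 label {self.layer2!r}")


@dataclass
class BenchmarkDataset:
    """A labeled collection of same-source sequences for one task/split."""

    examples: list[LabeledExample]
    task: Task
    split: Split = "core"
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            self.class_counts = self._count()

    def _count(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ex in self.examples:
            label = ex.layer2 if self.task == "strength" else ex.layer1
            counts[label] = counts.get(label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.examples)

    def sequences(self) -> list[DnaSequence]:
        return [ex.sequence for ex in self.examples]

    def labels(self) -> list[str]:
        """Task-relevant label per example (layer1 or layer2)."""
        key = "layer2" if self.task == "strength" else "layer1"
        return [getattr(ex, key) for ex in self.examples]


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a FASTA file into a list of uppercased :class:`DnaSequence`.

    Raises :class:`FastaFormatError` for a non-empty file with no
    parseable records and :class:`AlphabetError` (naming the offending
    record) for residues outside {A,C,G,T,N}.  An empty file yields an
    empty list.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: not FASTA (first non-blank character is not '>')")
    out: list[DnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - ALPHABET
        if bad:
            raise AlphabetError(
                f"{path}: record {rec.id!r} has residues outside ACGTN: {sorted(bad)}"
            )
        out.append(DnaSequence(rec.id, residues))
    if text.strip() and not out:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Iterable[DnaSequence], path: str | Path, width: int = 80) -> Path:
    """Write sequences to FASTA; round-trips through :func:`read_fasta`."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("refusing to write an empty FASTA file")
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    path = Path(path)
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(records)
    return path


def _load_manifest(directory: Path) -> dict:
    manifest_path = directory / MANIFEST_NAME
    if manifest_path.exists():
        with manifest_path.open() as fh:
            return yaml.safe_load(fh)
    return DEFAULT_MANIFEST


def write_manifest(directory: str | Path, manifest: dict | None = None) -> Path:
    """Write the file→label manifest next to the FASTA files."""
    directory = Path(directory)
    path = directory / MANIFEST_NAME
    with path.open("w") as fh:
        yaml.safe_dump(manifest or DEFAULT_MANIFEST, fh)
    return path


def load_benchmark(
    directory: str | Path, task: Task, split: Split = "core"
) -> BenchmarkDataset:
    """Load one task/split of the two-layer benchmark from ``directory``.

    The directory must contain one FASTA file per class as named by the
    manifest (``manifest.yaml``, falling back to the default layout).
    Class counts differing from the canonical benchmark are reported as a
    warning, not an error.  For the independent identification split the
    non-enhancer file is optional.
    """
    directory = Path(directory)
    manifest = _load_manifest(directory)
    try:
        file_map: dict[str, str] = manifest[task][split]
    except KeyError as exc:
        raise KeyError(f"manifest has no entry for task={task!r}, split={split!r}") from exc

    examples: list[LabeledExample] = []
    counts: dict[str, int] = {}
    for label, filename in file_map.items():
        fpath = directory / filename
        if not fpath.exists():
            optional = task == "identification" and split == "independent_test" and label == "non_enhancer"
            if optional:
                warnings.warn(
                    f"optional file {filename} absent; independent identification set "
                    "loaded with enhancers only"
                )
                continue
            raise BenchmarkNotInstalledError(
                f"benchmark file {fpath} not found; either install the two-layer "
                "benchmark FASTA files there or generate a synthetic stand-in with "
                "enhancerlm.synthetic_data / `enhancerlm generate-synthetic`"
            )
        seqs = read_fasta(fpath)
        for seq in seqs:
            if task == "strength":
                examples.append(LabeledExample(seq, "enhancer", label))  # type: ignore[arg-type]
            else:
                examples.append(LabeledExample(seq, label))  # type: ignore[arg-type]
        counts[label] = counts.get(label, 0) + len(seqs)

    for label, n in counts.items():
        expected = EXPECTED_COUNTS.get((task, split, label))
        if expected is not None and n != expected:
            warnings.warn(
                f"{task}/{split}/{label}: found {n} sequences, canonical benchmark has {expected}"
            )
    lengths = {len(ex.sequence) for ex in examples}
    if len(lengths) > 1:
        warnings.warn(f"{task}/{split}: sequences have mixed lengths {sorted(lengths)}")
    return BenchmarkDataset(examples, task=task, split=split, class_counts=counts)
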