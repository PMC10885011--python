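"""Synthetic two-layer enhancer datasets with a compositional class signal.

Real enhancer sequences are GC-enriched relative to non-enhancers, which
are A/T-rich and show an excess of AA/AAA/TT/TTT runs; strong enhancers
carry a weaker version of the same GC gradient relative to weak
enhancers.  The generator plants exactly that structure: residues are
drawn i.i.d. with a class-specific GC probability, optionally augmented
by a first-order Markov boost that makes an A (or T) more likely to
extend an existing A (or T) run in the AT-rich class.

The output is the same :class:`~enhancerlm.sequence_io.BenchmarkDataset`
the benchmark loader produces, so every downstream stage is
source-agnostic.  No attempt is made to simulate enhancer motif grammar
or genomic context.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import (
    BenchmarkDataset,
    DnaSequence,
    LabeledExample,
    write_fasta,
    write_manifest,
    DEFAULT_MANIFEST,
)

BASES = np.array(list("ACGT"))

#: Default GC probabilities: `easy` gives a strong, clearly separable
#: compositional signal; `hard` a weak one near the decision boundary.
PRESETS = {
    "easy": (0.60, 0.40),
    "hard": (0.52, 0.48),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic signal model.

    gc_positive / gc_negative are the marginal {G,C} probabilities of the
    positive (enhancer / strong) and negative (non-enhancer / weak)
    classes.  ``homopolymer_boost`` adds a first-order Markov excess to
    A→A and T→T transitions in the negative class: after an A, the
    probability of another A is multiplied by (1 + boost) and the three
    alternatives renormalised (likewise for T).
    """

    n_per_class: int = 200
    length: int = 200
    gc_positive: float = 0.60
    gc_negative: float = 0.40
    homopolymer_boost: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_positive < 1.0 and 0.0 < self.gc_negative < 1.0):
            raise ValueError("gc probabilities must lie strictly in (0, 1)")
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be non-negative")
        if self.length < 1:
            raise ValueError("length must be positive")
        if self.homopolymer_boost < 0:
            raise ValueError("homopolymer_boost must be non-negative")


def _base_probs(gc: float) -> np.ndarray:
    """Marginal probabilities (A, C, G, T) with P(G)=P(C)=gc/2."""
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _draw_iid(rng: np.random.Generator, n: int, length: int, gc: float) -> list[str]:
    probs = _base_probs(gc)
    idx = rng.choice(4, size=(n, length), p=probs)
    return ["".join(row) for row in BASES[idx]]


def _draw_markov(
    rng: np.random.Generator, n: int, length: int, gc: float, boost: float
) -> list[str]:
    """A/T-run-boosted sampling: first-order Markov chain over ACGT.

    The stationary behaviour stays close to the i.i.d. marginal; the
    boost only reweights the self-transition of A and of T.
    """
    probs = _base_probs(gc)
    # Transition rows: from A (index 0) and T (index 3) boost the
    # self-transition; other rows are the marginal.
    trans = np.tile(probs, (4, 1))
    for b in (0, 3):
        row = probs.copy()
        row[b] *= 1.0 + boost
        trans[b] = row / row.sum()
    seqs = np.empty((n, length), dtype=np.int64)
    seqs[:, 0] = rng.choice(4, size=n, p=probs)
    # Vectorised chain step via per-row inverse-CDF sampling.
    cum = np.cumsum(trans, axis=1)
    for t in range(1, length):
        u = rng.random(n)
        rows = cum[seqs[:, t - 1]]
        seqs[:, t] = (u[:, None] > rows).sum(axis=1)
    return ["".join(row) for row in BASES[seqs]]


def _generate(spec: SyntheticSpec, pos_label: tuple, neg_label: tuple, task: str) -> BenchmarkDataset:
    rng = np.random.default_rng(spec.seed)
    pos = _draw_iid(rng, spec.n_per_class, spec.length, spec.gc_positive)
    if spec.homopolymer_boost > 0:
        neg = _draw_markov(rng, spec.n_per_class, spec.length, spec.gc_negative, spec.homopolymer_boost)
    else:
        neg = _draw_iid(rng, spec.n_per_class, spec.length, spec.gc_negative)
    examples = [
        LabeledExample(DnaSequence(f"{pos_label[-1]}_{i}", s), *pos_label)
        for i, s in enumerate(pos)
    ] + [
        LabeledExample(DnaSequence(f"{neg_label[-1]}_{i}", s), *neg_label)
        for i, s in enumerate(neg)
    ]
    return BenchmarkDataset(examples, task=task)  # type: ignore[arg-type]


def generate_identification_dataset(spec: SyntheticSpec) -> BenchmarkDataset:
    """Balanced enhancer vs. non-enhancer dataset with a GC signal.

    Enhancers are drawn i.i.d. with GC probability ``gc_positive``;
    non-enhancers with ``gc_negative`` plus the A/T homopolymer boost.
    Deterministic under ``spec.seed``.
    """
    return _generate(spec, ("enhancer",), ("non_enhancer",), "identification")


def generate_strength_dataset(spec: SyntheticSpec) -> BenchmarkDataset:
    """Strong vs. weak enhancer dataset; all examples are layer-1 enhancers."""
    return _generate(spec, ("enhancer", "strong"), ("enhancer", "weak"), "strength")


def composition_report(dataset: BenchmarkDataset) -> pd.DataFrame:
    """Per-class, per-position nucleotide frequency table.

    Returns a DataFrame indexed by (class label, position) with columns
    A, C, G, T; each row sums to 1.  Requires equal-length sequences.
    """
    if not dataset.examples:
        raise ValueError("empty dataset")
    lengths = {len(ex.sequence) for ex in dataset.examples}
    if len(lengths) != 1:
        raise ValueError(f"sequences have ragged lengths {sorted(lengths)}")
    (length,) = lengths
    rows = []
    labels = dataset.labels()
    arr = np.frombuffer(
        "".join(ex.sequence.residues for ex in dataset.examples).encode(), dtype="S1"
    ).reshape(len(dataset.examples), length)
    for label in sorted(set(labels)):
        mask = np.array([l == label for l in labels])
        sub = arr[mask]
        for pos in range(length):
            col = sub[:, pos]
            freqs = [np.mean(col == base.encode()) for base in "ACGT"]
            rows.append({"class": label, "position": pos, **dict(zip("ACGT", freqs))})
    return pd.DataFrame(rows).set_index(["class", "position"])


def gc_fraction_scores(dataset: BenchmarkDataset) -> np.ndarray:
    """Per-example G+C fraction — the Bayes-aligned baseline score for the
    planted compositional signal; used as a separability oracle."""
    return np.array(
        [
            (ex.sequence.residues.count("G") + ex.sequence.residues.count("C"))
            / len(ex.sequence)
            for ex in dataset.examples
        ]
    )


def write_synthetic_benchmark(directory: str | Path, spec: SyntheticSpec) -> Path:
    """Write class-wise FASTA files plus manifest, mirroring the benchmark layout.

    Emits the identification core files and the strength core files from
    two generator draws (seeds ``spec.seed`` and ``spec.seed + 1``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ident = generate_identification_dataset(spec)
    strength = generate_strength_dataset(
        SyntheticSpec(
            n_per_class=spec.n_per_class,
            length=spec.length,
            gc_positive=spec.gc_positive,
            gc_negative=spec.gc_negative,
            homopolymer_boost=spec.homopolymer_boost,
            seed=spec.seed + 1,
        )
    )
    layout = DEFAULT_MANIFEST
    for dataset in (ident, strength):
        file_map = layout[dataset.task]["core"]
        for label, filename in file_map.items():
            seqs = [
                ex.sequence
                for ex in dataset.examples
                if (ex.layer2 if dataset.task == "strength" else ex.layer1) == label
            ]
            write_fasta(seqs, directory / filename)
    write_manifest(directory)
    return directory
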